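"""Synthetic cohorts, streamline phantoms, and diffusion-weighted signal.

Everything downstream of tractography and tensor fitting can be exercised on
the outputs of this module: geometric streamline bundles standing in for the
eight major white-matter tracts, diffusion-weighted volumes simulated from a
known tensor field, and covariate tables whose per-tract fractional
anisotropy (FA) follows an additive linear model in intracranial volume
(ICV), age, and sex.

The cohort defaults encode a population of 50-66 year olds with sex-specific
ICV distributions (men 1667.9 +/- 120.2 ml, women 1455.9 +/- 115.8 ml), a
small positive FA-ICV slope, a small negative FA-age slope, and a small
positive FA offset for women, with tract-level residual noise around 0.011
FA units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

TRACT_NAMES: Tuple[str, ...] = ("CC", "CG", "SLF", "ILF", "IFO", "CST", "OR", "UNC")

#: Per-tract mean FA baselines (men column of the reference summary table).
DEFAULT_TRACT_BASELINES: Dict[str, float] = {
    "CC": 0.359,
    "CG": 0.325,
    "SLF": 0.328,
    "ILF": 0.354,
    "IFO": 0.342,
    "CST": 0.392,
    "OR": 0.380,
    "UNC": 0.307,
}


@dataclass
class CohortSpec:
    """Parameters of the forward linear model generating a subject table.

    FA for each tract is
    ``baseline + beta_icv*(icv - mean icv) + beta_age*(age - mean age)
    + sex_offset*[female] + N(0, noise_sd)``.

    Units: ICV in ml, age in years, FA unitless. ``beta_icv`` is FA per ml,
    ``beta_age`` FA per year.
    """

    n_men: int = 383
    n_women: int = 429
    age_range: Tuple[float, float] = (50.0, 66.0)
    icv_mean_men: float = 1667.9
    icv_sd_men: float = 120.2
    icv_mean_women: float = 1455.9
    icv_sd_women: float = 115.8
    tract_baselines: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRACT_BASELINES)
    )
    beta_icv: float = 4.7e-5
    beta_age: float = -3.0e-4
    sex_offset: float = 0.004
    noise_sd: float = 0.011
    seed: int = 0

    def validate(self) -> None:
        if self.n_men <= 0 or self.n_women <= 0:
            raise ValueError("n_men and n_women must be positive")
        if self.icv_sd_men <= 0 or self.icv_sd_women <= 0:
            raise ValueError("ICV standard deviations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy low < high")
        if not self.tract_baselines:
            raise ValueError("tract_baselines must be non-empty")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Run the cohort model forward and return one row per subject.

    Columns: ``subject_id, sex, age, icv_ml`` plus ``<tract>_fa`` per tract.
    Sex is coded ``M``/``F``. ICVs are redrawn until positive (the default
    distributions make negative draws astronomically unlikely, but the
    contract requires positivity). Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_men + spec.n_women
    sex = np.array(["M"] * spec.n_men + ["F"] * spec.n_women)

    icv = np.empty(n)
    icv[: spec.n_men] = rng.normal(spec.icv_mean_men, spec.icv_sd_men, spec.n_men)
    icv[spec.n_men :] = rng.normal(
        spec.icv_mean_women, spec.icv_sd_women, spec.n_women
    )
    bad = icv <= 0
    while bad.any():
        means = np.where(sex == "M", spec.icv_mean_men, spec.icv_mean_women)
        sds = np.where(sex == "M", spec.icv_sd_men, spec.icv_sd_women)
        icv[bad] = rng.normal(means[bad], sds[bad])
        bad = icv <= 0

    age = rng.uniform(spec.age_range[0], spec.age_range[1], n)
    female = (sex == "F").astype(float)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "icv_ml": icv,
        }
    )
    icv_c = icv - icv.mean()
    age_c = age - age.mean()
    for tract, baseline in spec.tract_baselines.items():
        noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
        table[f"{tract}_fa"] = (
            baseline
            + spec.beta_icv * icv_c
            + spec.beta_age * age_c
            + spec.sex_offset * female
            + noise
        )
    return table


# ---------------------------------------------------------------------------
# Streamline bundle phantoms
# ---------------------------------------------------------------------------


@dataclass
class BundleGeometry:
    """A tract archetype: a centerline curve plus a dispersion radius."""

    name: str
    centerline: np.ndarray  # (m, 3) mm
    radius: float  # mm
    n_streamlines: int

    def validate(self) -> None:
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 2 or cl.shape[1] != 3:
            raise ValueError("centerline must be an (m>=2, 3) array")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")


def _unit_ball(rng: np.random.Generator, scale: float) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    if norm == 0:
        return np.zeros(3)
    r = scale * rng.uniform() ** (1.0 / 3.0)
    return v / norm * r


def generate_bundle(
    geometry: BundleGeometry,
    seed: int,
    flip: bool = True,
) -> List[np.ndarray]:
    """Generate streamlines as smooth random displacements of the centerline.

    Each streamline's offset is a quadratic Bezier curve through three random
    control vectors drawn uniformly from the ball of the geometry's radius;
    the convex-hull property bounds the pointwise offset by the radius, so
    ``radius=0`` reproduces the centerline exactly. With ``flip=True`` each
    streamline's point order is reversed with probability 1/2, so downstream
    distance computations must be flip-invariant.
    """
    geometry.validate()
    rng = np.random.default_rng(seed)
    cl = np.asarray(geometry.centerline, dtype=float)
    m = cl.shape[0]
    t = np.linspace(0.0, 1.0, m)[:, None]
    b0 = (1 - t) ** 2
    b1 = 2 * t * (1 - t)
    b2 = t**2

    streamlines: List[np.ndarray] = []
    for _ in range(geometry.n_streamlines):
        c0 = _unit_ball(rng, geometry.radius)
        c1 = _unit_ball(rng, geometry.radius)
        c2 = _unit_ball(rng, geometry.radius)
        offset = b0 * c0 + b1 * c1 + b2 * c2
        pts = cl + offset
        if flip and rng.uniform() < 0.5:
            pts = pts[::-1].copy()
        streamlines.append(pts)
    return streamlines


def archetype_centerlines(
    n_points: int = 40, scale: float = 60.0
) -> Dict[str, np.ndarray]:
    """Geometric centerlines for the eight tract archetypes.

    These are deliberately schematic curves (arches, verticals, gentle arcs)
    placed far apart in a ~(2*scale) mm cube so default phantoms form
    well-separated bundles; they are not anatomical models.
    """
    t = np.linspace(0.0, 1.0, n_points)
    s = scale

    def curve(x, y, z):
        return np.stack([x, y, z], axis=1)

    arch = np.sin(np.pi * t)
    curves = {
        # interhemispheric arch
        "CC": curve(s * (2 * t - 1), np.zeros_like(t), 0.5 * s * arch),
        # C-shaped curve, displaced laterally
        "CG": curve(
            0.3 * s + 0.2 * s * np.cos(np.pi * t),
            s * (2 * t - 1) * 0.6,
            1.2 * s + 0.3 * s * arch,
        ),
        # long anterior-posterior arc, superior
        "SLF": curve(0.9 * s * np.ones_like(t), s * (2 * t - 1) * 0.8, 2.2 * s + 0.2 * s * arch),
        # inferior longitudinal, straight-ish
        "ILF": curve(-0.9 * s * np.ones_like(t), s * (2 * t - 1) * 0.8, -1.2 * s * np.ones_like(t)),
        # fronto-occipital sweep
        "IFO": curve(-2.0 * s + 0.2 * s * arch, s * (2 * t - 1), 0.4 * s * np.ones_like(t)),
        # vertical projection tract
        "CST": curve(2.0 * s * np.ones_like(t), 0.2 * s * np.sin(2 * np.pi * t) * 0.3, s * (2 * t - 1)),
        # posterior radiation fanning backwards
        "OR": curve(0.5 * s + 0.4 * s * t, -2.2 * s + 0.8 * s * t, -2.2 * s * np.ones_like(t)),
        # hooked frontal-temporal curve
        "UNC": curve(
            -0.5 * s - 0.4 * s * np.sin(0.5 * np.pi * t),
            2.2 * s * np.ones_like(t),
            2.0 * s - 0.8 * s * t + 0.3 * s * arch,
        ),
    }
    return curves


def default_phantom(
    n_streamlines: int = 200,
    radius: float = 2.0,
    seed: int = 0,
    tracts: Sequence[str] = TRACT_NAMES,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Eight-bundle phantom: streamlines plus integer ground-truth labels."""
    centerlines = archetype_centerlines()
    streamlines: List[np.ndarray] = []
    labels: List[int] = []
    for i, name in enumerate(tracts):
        geom = BundleGeometry(name, centerlines[name], radius, n_streamlines)
        streamlines.extend(generate_bundle(geom, seed=seed + i))
        labels.extend([i] * n_streamlines)
    return streamlines, np.asarray(labels)


# ---------------------------------------------------------------------------
# Diffusion-weighted signal simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDWISpec:
    """Tensor field plus acquisition scheme for signal simulation.

    ``tensor_field`` has shape (X, Y, Z, 3, 3) in mm^2/s; ``bvals`` in s/mm^2;
    ``bvecs`` (n, 3) unit vectors. ``snr`` is the b=0 signal-to-noise ratio;
    ``inf`` means noiseless.
    """

    tensor_field: np.ndarray
    s0: float = 1000.0
    bvals: np.ndarray = field(default_factory=lambda: default_scheme()[0])
    bvecs: np.ndarray = field(default_factory=lambda: default_scheme()[1])
    snr: float = np.inf

    def validate(self) -> None:
        tf = np.asarray(self.tensor_field, dtype=float)
        if tf.ndim != 5 or tf.shape[-2:] != (3, 3):
            raise ValueError("tensor_field must have shape (X, Y, Z, 3, 3)")
        if not np.allclose(tf, np.swapaxes(tf, -1, -2), atol=1e-12):
            raise ValueError("tensors must be symmetric")
        evals = np.linalg.eigvalsh(tf.reshape(-1, 3, 3))
        if (evals < -1e-12).any():
            raise ValueError("tensors must be positive semi-definite")
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if (bvals < 0).any():
            raise ValueError("bvals must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        nz = bvals > 0
        if not np.allclose(norms[nz], 1.0, atol=1e-6):
            raise ValueError("bvecs for b>0 volumes must be unit vectors")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")


def default_scheme(
    n_directions: int = 40, n_b0: int = 5, b: float = 1000.0, seed: int = 42
) -> Tuple[np.ndarray, np.ndarray]:
    """A 40-direction, 5x b=0, b=1000 s/mm^2 single-shell scheme.

    Directions are quasi-uniform points on the sphere (Fibonacci spiral),
    which is sufficient for well-conditioned tensor estimation.
    """
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_directions
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def simulate_dwi(spec: SyntheticDWISpec, seed: int = 0) -> np.ndarray:
    """Simulate DWI volumes under S = s0 * exp(-b g^T D g) with Rician noise.

    Returns an (X, Y, Z, n_volumes) array. Noise sigma is ``s0 / snr``; the
    magnitude signal is ``sqrt((S + n1)^2 + n2^2)`` with independent Gaussian
    n1, n2, the standard model for magnitude MR data. ``snr=inf`` is
    deterministic and exact.
    """
    spec.validate()
    tf = np.asarray(spec.tensor_field, dtype=float)
    bvals = np.asarray(spec.bvals, dtype=float)
    bvecs = np.asarray(spec.bvecs, dtype=float)
    # g^T D g per voxel per direction
    quad = np.einsum("ni,xyzij,nj->xyzn", bvecs, tf, bvecs)
    signal = spec.s0 * np.exp(-bvals[None, None, None, :] * quad)
    if np.isinf(spec.snr):
        return signal
    if spec.snr <= 0:
        raise ValueError("snr must be positive or inf")
    rng = np.random.default_rng(seed)
    sigma = spec.s0 / spec.snr
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def tensor_from_eigen(
    evals: Sequence[float], evecs: Optional[np.ndarray] = None
) -> np.ndarray:
    """Build a 3x3 tensor from eigenvalues (and optional eigenvector triad)."""
    lam = np.asarray(evals, dtype=float)
    if evecs is None:
        return np.diag(lam)
    v = np.asarray(evecs, dtype=float)
    return v @ np.diag(lam) @ v.T


def uniform_tensor_field(
    shape: Tuple[int, int, int], tensor: np.ndarray
) -> np.ndarray:
    """Tile a single tensor over a voxel grid."""
    field_arr = np.empty(shape + (3, 3))
    field_arr[...] = tensor
    return field_arr
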