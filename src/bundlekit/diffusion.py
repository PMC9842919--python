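"""Diffusion tensor fitting, scalar indices, skeleton projection, motion RMS.

The tensor is estimated per voxel by log-linear least squares on
``log S = log S0 - b g^T D g``. Scalar indices follow the standard
eigenvalue formulas:

    FA = sqrt(1/2) * sqrt(((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2)
                          / (l1^2 + l2^2 + l3^2))
    MD = (l1 + l2 + l3) / 3,  AD = l1,  RD = (l2 + l3) / 2

Skeleton handling is registration-free: the skeleton is either supplied as a
mask or built by ridge detection on a mean-FA map thresholded at FA >= 0.2,
and each skeleton voxel takes the maximum FA found along its perpendicular
search direction (capped search), mirroring the projection step of
skeleton-based voxelwise analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

FA_SKELETON_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# Tensor fit
# ---------------------------------------------------------------------------


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    b = bvals
    cols = np.stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    return np.concatenate([np.ones((len(b), 1)), -cols], axis=1)


def fit_tensor(
    dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the diffusion tensor voxelwise by log-linear least squares.

    Parameters
    ----------
    dwi : (X, Y, Z, n) signal volumes.
    bvals, bvecs : acquisition scheme (n,) and (n, 3).

    Returns
    -------
    evals : (X, Y, Z, 3) eigenvalues sorted descending (l1 >= l2 >= l3).
    evecs : (X, Y, Z, 3, 3) eigenvectors as columns, matching evals order.
    valid : (X, Y, Z) bool, False where the b=0 signal is non-positive.
    """
    dwi = np.asarray(dwi, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    nz = bvals > 0
    if nz.sum() < 6 or (~nz).sum() < 1 or len(bvals) < 7:
        raise ValueError(
            "tensor fit needs >= 6 non-zero-b directions and >= 1 b=0 volume"
        )
    X = _design_matrix(bvals, bvecs)

    shape = dwi.shape[:3]
    flat = dwi.reshape(-1, dwi.shape[3])
    valid = (flat[:, ~nz] > 0).all(axis=1) & (flat > 0).all(axis=1)
    logs = np.where(flat > 0, np.log(np.maximum(flat, 1e-300)), 0.0)
    coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)  # (7, nvox)
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:7]
    tensors = np.empty((flat.shape[0], 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    tensors[~valid] = 0.0

    evals, evecs = np.linalg.eigh(tensors)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    return (
        evals.reshape(shape + (3,)),
        evecs.reshape(shape + (3, 3)),
        valid.reshape(shape),
    )


def compute_indices(evals: np.ndarray) -> dict:
    """FA, MD, AD, RD maps from sorted eigenvalue volumes.

    All-zero tensors get FA = 0 (background voxels must not poison skeleton
    statistics). FA is clipped to [0, 1]; noisy fits with negative
    eigenvalues can otherwise exceed 1.
    """
    lam = np.asarray(evals, dtype=float)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(np.where(den > 0, num / np.maximum(den, 1e-300), 0.0))
    fa = np.clip(np.where(den > 0, fa, 0.0), 0.0, 1.0)
    md = (l1 + l2 + l3) / 3.0
    rd = (l2 + l3) / 2.0
    return {"FA": fa, "MD": md, "AD": l1.copy(), "RD": rd}


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------


@dataclass
class SkeletonMask:
    """Boolean skeleton plus a per-voxel perpendicular search direction."""

    mask: np.ndarray  # (X, Y, Z) bool
    directions: np.ndarray  # (X, Y, Z, 3) unit vectors (zero off-skeleton)

    def __post_init__(self) -> None:
        if self.mask.shape != self.directions.shape[:3]:
            raise ValueError("mask and directions grids differ")


def build_skeleton(
    mean_fa: np.ndarray,
    threshold: float = FA_SKELETON_THRESHOLD,
    smooth_sigma: float = 1.0,
) -> SkeletonMask:
    """Ridge-detection skeleton of a mean FA map.

    A voxel joins the skeleton when its (smoothed) FA is at least
    ``threshold`` and is a local maximum along the direction of strongest
    downward curvature of the FA surface (the Hessian eigenvector with the
    most negative eigenvalue) — a discrete ridge test. The same direction is
    stored as the voxel's perpendicular search direction for projection.
    """
    from scipy.ndimage import gaussian_filter

    fa = np.asarray(mean_fa, dtype=float)
    sm = gaussian_filter(fa, smooth_sigma) if smooth_sigma > 0 else fa
    gx, gy, gz = np.gradient(sm)
    hess = np.empty(fa.shape + (3, 3))
    for i, g in enumerate((gx, gy, gz)):
        d = np.gradient(g)
        for j in range(3):
            hess[..., i, j] = d[j]
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))
    w, v = np.linalg.eigh(hess)
    direction = v[..., :, 0]  # most negative curvature

    candidates = fa >= threshold
    mask = np.zeros_like(candidates)
    directions = np.zeros(fa.shape + (3,))
    idx = np.argwhere(candidates)
    shape = fa.shape
    for x, y, z in idx:
        d = direction[x, y, z]
        n = np.linalg.norm(d)
        if n == 0:
            continue
        d = d / n
        step = np.round(d).astype(int)
        if not step.any():
            step = np.zeros(3, int)
            step[np.argmax(np.abs(d))] = int(np.sign(d[np.argmax(np.abs(d))]) or 1)
        p1 = np.array([x, y, z]) + step
        p2 = np.array([x, y, z]) - step
        ok = True
        for p in (p1, p2):
            if all(0 <= p[k] < shape[k] for k in range(3)):
                if sm[tuple(p)] > sm[x, y, z]:
                    ok = False
        if ok:
            mask[x, y, z] = True
            directions[x, y, z] = d
    return SkeletonMask(mask=mask, directions=directions)


def project_to_skeleton(
    fa_map: np.ndarray,
    skeleton: SkeletonMask,
    search_cap: int = 5,
) -> np.ndarray:
    """Carry the maximum FA along each skeleton voxel's search direction.

    Returns a map that is zero off the skeleton; each skeleton voxel holds
    the maximum of the FA values sampled at integer steps ``-cap..cap`` along
    its perpendicular direction (nearest-voxel sampling, clipped at the map
    boundary). A zero direction leaves the voxel's own value.
    """
    fa = np.asarray(fa_map, dtype=float)
    if fa.shape != skeleton.mask.shape:
        raise ValueError("FA map and skeleton grids differ")
    out = np.zeros_like(fa)
    shape = np.array(fa.shape)
    for x, y, z in np.argwhere(skeleton.mask):
        d = skeleton.directions[x, y, z]
        if not np.linalg.norm(d) > 0:
            out[x, y, z] = fa[x, y, z]
            continue
        best = fa[x, y, z]
        for t in range(-search_cap, search_cap + 1):
            p = np.round(np.array([x, y, z]) + t * d).astype(int)
            if (p >= 0).all() and (p < shape).all():
                best = max(best, fa[tuple(p)])
        out[x, y, z] = best
    return out


# ---------------------------------------------------------------------------
# Scan-to-scan head motion
# ---------------------------------------------------------------------------


@dataclass
class MotionTrace:
    """Per-volume scan-to-scan RMS displacement and its mean over DW volumes."""

    rms: np.ndarray  # (n_volumes - 1,) mm, pair (i-1, i) -> entry i-1
    rms_mean: float  # mm
    radius: float  # mm


def rms_between(t0: np.ndarray, t1: np.ndarray, radius: float = 80.0) -> float:
    """Jenkinson-style RMS displacement between two affine transforms.

    With M = T1 T0^{-1} - I, A its 3x3 part and t its translation:
    ``rms = sqrt(R^2/5 * tr(A^T A) + t^T t)``, the RMS displacement of points
    on a sphere of radius R approximating the head.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if abs(np.linalg.det(t0[:3, :3])) < 1e-12 or abs(np.linalg.det(t1[:3, :3])) < 1e-12:
        raise ValueError("singular affine transform")
    m = t1 @ np.linalg.inv(t0) - np.eye(4)
    a = m[:3, :3]
    t = m[:3, 3]
    return float(np.sqrt(radius**2 / 5.0 * np.trace(a.T @ a) + t @ t))


def motion_rms(
    affines: Sequence[np.ndarray],
    radius: float = 80.0,
    dwi_volumes: Optional[Sequence[bool]] = None,
) -> MotionTrace:
    """Scan-to-scan RMS motion from per-volume affine transforms.

    ``dwi_volumes`` flags which volumes are diffusion-weighted (b > 0);
    ``rms_mean`` averages the pairwise values whose *second* volume is
    diffusion-weighted (b=0 volumes excluded from the mean by default
    convention). With no flags, all pairs are averaged.
    """
    affines = [np.asarray(a, dtype=float) for a in affines]
    if len(affines) < 2:
        raise ValueError("need at least two affine transforms")
    values = np.array(
        [rms_between(affines[i - 1], affines[i], radius) for i in range(1, len(affines))]
    )
    if dwi_volumes is None:
        mean = float(values.mean())
    else:
        flags = np.asarray(list(dwi_volumes), dtype=bool)
        if len(flags) != len(affines):
            raise ValueError("dwi_volumes length must match affines")
        sel = flags[1:]
        if not sel.any():
            raise ValueError("no diffusion-weighted volumes to average over")
        mean = float(values[sel].mean())
    return MotionTrace(rms=values, rms_mean=mean, radius=radius)
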