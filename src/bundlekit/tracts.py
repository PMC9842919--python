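"""Voxel ROIs from tracts: rasterization, tract volume, and mean FA.

A tract's ROI is the set of voxels containing at least one streamline
sample; tract volume is the voxel count times the voxel volume, and tract
FA is the arithmetic mean of the FA map over the ROI. Rasterization uses a
voxel-center convention with half-open voxel boxes: voxel ``i`` along an
axis covers ``[i - 0.5, i + 0.5)`` in voxel coordinates, so every mm point
maps to exactly one voxel. Streamline segments are supersampled at a step
of a quarter of the smallest voxel dimension so no crossed voxel is missed
at realistic curvature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class Grid:
    """A voxel grid: shape plus a voxel-to-mm affine (NIfTI convention)."""

    shape: tuple
    affine: np.ndarray  # (4, 4)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        pts = np.asarray(points_mm, dtype=float)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class TractROI:
    """Boolean voxel mask of a tract on a subject grid."""

    mask: np.ndarray
    voxel_volume: float  # mm^3
    name: str = ""

    def __post_init__(self) -> None:
        if self.voxel_volume <= 0:
            raise ValueError("voxel volume must be positive")


def _supersample(points: np.ndarray, step: float) -> np.ndarray:
    """Insert samples along each segment so consecutive samples are <= step apart."""
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / step)))
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.concatenate(out)


def rasterize_tract(
    streamlines: Sequence[np.ndarray],
    grid: Grid,
    name: str = "",
    supersample_factor: float = 0.25,
) -> TractROI:
    """Mark every voxel visited by at least one streamline sample.

    Points outside the grid are ignored with a warning. Membership uses
    half-open boxes: index = floor(voxel_coord + 0.5).
    """
    mask = np.zeros(grid.shape, dtype=bool)
    step = supersample_factor * float(grid.spacing.min())
    clipped = False
    for sl in streamlines:
        pts = np.asarray(sl, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("streamlines must be (m, 3) arrays")
        dense = _supersample(pts, step)
        vox = grid.mm_to_voxel(dense)
        idx = np.floor(vox + 0.5).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
        if not inside.all():
            clipped = True
        idx = idx[inside]
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if clipped:
        warnings.warn("streamline points outside the grid were ignored", stacklevel=2)
    return TractROI(mask=mask, voxel_volume=grid.voxel_volume, name=name)


def tract_volume(roi: TractROI) -> float:
    """Tract volume in mm^3: set-voxel count times voxel volume."""
    return float(roi.mask.sum()) * roi.voxel_volume


def tract_mean_fa(roi: TractROI, fa_map: np.ndarray) -> float:
    """Arithmetic mean FA over the ROI voxels.

    Raises on an empty ROI (the subject/tract is then excluded case-wise,
    matching how dropped tracts are handled at the cohort level).
    """
    fa = np.asarray(fa_map, dtype=float)
    if fa.shape != roi.mask.shape:
        raise ValueError("ROI and FA map grids differ")
    if not roi.mask.any():
        raise ValueError("mean FA of an empty ROI is undefined")
    return float(fa[roi.mask].mean())
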