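"""File I/O: TRK/TCK streamlines, NIfTI volumes, FSL bval/bvec, CSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .clustering import ConsensusSegmentation


def save_streamlines(
    streamlines: Sequence[np.ndarray],
    path: str,
    affine: Optional[np.ndarray] = None,
) -> None:
    """Write streamlines (mm coordinates) as TRK or TCK by file extension."""
    path = str(path)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.endswith(".trk"):
        header = nib.streamlines.trk.TrkFile.create_empty_header()
        header["voxel_to_rasmm"] = affine.astype(np.float32)
        header["voxel_sizes"] = np.linalg.norm(affine[:3, :3], axis=0).astype(
            np.float32
        )
        header["dimensions"] = np.array([1, 1, 1], dtype=np.uint16)
        nib.streamlines.save(tractogram, path, header=header)
    elif path.endswith(".tck"):
        nib.streamlines.save(tractogram, path)
    else:
        raise ValueError("streamline path must end in .trk or .tck")


def load_streamlines(path: str) -> List[np.ndarray]:
    """Read TRK/TCK streamlines into mm-coordinate arrays."""
    obj = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in obj.tractogram.streamlines]


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_nifti(path: str) -> Tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_scheme(bvals: np.ndarray, bvecs: np.ndarray, prefix: str) -> None:
    """FSL-dialect sidecars: one whitespace row of b-values, three of vectors."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    np.savetxt(f"{prefix}.bval", bvals[None], fmt="%.6g")
    np.savetxt(f"{prefix}.bvec", bvecs.T, fmt="%.8g")


def load_scheme(prefix: str) -> Tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(f"{prefix}.bval").ravel()
    bvecs = np.loadtxt(f"{prefix}.bvec")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def save_subject_table(table: pd.DataFrame, path: str) -> None:
    """Subject table CSV: subject_id, sex (M/F), age, icv_ml, per-tract columns."""
    table.to_csv(str(path), index=False)


def load_subject_table(path: str) -> pd.DataFrame:
    return pd.read_csv(str(path))


def save_segmentation(
    segmentation: ConsensusSegmentation,
    subject_ids: Sequence[str],
    path: str,
) -> None:
    """Consensus labels and stabilities: streamline_id,subject_id,label,stability."""
    pd.DataFrame(
        {
            "streamline_id": np.arange(len(segmentation.labels)),
            "subject_id": list(subject_ids),
            "label": segmentation.labels,
            "stability": segmentation.stability,
        }
    ).to_csv(str(path), index=False)
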