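"""Shared containers and file IO for the connectome-asymmetry pipeline.

Coordinate convention used throughout the package: voxel index ``i`` owns the
half-open interval ``[i, i + 1)`` along its axis, the voxel center sits at
``i + 0.5``, and world coordinates (mm) are ``affine @ [vx, vy, vz, 1]``.
Streamline points are always stored in world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabelVolume",
    "ConnectivityMatrix",
    "validate_roi_table",
    "load_roi_table",
    "save_roi_table",
    "load_label_volume",
    "save_streamlines",
    "load_streamlines",
    "streamline_arrays",
]

# TSV float formatting is pinned so that repeated runs of the pipeline emit
# byte-identical output files.
TSV_FLOAT_FORMAT = "%.10g"


@dataclass
class LabelVolume:
    """Integer-labelled 3-D parcellation grid with a voxel-to-world affine.

    ``data`` holds one integer label per voxel (0 = background); ``affine``
    maps homogeneous voxel coordinates to world mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (continuous) to voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        out = pts @ inv[:3, :3].T + inv[:3, 3]
        return out

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(voxels, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        nib.save(img, str(path))


def load_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(np.asarray(img.dataobj).astype(np.int32), img.affine)


# ---------------------------------------------------------------------------
# ROI table
# ---------------------------------------------------------------------------

ROI_COLUMNS = ["id", "name", "hemisphere", "homolog_id", "supratentorial"]


def validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of an ROI table and return it.

    Required columns: id, name, hemisphere ('left'|'right'), homolog_id and a
    boolean ``supratentorial`` flag (cerebellar/infratentorial ROIs are
    excluded from link-wise asymmetry).  The homolog relation must be a
    bijection between hemispheres with homolog(homolog(r)) == r.
    """
    for col in ROI_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"ROI table missing column {col!r}")
    ids = table["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("ROI ids must be unique")
    if not set(table["hemisphere"]) <= {"left", "right"}:
        raise ValueError("hemisphere must be 'left' or 'right'")
    homolog = dict(zip(table["id"], table["homolog_id"]))
    hemi = dict(zip(table["id"], table["hemisphere"]))
    for rid, hid in homolog.items():
        if hid not in homolog:
            raise ValueError(f"homolog {hid} of ROI {rid} not in table")
        if homolog[hid] != rid:
            raise ValueError(f"homolog relation not involutive for ROI {rid}")
        if hemi[hid] == hemi[rid]:
            raise ValueError(f"ROI {rid} and homolog {hid} share a hemisphere")
    return table


def load_roi_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["supratentorial"] = table["supratentorial"].astype(bool)
    return validate_roi_table(table)


def save_roi_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_roi_table(table).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Connectivity matrix
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N nonnegative link-weight matrix keyed to an ROI table.

    ``weights[i, j]`` is the link weight between the ROIs at positions i and j
    of ``roi_ids`` (row/column order).  Self-link (diagonal) weights are kept
    but excluded from asymmetry analysis.
    """

    weights: np.ndarray
    roi_ids: np.ndarray
    roi_table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        n = len(self.roi_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match ROI count")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("connectivity matrix must be symmetric")
        if (self.weights < 0).any():
            raise ValueError("connectivity weights must be nonnegative")
        if n != len(self.roi_table):
            raise ValueError("ROI table size does not match matrix dimension")

    @property
    def n(self) -> int:
        return len(self.roi_ids)

    def index_of(self, roi_id: int) -> int:
        idx = np.flatnonzero(self.roi_ids == roi_id)
        if idx.size == 0:
            raise KeyError(f"ROI {roi_id} not in matrix")
        return int(idx[0])

    def weight(self, roi_a: int, roi_b: int) -> float:
        return float(self.weights[self.index_of(roi_a), self.index_of(roi_b)])

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.weights, index=self.roi_ids, columns=self.roi_ids)
        frame.to_csv(path, sep="\t", index_label="roi", float_format=TSV_FLOAT_FORMAT)

    @classmethod
    def from_tsv(cls, path: str | Path, roi_table: pd.DataFrame) -> "ConnectivityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="roi")
        ids = frame.index.to_numpy()
        return cls(frame.to_numpy(dtype=float), ids, roi_table)


# ---------------------------------------------------------------------------
# Streamline IO (TRK / TCK via nibabel)
# ---------------------------------------------------------------------------


def streamline_arrays(streamlines: Iterable[Sequence]) -> list[np.ndarray]:
    """Coerce to a list of (n_i, 3) float arrays, validating basic invariants."""
    out = []
    for s in streamlines:
        arr = np.asarray(s, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
            raise ValueError("each streamline needs >= 2 points of dimension 3")
        if (np.linalg.norm(np.diff(arr, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive streamline points must be distinct")
        out.append(arr)
    return out


def save_streamlines(
    streamlines: Sequence[np.ndarray],
    path: str | Path,
    affine: np.ndarray,
    shape: tuple[int, int, int],
) -> None:
    """Write streamlines (world mm) as TRK or TCK, chosen by file suffix.

    TRK stores the reference grid (dimensions, voxel sizes, voxel-to-world
    affine) in its header per the trackvis voxel-mm convention; TCK stores
    points directly in world mm.
    """
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(list(streamlines), affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = {
            nib.streamlines.Field.VOXEL_TO_RASMM: np.asarray(affine, dtype=float),
            nib.streamlines.Field.VOXEL_SIZES: np.sqrt(
                (np.asarray(affine)[:3, :3] ** 2).sum(axis=0)
            ),
            nib.streamlines.Field.DIMENSIONS: np.asarray(shape, dtype=np.int16),
        }
        nib.streamlines.save(nib.streamlines.TrkFile(tractogram, header), str(path))
    elif path.suffix == ".tck":
        nib.streamlines.save(nib.streamlines.TckFile(tractogram), str(path))
    else:
        raise ValueError(f"unsupported streamline format: {path.suffix}")


def load_streamlines(path: str | Path) -> list[np.ndarray]:
    """Read a TRK/TCK file; returns streamlines in world mm."""
    tractogram = nib.streamlines.load(str(path)).tractogram
    return [np.asarray(s, dtype=float) for s in tractogram.streamlines]
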