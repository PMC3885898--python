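"""Connectome assembly: endpoint parcellation, link counts, weight correction.

A streamline contributes a link between ROIs i and j iff both of its terminal
points fall inside labelled voxels; streamlines with an endpoint in background
(label 0, or outside the grid) are discarded, and streamlines starting and
ending in the same ROI are recorded on the matrix diagonal but excluded from
link analysis.  Raw counts are then corrected for ROI size and streamline
length (connection-density correction): the weight of link (i, j) is

    w_ij = 2 / (S_i + S_j) * sum_f 1 / l_f

over the kept streamlines f of the link, where S_i is ROI i's surface area
(exposed voxel-face area, mm^2) and l_f the streamline's arc length in mm —
inversely proportional to the summed surfaces of the linked ROIs and to fiber
length, compensating tractography's bias toward large, nearby regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, LabelVolume

__all__ = [
    "LinkStats",
    "assign_endpoints",
    "streamline_length",
    "roi_surface",
    "surface_table",
    "build_matrix",
    "hagmann_correct",
    "apply_gm_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class LinkStats:
    """Per-link bookkeeping produced while building the count matrix."""

    lengths: dict[tuple[int, int], list[float]] = field(default_factory=dict)
    diagonal: dict[int, int] = field(default_factory=dict)
    n_kept: int = 0
    n_self: int = 0
    n_discarded: int = 0

    def add(self, roi_i: int, roi_j: int, length: float) -> None:
        if length <= 0:
            raise ValueError("streamline length must be positive")
        key = (min(roi_i, roi_j), max(roi_i, roi_j))
        self.lengths.setdefault(key, []).append(length)
        self.n_kept += 1

    def count(self, roi_i: int, roi_j: int) -> int:
        key = (min(roi_i, roi_j), max(roi_i, roi_j))
        return len(self.lengths.get(key, ()))

    def mean_length(self, roi_i: int, roi_j: int) -> float:
        key = (min(roi_i, roi_j), max(roi_i, roi_j))
        return float(np.mean(self.lengths[key]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, len(ls), float(np.mean(ls)))
            for (a, b), ls in sorted(self.lengths.items())
        ]
        return pd.DataFrame(rows, columns=["roi_a", "roi_b", "count", "mean_length_mm"])


def _endpoint_label(point: np.ndarray, labels: LabelVolume) -> int:
    """Label of the voxel containing a world-mm point; 0 outside the grid.

    Voxel membership is floor of the inverse-affine coordinate; a coordinate
    exactly on the far boundary of the grid belongs to the last voxel.
    """
    vox = labels.world_to_voxel(point)[0]
    idx = np.floor(vox).astype(int)
    shape = np.asarray(labels.shape)
    on_far_edge = (vox == shape) & (idx == shape)
    idx[on_far_edge] -= 1
    if (idx < 0).any() or (idx >= shape).any():
        logger.debug("endpoint %s outside the volume grid; treated as background", point)
        return 0
    return int(labels.data[tuple(idx)])


def assign_endpoints(
    streamline: np.ndarray, labels: LabelVolume
) -> tuple[int, int] | None:
    """Map a streamline's two terminal points to an ROI pair, or discard.

    Returns (roi_i, roi_j) when both endpoints lie in labelled voxels
    (including i == j for self-links, recorded on the diagonal downstream);
    returns None when either endpoint is in background or off-grid.
    """
    pts = np.asarray(streamline, dtype=float)
    label_i = _endpoint_label(pts[0], labels)
    label_j = _endpoint_label(pts[-1], labels)
    if label_i == 0 or label_j == 0:
        return None
    return label_i, label_j


def streamline_length(streamline: np.ndarray) -> float:
    """Arc length in mm: sum of Euclidean segment lengths."""
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("streamline needs >= 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def roi_surface(labels: LabelVolume, roi_id: int) -> float:
    """Exposed surface area (mm^2) of an ROI in the label grid.

    Counts voxel faces owned by the ROI whose 6-neighbour carries a different
    label (or lies outside the grid), weighting each face by its area from the
    voxel dimensions.
    """
    data = labels.data
    inside = data == roi_id
    if not inside.any():
        raise ValueError(f"ROI {roi_id} not present in the label volume")
    dx, dy, dz = labels.voxel_sizes
    face_areas = (dy * dz, dx * dz, dx * dy)
    total = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(inside, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        lo = np.take(padded, range(0, data.shape[axis]), axis=axis)
        hi = np.take(padded, range(2, data.shape[axis] + 2), axis=axis)
        exposed = int((inside & ~lo).sum()) + int((inside & ~hi).sum())
        total += exposed * area
    return total


def surface_table(labels: LabelVolume, roi_ids: np.ndarray) -> pd.Series:
    """Surface area per ROI id, skipping ROIs absent from the volume (area 0)."""
    values = {}
    for rid in roi_ids:
        rid = int(rid)
        values[rid] = roi_surface(labels, rid) if (labels.data == rid).any() else 0.0
    return pd.Series(values, name="surface_mm2")


def build_matrix(
    streamlines: list[np.ndarray],
    labels: LabelVolume,
    roi_table: pd.DataFrame,
) -> tuple[ConnectivityMatrix, LinkStats]:
    """Count streamlines per ROI pair into a symmetric connectivity matrix.

    The returned matrix holds raw streamline counts (entry A_ij = number of
    streamlines whose endpoints lie in ROIs i and j); self-links go on the
    diagonal and discarded/self/kept totals always sum to the input count.
    """
    roi_ids = np.asarray(roi_table["id"], dtype=int)
    index = {int(rid): k for k, rid in enumerate(roi_ids)}
    n = len(roi_ids)
    counts = np.zeros((n, n), dtype=float)
    stats = LinkStats()
    for s in streamlines:
        pair = assign_endpoints(s, labels)
        if pair is None:
            stats.n_discarded += 1
            continue
        i, j = pair
        if i not in index or j not in index:
            stats.n_discarded += 1
            continue
        if i == j:
            counts[index[i], index[i]] += 1
            stats.diagonal[i] = stats.diagonal.get(i, 0) + 1
            stats.n_self += 1
            continue
        counts[index[i], index[j]] += 1
        counts[index[j], index[i]] += 1
        stats.add(i, j, streamline_length(s))
    assert stats.n_kept + stats.n_self + stats.n_discarded == len(streamlines)
    return ConnectivityMatrix(counts, roi_ids, roi_table), stats


def hagmann_correct(
    raw: ConnectivityMatrix,
    surfaces: pd.Series,
    stats: LinkStats,
) -> ConnectivityMatrix:
    """Correct raw counts for ROI surface and fiber length.

    w_ij = 2/(S_i + S_j) * sum over the link's streamlines of 1/length; links
    with zero count keep weight zero.  A linked ROI with zero surface is an
    error.  The diagonal is carried over unchanged (it is excluded from
    analysis anyway).
    """
    n = raw.n
    weights = np.zeros((n, n), dtype=float)
    for (a, b), lengths in stats.lengths.items():
        s_a = float(surfaces[a])
        s_b = float(surfaces[b])
        if s_a <= 0 or s_b <= 0:
            raise ValueError(f"linked ROI with zero surface in pair ({a}, {b})")
        w = 2.0 / (s_a + s_b) * float(np.sum(1.0 / np.asarray(lengths)))
        ia, ib = raw.index_of(a), raw.index_of(b)
        weights[ia, ib] = weights[ib, ia] = w
    np.fill_diagonal(weights, np.diag(raw.weights))
    return ConnectivityMatrix(weights, raw.roi_ids, raw.roi_table)


def apply_gm_threshold(
    labels: LabelVolume, gm_probability: np.ndarray, threshold: float = 0.5
) -> LabelVolume:
    """Zero out parcel labels where gray-matter probability <= threshold.

    Mirrors intersecting an atlas with a probabilistic gray-matter map,
    keeping only voxels with probability greater than the threshold.
    """
    gm = np.asarray(gm_probability, dtype=float)
    if gm.shape != labels.shape:
        raise ValueError("gray-matter map shape must match the label volume")
    data = labels.data.copy()
    data[gm <= threshold] = 0
    return LabelVolume(data, labels.affine)
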