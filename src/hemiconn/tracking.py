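"""Deterministic FACT streamline propagation and spline filtering.

FACT (fiber assignment by continuous tracking) steps along the principal
diffusion eigenvector of the voxel containing the current point, with no
interpolation.  Propagation is bidirectional from every seed, the eigenvector
sign at each step is chosen to minimise the angular change, and a streamline
terminates when it leaves the tracking mask or when the turning angle between
successive steps exceeds the angle threshold (default 45 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelVolume

__all__ = ["TensorVolume", "TrackingConfig", "seed_points", "fact_track", "spline_filter"]


@dataclass
class TensorVolume:
    """Principal-eigenvector field: one unit 3-vector per voxel inside a mask."""

    evecs: np.ndarray  # (X, Y, Z, 3)
    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray  # voxel -> world mm

    def __post_init__(self) -> None:
        self.evecs = np.asarray(self.evecs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.evecs.ndim != 4 or self.evecs.shape[3] != 3:
            raise ValueError("evecs must have shape (X, Y, Z, 3)")
        if self.mask.shape != self.evecs.shape[:3]:
            raise ValueError("mask shape must match eigenvector grid")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def validate_unit_norm(self, atol: float = 1e-6) -> None:
        norms = np.linalg.norm(self.evecs[self.mask], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=atol):
            bad = int((~np.isclose(norms, 1.0, atol=atol)).sum())
            raise ValueError(f"{bad} masked voxels carry non-unit eigenvectors")


@dataclass
class TrackingConfig:
    """FACT parameters.

    angle_threshold_deg: maximum turning angle between successive steps.
    step_size: propagation step in mm; if None, 0.5 x the smallest voxel
        dimension of the field being tracked.
    min_length: discard streamlines shorter than this (mm).
    seeds_per_voxel: seeds placed per masked voxel (at the voxel center).
    """

    angle_threshold_deg: float = 45.0
    step_size: float | None = None
    min_length: float = 10.0
    seeds_per_voxel: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.angle_threshold_deg < 90:
            raise ValueError("angle_threshold_deg must lie in (0, 90)")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.min_length < 0:
            raise ValueError("min_length must be nonnegative")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")

    def resolved_step(self, voxel_sizes: np.ndarray) -> float:
        if self.step_size is not None:
            return float(self.step_size)
        return 0.5 * float(np.min(voxel_sizes))


def seed_points(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World-mm seed points, one per masked voxel center, in raster order.

    An empty mask yields an empty (0, 3) array, not an error.
    """
    mask = np.asarray(mask, dtype=bool)
    affine = np.asarray(affine, dtype=float)
    vox = np.argwhere(mask).astype(float) + 0.5  # voxel centers, C-raster order
    if vox.size == 0:
        return np.empty((0, 3), dtype=float)
    return vox @ affine[:3, :3].T + affine[:3, 3]


def _voxel_of(point: np.ndarray, inv_affine: np.ndarray) -> np.ndarray:
    vox = inv_affine[:3, :3] @ point + inv_affine[:3, 3]
    return np.floor(vox).astype(int)


def _in_mask(idx: np.ndarray, mask: np.ndarray) -> bool:
    if (idx < 0).any() or (idx >= np.asarray(mask.shape)).any():
        return False
    return bool(mask[tuple(idx)])


def _propagate_half(
    field: TensorVolume,
    inv_affine: np.ndarray,
    start: np.ndarray,
    direction: np.ndarray,
    step: float,
    cos_threshold: float,
) -> list[np.ndarray]:
    """One propagation direction of FACT; returns points including the seed."""
    points = [start.copy()]
    p = start.copy()
    d = direction.copy()
    max_steps = int(4 * np.sum(field.shape) / step * float(np.max(field.voxel_sizes))) + 16
    for _ in range(max_steps):
        idx = _voxel_of(p, inv_affine)
        if not _in_mask(idx, field.mask):
            break
        e = field.evecs[tuple(idx)]
        if float(np.dot(e, d)) < 0:
            e = -e
        if float(np.dot(e, d)) < cos_threshold:
            break  # turning angle exceeds the threshold
        p_next = p + step * e
        idx_next = _voxel_of(p_next, inv_affine)
        if not _in_mask(idx_next, field.mask):
            break
        points.append(p_next)
        p = p_next
        d = e
    return points


def fact_track(field: TensorVolume, cfg: TrackingConfig) -> list[np.ndarray]:
    """Track streamlines from every masked voxel center (FACT propagation).

    Bidirectional: the two half-tracks started along +/- the seed voxel's
    eigenvector are joined at the seed.  Streamlines shorter than
    cfg.min_length (mm of polyline arc length) are discarded.  Output order
    follows raster seed order, so results are deterministic.
    """
    field.validate_unit_norm()
    inv_affine = np.linalg.inv(field.affine)
    step = cfg.resolved_step(field.voxel_sizes)
    cos_threshold = float(np.cos(np.radians(cfg.angle_threshold_deg)))
    streamlines: list[np.ndarray] = []
    seeds = seed_points(field.mask, field.affine)
    for seed in seeds:
        idx = _voxel_of(seed, inv_affine)
        e0 = field.evecs[tuple(idx)]
        forward = _propagate_half(field, inv_affine, seed, e0, step, cos_threshold)
        backward = _propagate_half(field, inv_affine, seed, -e0, step, cos_threshold)
        pts = backward[::-1][:-1] + forward  # seed appears once
        if len(pts) < 2:
            continue
        line = np.asarray(pts)
        if streamline_arc_length(line) >= cfg.min_length:
            streamlines.append(line)
    return streamlines


def streamline_arc_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(points, dtype=float), axis=0), axis=1).sum())


def spline_filter(points: np.ndarray, resample_step: float) -> np.ndarray:
    """Smooth a streamline by cubic-spline resampling along arc length.

    Fits an interpolating spline (cubic where enough points exist)
    parameterised by cumulative chordal arc length and resamples it at
    ``resample_step`` mm.  The two endpoints are preserved exactly.
    """
    from scipy.interpolate import make_interp_spline

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("streamline must be an (n >= 2, 3) array")
    if resample_step <= 0:
        raise ValueError("resample_step must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0])
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("degenerate streamline: all points identical")
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    total = t[-1]
    k = min(3, len(pts) - 1)
    spline = make_interp_spline(t, pts, k=k, axis=0)
    n_out = max(2, int(round(total / resample_step)) + 1)
    ts = np.linspace(0.0, total, n_out)
    out = np.asarray(spline(ts))
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out
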