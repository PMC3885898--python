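"""Digital phantom cohorts with known connectivity and injected asymmetry.

The phantom emulates the study design this package targets: a cohort of
subjects (default 17), a parcellation of 2x45 mirror-symmetric ROIs (labels
1..45 left hemisphere, 46..90 right), and white-matter bundles linking ROI
pairs whose left/right streamline counts carry a configurable asymmetry
index plus between-subject noise.  Every downstream stage (tracking,
connectome assembly, asymmetry statistics, bundle summarisation) can be
exercised against the phantom's ground truth without any external data.

Asymmetry is injected on streamline *counts* (the raw link weight before
surface/length correction): a target asymmetry index delta for a link yields
expected left/right counts ``base * (1 -/+ delta/2)``, so that
``(R - L) / ((R + L) / 2) == delta`` exactly in the noise-free case.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .core import LabelVolume, validate_roi_table
from .tracking import TensorVolume

__all__ = [
    "BundleDef",
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "make_phantom_parcellation",
    "make_phantom_streamlines",
    "make_phantom_tensor_field",
    "subject_link_counts",
    "subject_count_matrix",
    "default_bundle_defs",
    "spec_from_yaml",
    "spec_to_yaml",
]


class PlacementError(ValueError):
    """Raised when the grid cannot hold the requested parcellation."""


class BundleDef(NamedTuple):
    """One homologous bundle, identified by side-free pair ids (1..n_rois/2).

    ``curvature`` is the sagitta (mm) of the circular-arc centerline; 0 means
    a straight bundle.
    """

    roi_a: int
    roi_b: int
    base_count: int
    curvature: float = 0.0


def default_bundle_defs(n_rois: int, base_count: int = 50) -> list[BundleDef]:
    """Disjoint chain pairing (1,2), (3,4), ... among left-hemisphere ids."""
    half = n_rois // 2
    return [BundleDef(a, a + 1, base_count) for a in range(1, half, 2)]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort.

    asymmetry_map maps a side-free link (a, b) to its target asymmetry index
    delta in [-2, 2]; links not listed get delta = 0.  subject_noise_sd is the
    log-scale SD of multiplicative lognormal noise applied independently to
    each side's expected count before rounding.
    """

    grid_shape: tuple[int, int, int] = (24, 15, 12)
    voxel_size: float = 1.0
    n_rois: int = 90
    bundle_defs: list[BundleDef] = dc_field(default_factory=list)
    asymmetry_map: dict[tuple[int, int], float] = dc_field(default_factory=dict)
    subject_noise_sd: float = 0.1
    n_subjects: int = 17
    rng_seed: int = 0
    stray_fraction: float = 0.10
    block_size: int = 2
    gap: int = 1
    tube_radius: float = 1.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be three positive ints")
        if self.grid_shape[0] % 2:
            raise ValueError("grid_shape[0] must be even (mid-sagittal mirror plane)")
        if self.n_rois % 2 or self.n_rois < 2:
            raise ValueError("n_rois must be even and >= 2")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0 <= self.stray_fraction < 1:
            raise ValueError("stray_fraction must be in [0, 1)")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be nonnegative")
        self.bundle_defs = [BundleDef(*b) for b in self.bundle_defs]
        half = self.n_rois // 2
        for b in self.bundle_defs:
            if b.roi_a == b.roi_b:
                raise ValueError(f"bundle {b} must connect two distinct ROIs")
            if not (1 <= b.roi_a <= half and 1 <= b.roi_b <= half):
                raise ValueError(f"bundle {b}: pair ids must lie in 1..{half}")
            if b.base_count < 0:
                raise ValueError(f"bundle {b}: base_count must be >= 0")
        for link, delta in self.asymmetry_map.items():
            if abs(delta) > 2:
                raise ValueError(f"target AI {delta} for link {link} outside [-2, 2]")

    @property
    def half(self) -> int:
        return self.n_rois // 2

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        return aff

    def target_ai(self, roi_a: int, roi_b: int) -> float:
        key = (roi_a, roi_b) if (roi_a, roi_b) in self.asymmetry_map else (roi_b, roi_a)
        return float(self.asymmetry_map.get(key, 0.0))


@dataclass
class GroundTruth:
    """Per-subject generative truth: link counts and the injected AIs."""

    true_matrix: np.ndarray
    true_link_ai: dict[tuple[int, int], float]
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.true_matrix, self.true_matrix.T):
            raise ValueError("true_matrix must be symmetric")
        if (self.true_matrix < 0).any():
            raise ValueError("true_matrix must be nonnegative")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.true_matrix, index=self.roi_ids, columns=self.roi_ids).to_csv(
            path, sep="\t", index_label="roi"
        )


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------


def _block_lattice(spec: PhantomSpec) -> tuple[int, int, int]:
    pitch = spec.block_size + spec.gap
    mid = spec.grid_shape[0] // 2

    def n_along(extent: int) -> int:
        if extent < spec.block_size:
            return 0
        return (extent - spec.block_size) // pitch + 1

    return n_along(mid), n_along(spec.grid_shape[1]), n_along(spec.grid_shape[2])


def _left_block_origin(spec: PhantomSpec, pair_index: int) -> tuple[int, int, int]:
    """Lattice origin (voxel) of left-hemisphere block ``pair_index`` (0-based)."""
    lattice = _block_lattice(spec)
    capacity = int(np.prod(lattice))
    if pair_index >= capacity:
        raise PlacementError(
            f"grid {spec.grid_shape} too small: cannot place ROI {capacity + 1} "
            f"(capacity {capacity} blocks per hemisphere)"
        )
    pitch = spec.block_size + spec.gap
    ia, ib, ic = np.unravel_index(pair_index, lattice)
    return int(ia) * pitch, int(ib) * pitch, int(ic) * pitch


def make_phantom_parcellation(spec: PhantomSpec) -> tuple[LabelVolume, pd.DataFrame]:
    """Build the mirror-symmetric block parcellation and its ROI table.

    Left-hemisphere ROIs get labels 1..n/2 and occupy axis-0 indices below the
    mid-sagittal plane (grid center along axis 0); each right-hemisphere ROI
    (labels n/2+1..n) is the exact mirror image of its homolog, which has
    ``homolog_id = id + n/2``.
    """
    half = spec.half
    X = spec.grid_shape[0]
    b = spec.block_size
    data = np.zeros(spec.grid_shape, dtype=np.int32)
    rows = []
    for k in range(half):
        ox, oy, oz = _left_block_origin(spec, k)
        data[ox : ox + b, oy : oy + b, oz : oz + b] = k + 1
        # mirror across the mid-plane: voxel row i maps to X - 1 - i
        data[X - ox - b : X - ox, oy : oy + b, oz : oz + b] = k + 1 + half
        rows.append((k + 1, f"region{k + 1:02d}_L", "left", k + 1 + half, True))
        rows.append((k + 1 + half, f"region{k + 1:02d}_R", "right", k + 1, True))
    table = pd.DataFrame(
        sorted(rows), columns=["id", "name", "hemisphere", "homolog_id", "supratentorial"]
    )
    return LabelVolume(data, spec.affine), validate_roi_table(table)


def _block_box(spec: PhantomSpec, roi_id: int) -> tuple[np.ndarray, np.ndarray]:
    """World-mm bounding box (lo, hi) of an ROI's block."""
    half = spec.half
    pair = roi_id if roi_id <= half else roi_id - half
    ox, oy, oz = _left_block_origin(spec, pair - 1)
    b = spec.block_size
    if roi_id > half:
        ox = spec.grid_shape[0] - ox - b
    lo = np.array([ox, oy, oz], dtype=float)
    hi = lo + b
    return lo * spec.voxel_size, hi * spec.voxel_size


def _block_center(spec: PhantomSpec, roi_id: int) -> np.ndarray:
    lo, hi = _block_box(spec, roi_id)
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Bundle centerlines
# ---------------------------------------------------------------------------


def _grid_center(spec: PhantomSpec) -> np.ndarray:
    return np.asarray(spec.grid_shape, dtype=float) * spec.voxel_size / 2.0


def _perp_unit(d: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to d."""
    basis = np.eye(3)
    e = basis[np.argmin(np.abs(d))]
    u = np.cross(d, e)
    return u / np.linalg.norm(u)


def _arc_centerline(
    p0: np.ndarray,
    p1: np.ndarray,
    sagitta: float,
    n: int,
    orient_toward: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Points and unit tangents of a circular arc from p0 to p1.

    The arc bulges by ``sagitta`` mm perpendicular to the chord, in the plane
    spanned by the chord and a deterministic normal; when ``orient_toward``
    (a world point, e.g. the grid center) is given, the bulge points toward
    it so phantom arcs stay inside the grid.  sagitta == 0 degenerates to the
    straight segment.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    chord = p1 - p0
    c = np.linalg.norm(chord)
    if c == 0:
        raise ValueError("bundle endpoints coincide")
    d = chord / c
    if sagitta == 0:
        t = np.linspace(0.0, 1.0, n)[:, None]
        pts = p0 + t * chord
        tangents = np.tile(d, (n, 1))
        return pts, tangents
    u = _perp_unit(d)
    if orient_toward is not None:
        toward = np.asarray(orient_toward, dtype=float) - (p0 + p1) / 2
        if float(np.dot(u, toward)) < 0:
            u = -u
    h = float(sagitta)
    r = c**2 / (8 * h) + h / 2  # circle radius from chord length and sagitta
    mid = (p0 + p1) / 2
    center = mid - (r - h) * u
    # angular half-span of the arc
    phi = np.arcsin(min(1.0, c / (2 * r)))
    angles = np.linspace(-phi, phi, n)
    pts = center[None, :] + r * (
        np.outer(np.cos(angles), u) + np.outer(np.sin(angles), d)
    )
    tangents = -np.outer(np.sin(angles), u) + np.outer(np.cos(angles), d)
    return pts, tangents


def _bundle_pairs(spec: PhantomSpec, bundle: BundleDef) -> list[tuple[int, int]]:
    """(left pair, right pair) ROI label tuples for one bundle definition."""
    h = spec.half
    return [(bundle.roi_a, bundle.roi_b), (bundle.roi_a + h, bundle.roi_b + h)]


# ---------------------------------------------------------------------------
# Streamline cohort generation
# ---------------------------------------------------------------------------


def _counts_rng(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.rng_seed), int(subject_index), 0])


def _geometry_rng(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.rng_seed), int(subject_index), 1])


def subject_link_counts(
    spec: PhantomSpec, subject_index: int
) -> dict[tuple[int, int], tuple[int, int]]:
    """Draw (left_count, right_count) per bundle for one subject.

    Expected counts are ``base * (1 - delta/2)`` on the left and
    ``base * (1 + delta/2)`` on the right, each multiplied by independent
    lognormal(0, subject_noise_sd) noise and rounded to an integer.
    Deterministic given (rng_seed, subject_index).
    """
    rng = _counts_rng(spec, subject_index)
    counts: dict[tuple[int, int], tuple[int, int]] = {}
    for bundle in spec.bundle_defs:
        delta = spec.target_ai(bundle.roi_a, bundle.roi_b)
        mean_l = bundle.base_count * (1.0 - delta / 2.0)
        mean_r = bundle.base_count * (1.0 + delta / 2.0)
        if spec.subject_noise_sd > 0:
            mean_l *= rng.lognormal(0.0, spec.subject_noise_sd)
            mean_r *= rng.lognormal(0.0, spec.subject_noise_sd)
        counts[(bundle.roi_a, bundle.roi_b)] = (
            int(round(mean_l)),
            int(round(mean_r)),
        )
    return counts


def subject_count_matrix(
    spec: PhantomSpec, subject_index: int, roi_table: pd.DataFrame
) -> np.ndarray:
    """Ground-truth link-count matrix (n_rois x n_rois) for one subject."""
    n = spec.n_rois
    half = spec.half
    mat = np.zeros((n, n), dtype=np.int64)
    for (a, b), (c_left, c_right) in subject_link_counts(spec, subject_index).items():
        mat[a - 1, b - 1] += c_left
        mat[b - 1, a - 1] += c_left
        mat[a - 1 + half, b - 1 + half] += c_right
        mat[b - 1 + half, a - 1 + half] += c_right
    return mat


def _sample_in_box(rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + rng.random(3) * (hi - lo)


def _polyline(
    p0: np.ndarray,
    p1: np.ndarray,
    curvature: float,
    spacing: float,
    orient_toward: np.ndarray | None = None,
) -> np.ndarray:
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / spacing)) + 1)
    pts, _ = _arc_centerline(p0, p1, curvature, n, orient_toward)
    return pts


def make_phantom_streamlines(
    spec: PhantomSpec,
    subject_index: int,
    parcellation: tuple[LabelVolume, pd.DataFrame] | None = None,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Generate one subject's streamline set plus its generative ground truth.

    Bundle streamlines have both endpoints uniformly sampled inside the two
    linked left-hemisphere ROI blocks; right-hemisphere streamlines are exact
    mirror images (across the mid-sagittal plane) of their left counterparts,
    so that with equal left/right counts the two hemispheres are perfectly
    symmetric — geometry included — and every downstream asymmetry is zero.
    A stray fraction of additional streamlines has at least one endpoint in
    background, to exercise the downstream endpoint-discard rule; strays are
    not counted in ``GroundTruth.true_matrix``.  Deterministic given
    (rng_seed, subject_index).
    """
    if parcellation is None:
        parcellation = make_phantom_parcellation(spec)
    labels, _roi_table = parcellation
    rng = _geometry_rng(spec, subject_index)
    counts = subject_link_counts(spec, subject_index)
    half = spec.half
    n = spec.n_rois
    spacing = spec.voxel_size
    true_matrix = np.zeros((n, n), dtype=np.int64)
    streamlines: list[np.ndarray] = []

    x_extent = spec.grid_shape[0] * spec.voxel_size

    def _mirror(points: np.ndarray) -> np.ndarray:
        out = points.copy()
        out[:, 0] = x_extent - out[:, 0]
        return out

    for bundle in spec.bundle_defs:
        c_left, c_right = counts[(bundle.roi_a, bundle.roi_b)]
        (left_a, left_b), (right_a, right_b) = _bundle_pairs(spec, bundle)
        lo_a, hi_a = _block_box(spec, left_a)
        lo_b, hi_b = _block_box(spec, left_b)
        # one shared pool of left-side geometries; the right bundle reuses
        # mirrored copies so equal counts imply exact hemispheric symmetry
        pool = [
            _polyline(
                _sample_in_box(rng, lo_a, hi_a),
                _sample_in_box(rng, lo_b, hi_b),
                bundle.curvature,
                spacing,
                _grid_center(spec),
            )
            for _ in range(max(c_left, c_right))
        ]
        streamlines.extend(pool[:c_left])
        streamlines.extend(_mirror(line) for line in pool[:c_right])
        for roi_a, roi_b, c_side in (
            (left_a, left_b, c_left),
            (right_a, right_b, c_right),
        ):
            true_matrix[roi_a - 1, roi_b - 1] += c_side
            true_matrix[roi_b - 1, roi_a - 1] += c_side

    # stray streamlines: >= 1 endpoint in background, discarded downstream
    n_stray = int(round(spec.stray_fraction * len(streamlines)))
    if n_stray:
        background = np.argwhere(labels.data == 0)
        if background.size == 0:
            raise ValueError("no background voxels available for stray streamlines")
        extent = np.asarray(spec.grid_shape, dtype=float) * spec.voxel_size
        for _ in range(n_stray):
            vox = background[rng.integers(len(background))]
            e0 = (vox + rng.random(3)) * spec.voxel_size
            e1 = rng.random(3) * extent
            while np.linalg.norm(e1 - e0) < spacing / 2:
                e1 = rng.random(3) * extent
            streamlines.append(_polyline(e0, e1, 0.0, spacing))

    truth = GroundTruth(
        true_matrix=true_matrix,
        true_link_ai={
            (b.roi_a, b.roi_b): spec.target_ai(b.roi_a, b.roi_b)
            for b in spec.bundle_defs
        },
        roi_ids=np.arange(1, n + 1),
    )
    return streamlines, truth


# ---------------------------------------------------------------------------
# Tensor field phantom
# ---------------------------------------------------------------------------


def make_phantom_tensor_field(spec: PhantomSpec) -> TensorVolume:
    """Build a principal-eigenvector field of tube bundles plus its mask.

    Each bundle contributes two tubes (left pair, mirrored right pair) whose
    centerline runs block-center to block-center; inside a tube the
    eigenvector is the unit tangent of the nearest centerline point and the
    white-matter mask is the union of tubes.  Overlapping tubes whose tangents
    disagree by more than 30 degrees raise an error listing the voxels.
    """
    shape = spec.grid_shape
    vs = spec.voxel_size
    evecs = np.zeros(shape + (3,), dtype=float)
    mask = np.zeros(shape, dtype=bool)
    conflicts: list[tuple[int, int, int]] = []
    cos_tol = np.cos(np.radians(30.0))

    grid = np.indices(shape).reshape(3, -1).T  # voxel indices, raster order
    centers = (grid + 0.5) * vs

    for bundle in spec.bundle_defs:
        for roi_a, roi_b in _bundle_pairs(spec, bundle):
            p0 = _block_center(spec, roi_a)
            p1 = _block_center(spec, roi_b)
            n_samples = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / (vs / 4))) + 1)
            pts, tangents = _arc_centerline(
                p0, p1, bundle.curvature, n_samples, _grid_center(spec)
            )
            d2 = ((centers[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            nearest = np.argmin(d2, axis=1)
            inside = np.sqrt(d2[np.arange(len(centers)), nearest]) <= spec.tube_radius * vs
            for flat_idx in np.flatnonzero(inside):
                vox = tuple(grid[flat_idx])
                tan = tangents[nearest[flat_idx]]
                if mask[vox]:
                    if abs(float(np.dot(evecs[vox], tan))) < cos_tol:
                        conflicts.append(vox)
                        continue
                else:
                    mask[vox] = True
                    evecs[vox] = tan

    if conflicts:
        raise ValueError(
            f"overlapping tubes with conflicting tangents at voxels {sorted(set(conflicts))}"
        )
    return TensorVolume(evecs=evecs, mask=mask, affine=spec.affine)


# ---------------------------------------------------------------------------
# YAML round trip for PhantomSpec
# ---------------------------------------------------------------------------


def spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    payload = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size": spec.voxel_size,
        "n_rois": spec.n_rois,
        "bundle_defs": [list(b) for b in spec.bundle_defs],
        "asymmetry_map": {f"{a},{b}": float(d) for (a, b), d in spec.asymmetry_map.items()},
        "subject_noise_sd": spec.subject_noise_sd,
        "n_subjects": spec.n_subjects,
        "rng_seed": spec.rng_seed,
        "stray_fraction": spec.stray_fraction,
        "block_size": spec.block_size,
        "gap": spec.gap,
        "tube_radius": spec.tube_radius,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    payload = yaml.safe_load(Path(path).read_text())
    if "asymmetry_map" in payload:
        payload["asymmetry_map"] = {
            tuple(int(v) for v in key.split(",")): float(val)
            for key, val in payload["asymmetry_map"].items()
        }
    if "grid_shape" in payload:
        payload["grid_shape"] = tuple(payload["grid_shape"])
    return PhantomSpec(**payload)
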