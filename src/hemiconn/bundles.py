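"""Bundle summarisation: one centroid path per link for visualization.

Each link's streamline bundle is reduced to a single representative polyline:
streamlines are oriented consistently (canonically from the lower-id ROI to
the higher-id one), resampled to a fixed number of equally spaced points
along arc length ("serial transverse sections"), and the section-wise mean of
corresponding points — the centroid of each section — is connected in order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import assign_endpoints
from .core import LabelVolume

__all__ = ["BundlePath", "resample_streamline", "bundle_centroid_path", "group_by_link", "paths_to_frame"]


@dataclass
class BundlePath:
    """Centroid polyline summarising one link's streamline bundle."""

    roi_a: int
    roi_b: int
    points: np.ndarray  # (n_sections, 3) world mm
    n_streamlines: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centroid path needs >= 2 points")
        if self.n_streamlines < 1:
            raise ValueError("a bundle path needs >= 1 contributing streamline")


def resample_streamline(streamline: np.ndarray, n_points: int) -> np.ndarray:
    """Resample to n_points equally spaced in cumulative arc length.

    Endpoints are preserved exactly; n_points == 2 returns just the two
    endpoints.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("streamline needs >= 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if seg.sum() == 0:
        raise ValueError("degenerate streamline: zero arc length")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    ts = np.linspace(0.0, t[-1], n_points)
    out = np.column_stack([np.interp(ts, t, pts[:, k]) for k in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def _orient_bundle(
    bundle: list[np.ndarray],
    link: tuple[int, int] | None,
    labels: LabelVolume | None,
) -> list[np.ndarray]:
    """Flip streamlines so all run in the bundle's canonical direction.

    With a label volume the canonical direction is lower ROI id -> higher ROI
    id.  Without labels a geometric fallback is used: the first streamline is
    oriented so its start point is lexicographically smallest of its two
    endpoints, and the rest align to it by endpoint proximity.  Both rules are
    invariant to reversing any input streamline's point order.
    """
    if labels is not None and link is not None:
        lo = min(link)
        oriented = []
        for s in bundle:
            pair = assign_endpoints(s, labels)
            if pair is None or set(pair) != set(link):
                raise ValueError("streamline endpoints do not match the bundle's link")
            oriented.append(s if pair[0] == lo else s[::-1])
        return oriented
    first = bundle[0]
    if tuple(first[-1]) < tuple(first[0]):
        first = first[::-1]
    anchor = first[0]
    oriented = [first]
    for s in bundle[1:]:
        d_start = np.linalg.norm(s[0] - anchor)
        d_end = np.linalg.norm(s[-1] - anchor)
        oriented.append(s if d_start <= d_end else s[::-1])
    return oriented


def bundle_centroid_path(
    bundle: list[np.ndarray],
    n_sections: int = 20,
    link: tuple[int, int] | None = None,
    labels: LabelVolume | None = None,
) -> BundlePath:
    """Mean path of a bundle: section-wise centroid of corresponded points.

    Every streamline is oriented consistently, resampled to ``n_sections``
    arc-length-equidistant points, and section k's centroid is the mean of
    the k-th points across streamlines.
    """
    if not bundle:
        raise ValueError("empty bundle")
    oriented = _orient_bundle(list(bundle), link, labels)
    stack = np.stack([resample_streamline(s, n_sections) for s in oriented])
    centroids = stack.mean(axis=0)
    a, b = link if link is not None else (0, 0)
    lo, hi = (min(a, b), max(a, b)) if link is not None else (0, 0)
    return BundlePath(roi_a=lo, roi_b=hi, points=centroids, n_streamlines=len(bundle))


def group_by_link(
    streamlines: list[np.ndarray], labels: LabelVolume
) -> dict[tuple[int, int], list[np.ndarray]]:
    """Bucket streamlines by their (unordered) endpoint ROI pair.

    Discarded (background-endpoint) and self-link streamlines are skipped.
    """
    bundles: dict[tuple[int, int], list[np.ndarray]] = {}
    for s in streamlines:
        pair = assign_endpoints(s, labels)
        if pair is None or pair[0] == pair[1]:
            continue
        key = (min(pair), max(pair))
        bundles.setdefault(key, []).append(s)
    return bundles


def paths_to_frame(paths: list[BundlePath]) -> pd.DataFrame:
    """Long-format table: one row per (link, section index, x, y, z)."""
    rows = []
    for path in paths:
        for k, (x, y, z) in enumerate(path.points):
            rows.append((path.roi_a, path.roi_b, k, x, y, z, path.n_streamlines))
    return pd.DataFrame(
        rows, columns=["roi_a", "roi_b", "section", "x", "y", "z", "n_streamlines"]
    )
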