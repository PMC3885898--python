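"""End-to-end phantom pipeline: simulate -> track -> connectome -> asymmetry -> bundles.

All tabular outputs are TSV with pinned float formatting, so a fixed
PhantomSpec (including its seed) reproduces byte-identical files run to run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .asymmetry import (
    CohortMatrices,
    link_ai_matrices,
    link_asymmetry_table,
    roi_asymmetry_table,
    save_table,
)
from .bundles import bundle_centroid_path, group_by_link, paths_to_frame
from .connectome import build_matrix, hagmann_correct, surface_table
from .core import TSV_FLOAT_FORMAT, save_roi_table, save_streamlines
from .phantom import PhantomSpec, make_phantom_parcellation, make_phantom_streamlines, make_phantom_tensor_field
from .tracking import TrackingConfig, fact_track, spline_filter

__all__ = ["run_pipeline"]


def run_pipeline(
    spec: PhantomSpec,
    out_dir: str | Path,
    tracking_cfg: TrackingConfig | None = None,
    presence_fraction: float = 0.75,
    n_sections: int = 20,
    write_volumes: bool = False,
) -> dict[str, Path]:
    """Run the whole phantom analysis and write its outputs under out_dir.

    Per subject, streamlines come from the phantom generator and are assembled
    into a surface/length-corrected connectivity matrix; the cohort then
    yields ROI- and link-wise asymmetry tables.  Independently, FACT tracking
    on the phantom's tensor field produces a tracked connectome and the
    per-link centroid bundle paths.  Returns the paths of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    labels, roi_table = make_phantom_parcellation(spec)
    paths["roi_table"] = out / "rois.tsv"
    save_roi_table(roi_table, paths["roi_table"])
    if write_volumes:
        paths["labels"] = out / "labels.nii.gz"
        labels.save(paths["labels"])

    surfaces = surface_table(labels, roi_table["id"].to_numpy())

    subjects, matrices = [], []
    for s in range(spec.n_subjects):
        streamlines, truth = make_phantom_streamlines(spec, s, (labels, roi_table))
        raw, stats = build_matrix(streamlines, labels, roi_table)
        corrected = hagmann_correct(raw, surfaces, stats)
        sid = f"subject{s:02d}"
        subjects.append(sid)
        matrices.append(corrected)
        p = out / f"matrix_{sid}.tsv"
        corrected.to_tsv(p)
        paths[f"matrix_{sid}"] = p

    cohort = CohortMatrices(subjects, matrices)
    paths["roi_asymmetry"] = out / "roi_asymmetry.tsv"
    save_table(roi_asymmetry_table(cohort), paths["roi_asymmetry"])
    paths["link_asymmetry"] = out / "link_asymmetry.tsv"
    save_table(link_asymmetry_table(cohort, presence_fraction), paths["link_asymmetry"])
    for key, frame in link_ai_matrices(cohort, presence_fraction).items():
        p = out / f"link_{key}_matrix.tsv"
        frame.to_csv(p, sep="\t", index_label="pair", float_format=TSV_FLOAT_FORMAT)
        paths[f"link_{key}_matrix"] = p

    # tracked route: FACT on the phantom eigenvector field, then bundles
    if spec.bundle_defs:
        field = make_phantom_tensor_field(spec)
        cfg = tracking_cfg or TrackingConfig(min_length=2.0)
        tracked = fact_track(field, cfg)
        step = cfg.resolved_step(field.voxel_sizes)
        tracked = [spline_filter(s, step) for s in tracked]
        if write_volumes and tracked:
            paths["tracked_trk"] = out / "tracked.trk"
            save_streamlines(tracked, paths["tracked_trk"], spec.affine, spec.grid_shape)
        raw, _stats = build_matrix(tracked, labels, roi_table)
        paths["tracked_matrix"] = out / "tracked_matrix.tsv"
        raw.to_tsv(paths["tracked_matrix"])
        bundles = group_by_link(tracked, labels)
        centroid_paths = [
            bundle_centroid_path(b, n_sections, link=key, labels=labels)
            for key, b in sorted(bundles.items())
        ]
        frame = paths_to_frame(centroid_paths)
        paths["bundle_paths"] = out / "bundle_paths.tsv"
        frame.to_csv(
            paths["bundle_paths"], sep="\t", index=False, float_format=TSV_FLOAT_FORMAT
        )
    return paths
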