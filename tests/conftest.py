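import numpy as np
import pytest

import hemiconn as hc
from hemiconn.asymmetry import CohortMatrices
from hemiconn.core import ConnectivityMatrix


@pytest.fixture(scope="session")
def small_spec() -> hc.PhantomSpec:
    """Four-ROI phantom with one leftward-asymmetric bundle."""
    return hc.PhantomSpec(
        n_rois=4,
        grid_shape=(20, 10, 10),
        bundle_defs=[hc.BundleDef(1, 2, 50, 0.0)],
        asymmetry_map={(1, 2): -0.5},
        subject_noise_sd=0.1,
        n_subjects=5,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_parcellation(small_spec):
    return hc.make_phantom_parcellation(small_spec)


def build_cohort(spec: hc.PhantomSpec, parcellation=None, correct=True) -> CohortMatrices:
    """Generate the full cohort of (optionally corrected) matrices for a spec."""
    if parcellation is None:
        parcellation = hc.make_phantom_parcellation(spec)
    labels, roi_table = parcellation
    surfaces = hc.surface_table(labels, roi_table["id"].to_numpy()) if correct else None
    matrices = []
    for s in range(spec.n_subjects):
        streamlines, _ = hc.make_phantom_streamlines(spec, s, parcellation)
        raw, stats = hc.build_matrix(streamlines, labels, roi_table)
        matrices.append(hc.hagmann_correct(raw, surfaces, stats) if correct else raw)
    return CohortMatrices([f"subject{s:02d}" for s in range(spec.n_subjects)], matrices)


def count_cohort(spec: hc.PhantomSpec, roi_table) -> CohortMatrices:
    """Cohort of ground-truth count matrices (no streamline geometry)."""
    ids = roi_table["id"].to_numpy()
    mats = [
        ConnectivityMatrix(
            hc.subject_count_matrix(spec, s, roi_table).astype(float), ids, roi_table
        )
        for s in range(spec.n_subjects)
    ]
    return CohortMatrices([f"subject{s:02d}" for s in range(spec.n_subjects)], mats)


def turning_angles_deg(streamline: np.ndarray) -> np.ndarray:
    """Interior turning angles of a polyline, in degrees."""
    v = np.diff(np.asarray(streamline, dtype=float), axis=0)
    v = v / np.linalg.norm(v, axis=1)[:, None]
    cosang = np.clip((v[:-1] * v[1:]).sum(axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))
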