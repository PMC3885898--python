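"""Asymmetry indices, ROI strengths, presence filter, and one-sample t-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hemiconn as hc
from hemiconn.asymmetry import (
    CohortMatrices,
    UndefinedAsymmetry,
    UntestableSample,
    asymmetry_index,
    link_ai_matrices,
    link_asymmetry_table,
    one_sample_t,
    p_from_t,
    roi_asymmetry_table,
    roi_strength,
    swap_hemispheres,
)
from hemiconn.core import ConnectivityMatrix

from conftest import build_cohort, count_cohort


def roi_table_6():
    rows = [
        (1, "a_L", "left", 4, True),
        (2, "b_L", "left", 5, True),
        (3, "c_L", "left", 6, True),
        (4, "a_R", "right", 1, True),
        (5, "b_R", "right", 2, True),
        (6, "c_R", "right", 3, True),
    ]
    return pd.DataFrame(rows, columns=["id", "name", "hemisphere", "homolog_id", "supratentorial"])


def matrix_from(weights, table):
    return ConnectivityMatrix(np.asarray(weights, dtype=float), table["id"].to_numpy(), table)


class TestAsymmetryIndex:
    @pytest.mark.parametrize(
        "left,right,expected",
        [(1.0, 1.0, 0.0), (1.0, 0.0, -2.0), (0.0, 1.0, 2.0), (1.0, 0.9, -0.10526315789473684)],
    )
    def test_values(self, left, right, expected):
        assert asymmetry_index(left, right) == pytest.approx(expected, abs=1e-12)

    def test_undefined_for_double_zero(self):
        with pytest.raises(UndefinedAsymmetry):
            asymmetry_index(0.0, 0.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(-1.0, 2.0)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            l, r = rng.random(2) * 10
            if l + r:
                assert -2.0 <= asymmetry_index(l, r) <= 2.0


class TestRoiStrength:
    def test_only_homolog_link_gives_zero(self):
        table = roi_table_6()
        w = np.zeros((6, 6))
        w[0, 3] = w[3, 0] = 5.0  # ROI 1 <-> its homolog 4
        assert roi_strength(matrix_from(w, table), 1) == 0.0

    def test_single_offdiagonal_link(self):
        table = roi_table_6()
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 2.5
        assert roi_strength(matrix_from(w, table), 1) == 2.5

    def test_matches_bruteforce(self):
        table = roi_table_6()
        rng = np.random.default_rng(4)
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        m = matrix_from(w, table)
        for rid in table["id"]:
            i = int(rid) - 1
            hom = int(table.loc[table["id"] == rid, "homolog_id"].iloc[0]) - 1
            expected = sum(w[i, j] for j in range(6) if j not in (i, hom))
            assert roi_strength(m, rid) == pytest.approx(expected)

    def test_unknown_roi(self):
        with pytest.raises(KeyError):
            roi_strength(matrix_from(np.zeros((6, 6)), roi_table_6()), 99)


class TestOneSampleT:
    def test_zero_mean_symmetric_sample(self):
        t, df, p = one_sample_t(np.array([-1.0, 0.0, 1.0]))
        assert t == 0.0 and df == 2 and p == 1.0

    def test_constant_nonzero_sample_untestable(self):
        with pytest.raises(UntestableSample):
            one_sample_t(np.array([0.3, 0.3, 0.3]))

    def test_all_zero_sample_is_null(self):
        t, df, p = one_sample_t(np.zeros(5))
        assert t == 0.0 and p == 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(0.2, 1.0, size=rng.integers(3, 30))
            t, df, p = one_sample_t(x)
            ref = sps.ttest_1samp(x, 0.0)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestPfromT:
    def test_zero_t(self):
        assert p_from_t(0.0, 16) == 1.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)

    def test_monotone_in_abs_t(self):
        ps = [p_from_t(t, 16) for t in np.linspace(0, 6, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_sign_invariant(self):
        assert p_from_t(2.5, 10) == p_from_t(-2.5, 10)

    def test_matches_numerical_integration(self):
        from scipy.integrate import quad

        for df in (1, 4, 16, 40):
            for t in (0.5, 2.0, 5.0):
                tail, _ = quad(lambda x: sps.t.pdf(x, df), t, np.inf)
                assert p_from_t(t, df) == pytest.approx(2 * tail, abs=1e-10)


class TestRoiAsymmetryTable:
    def test_mirrored_cohort_all_null(self):
        spec = hc.PhantomSpec(
            n_rois=6,
            grid_shape=(24, 15, 12),
            bundle_defs=[hc.BundleDef(1, 2, 20, 0.0), hc.BundleDef(2, 3, 10, 0.0)],
            subject_noise_sd=0.0,
            n_subjects=3,
        )
        _, table = hc.make_phantom_parcellation(spec)
        out = roi_asymmetry_table(count_cohort(spec, table))
        testable = out[out["n"] > 0]
        assert (testable["mean_ai"] == 0.0).all()
        assert (testable["t"] == 0.0).all()
        assert (testable["p"] == 1.0).all()

    def test_one_record_per_homologous_pair(self):
        spec = hc.PhantomSpec(n_rois=90, bundle_defs=[hc.BundleDef(1, 2, 5, 0.0)], n_subjects=2)
        _, table = hc.make_phantom_parcellation(spec)
        out = roi_asymmetry_table(count_cohort(spec, table))
        assert len(out) == 45

    def test_injected_leftward_asymmetry_detected(self, small_spec, small_parcellation):
        cohort = build_cohort(small_spec, small_parcellation)
        out = roi_asymmetry_table(cohort)
        involved = out[out["pair_id"].isin([1, 2])]
        assert (involved["mean_ai"] < 0).all()  # delta = -0.5 -> leftward

    def test_unusable_pairs_flagged_not_dropped(self):
        spec = hc.PhantomSpec(n_rois=6, bundle_defs=[hc.BundleDef(1, 2, 10, 0.0)], n_subjects=2)
        _, table = hc.make_phantom_parcellation(spec)
        out = roi_asymmetry_table(count_cohort(spec, table))
        assert len(out) == 3  # pair 3 has no links but still gets a record
        pair3 = out[out["pair_id"] == 3].iloc[0]
        assert pair3["untestable"] and pair3["n"] == 0


class TestLinkAsymmetryTable:
    def make_cohort(self, presence_counts, n_subjects=17):
        """Cohort where link (1,2) appears in presence_counts[0] subjects etc."""
        table = roi_table_6()
        mats = []
        for s in range(n_subjects):
            w = np.zeros((6, 6))
            if s < presence_counts[0]:
                w[0, 1] = w[1, 0] = 1.0  # left link of unit (a=1, b=2)
            if s < presence_counts[1]:
                w[1, 2] = w[2, 1] = 2.0 + s  # left link of unit (2, 3)
                w[4, 5] = w[5, 4] = 1.0
            mats.append(matrix_from(w, table))
        return CohortMatrices([f"s{i}" for i in range(n_subjects)], mats)

    def test_threshold_thirteen_of_seventeen(self):
        assert math.ceil(0.75 * 17) == 13
        cohort = self.make_cohort([13, 12])
        out = link_asymmetry_table(cohort, 0.75)
        units = {(int(r["pair_a"]), int(r["pair_b"])) for _, r in out.iterrows()}
        assert (1, 2) in units  # tracked in exactly 13 subjects: kept
        assert (2, 3) not in units  # tracked in 12 subjects: excluded

    def test_presence_fraction_validation(self):
        cohort = self.make_cohort([17, 17])
        with pytest.raises(ValueError):
            link_asymmetry_table(cohort, 0.0)
        with pytest.raises(ValueError):
            link_asymmetry_table(cohort, 1.2)

    def test_presence_monotonicity(self, small_spec, small_parcellation):
        cohort = build_cohort(small_spec, small_parcellation)
        kept = []
        for frac in (0.2, 0.5, 0.8, 1.0):
            out = link_asymmetry_table(cohort, frac)
            kept.append({(int(r["pair_a"]), int(r["pair_b"])) for _, r in out.iterrows()})
        for smaller, larger in zip(kept[1:], kept[:-1]):
            assert smaller <= larger

    def test_link_matrix_45x45(self):
        spec = hc.PhantomSpec(n_rois=90, bundle_defs=[hc.BundleDef(1, 2, 20, 0.0)], n_subjects=3)
        _, table = hc.make_phantom_parcellation(spec)
        frames = link_ai_matrices(count_cohort(spec, table), 0.75)
        assert frames["mean_ai"].shape == (45, 45)
        assert frames["t"].shape == (45, 45)

    def test_non_supratentorial_rois_excluded(self):
        table = roi_table_6()
        table.loc[table["id"].isin([3, 6]), "supratentorial"] = False
        mats = []
        for s in range(4):
            w = np.zeros((6, 6))
            w[0, 1] = w[1, 0] = 1.0 + s
            w[3, 4] = w[4, 3] = 1.5
            w[1, 2] = w[2, 1] = 1.0  # involves the infratentorial pair
            mats.append(matrix_from(w, table))
        cohort = CohortMatrices(list("abcd"), mats)
        out = link_asymmetry_table(cohort, 0.5)
        assert set(out["pair_a"]) | set(out["pair_b"]) <= {1, 2}

    def test_ai_bounds(self, small_spec, small_parcellation):
        cohort = build_cohort(small_spec, small_parcellation)
        out = link_asymmetry_table(cohort, 0.5)
        assert out["mean_ai"].abs().max() <= 2.0
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()


class TestHemisphereSwapAntisymmetry:
    def test_roi_and_link_tables_negate(self, small_spec, small_parcellation):
        cohort = build_cohort(small_spec, small_parcellation)
        swapped = CohortMatrices(
            cohort.subjects, [swap_hemispheres(m) for m in cohort.matrices]
        )
        for fn in (roi_asymmetry_table, link_asymmetry_table):
            a = fn(cohort).sort_index(axis=0)
            b = fn(swapped).sort_index(axis=0)
            key = ["pair_id"] if "pair_id" in a.columns else ["pair_a", "pair_b"]
            a = a.sort_values(key).reset_index(drop=True)
            b = b.sort_values(key).reset_index(drop=True)
            assert np.allclose(a["mean_ai"], -b["mean_ai"], atol=1e-12)
            assert np.allclose(a["t"].fillna(0), -b["t"].fillna(0), atol=1e-9)
            assert np.allclose(a["p"].fillna(-1), b["p"].fillna(-1), atol=1e-9)
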