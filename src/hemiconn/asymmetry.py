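"""Hemispheric asymmetry of connectome weights: AI computation and t-tests.

The asymmetry index of a left/right weight pair is

    AI = (R - L) / ((R + L) / 2),

bounded in [-2, 2]; negative values mean leftward dominance, positive values
rightward.  ROI-level asymmetry compares the connectivity strength of each
ROI (sum of its link weights, excluding the self-link and the link to its
contralateral homolog) with that of its homolog.  Link-level asymmetry
compares each intra-hemispheric link with the homologous link in the opposite
hemisphere, restricted to supratentorial ROIs and to links tracked in more
than a presence fraction (default 75%) of subjects.  Each unit's AI sample
across subjects is tested against zero with a two-tailed one-sample t-test.

No multiple-comparison correction is applied to the reported p values; a
Benjamini-Hochberg column (``p_fdr_bh``) is emitted alongside as a clearly
labelled extension for users who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConnectivityMatrix, TSV_FLOAT_FORMAT, validate_roi_table

__all__ = [
    "UndefinedAsymmetry",
    "UntestableSample",
    "CohortMatrices",
    "asymmetry_index",
    "roi_strength",
    "one_sample_t",
    "p_from_t",
    "roi_asymmetry_table",
    "link_asymmetry_table",
    "link_ai_matrices",
    "swap_hemispheres",
    "save_table",
]


class UndefinedAsymmetry(ValueError):
    """AI is undefined when both hemispheres carry zero weight."""


class UntestableSample(ValueError):
    """One-sample t-test is undefined (n < 2 or zero sample variance)."""


@dataclass
class CohortMatrices:
    """Ordered per-subject corrected connectivity matrices on one ROI table."""

    subjects: list[str]
    matrices: list[ConnectivityMatrix]

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.matrices):
            raise ValueError("one matrix per subject required")
        if len(self.matrices) < 2:
            raise ValueError("a cohort needs >= 2 subjects")
        ref = self.matrices[0]
        for m in self.matrices[1:]:
            if not np.array_equal(m.roi_ids, ref.roi_ids):
                raise ValueError("all cohort matrices must share one ROI ordering")
        validate_roi_table(ref.roi_table)

    @property
    def roi_table(self) -> pd.DataFrame:
        return self.matrices[0].roi_table

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)


def asymmetry_index(left: float, right: float) -> float:
    """(R - L) / ((R + L) / 2); negative = leftward, positive = rightward."""
    if left < 0 or right < 0:
        raise ValueError("weights must be nonnegative")
    if left + right == 0:
        raise UndefinedAsymmetry("AI undefined for L = R = 0")
    return (right - left) / ((right + left) / 2.0)


def roi_strength(matrix: ConnectivityMatrix, roi_id: int) -> float:
    """Sum of an ROI's link weights, excluding self and contralateral homolog.

    Ipsilateral and contralateral (inter-hemispheric) links all contribute;
    only the diagonal entry and the link to the ROI's own homolog are
    discarded.
    """
    table = matrix.roi_table
    row_sel = table["id"] == roi_id
    if not row_sel.any():
        raise KeyError(f"unknown ROI {roi_id}")
    homolog = int(table.loc[row_sel, "homolog_id"].iloc[0])
    i = matrix.index_of(roi_id)
    total = float(matrix.weights[i].sum())
    total -= float(matrix.weights[i, i])
    total -= float(matrix.weights[i, matrix.index_of(homolog)])
    return total


def one_sample_t(values: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed one-sample t-test of the sample mean against zero.

    Returns (t, df, p) with t = mean / (sd / sqrt(n)), df = n - 1.  Raises
    UntestableSample for n < 2 or zero sample variance.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise UntestableSample(f"need >= 2 samples, got {n}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        if float(np.mean(x)) == 0:
            # degenerate sample exactly at the null: no evidence against it
            return 0.0, n - 1, 1.0
        raise UntestableSample("zero sample variance")
    t = float(np.mean(x) / (sd / math.sqrt(n)))
    return t, n - 1, p_from_t(t, n - 1)


def p_from_t(t: float, df: int) -> float:
    """Two-tailed tail mass 2 P(T_df >= |t|) of Student's t."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sps.t.sf(abs(t), df))


def _benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    from statsmodels.stats.multitest import multipletests

    out = pd.Series(np.nan, index=p_values.index)
    testable = p_values.notna()
    if testable.any():
        out[testable] = multipletests(p_values[testable], method="fdr_bh")[1]
    return out


def _ordered(table: pd.DataFrame) -> pd.DataFrame:
    """Leftward (negative mean AI) block first, p ascending within each block."""
    table = table.copy()
    table["_sign"] = np.where(table["mean_ai"] < 0, 0, 1)
    table["_p"] = table["p"].fillna(np.inf)
    table = table.sort_values(["_sign", "_p"], kind="mergesort")
    return table.drop(columns=["_sign", "_p"]).reset_index(drop=True)


def _homolog_pairs(roi_table: pd.DataFrame) -> pd.DataFrame:
    """One row per homologous pair: side-free pair index, left id, right id."""
    left = roi_table[roi_table["hemisphere"] == "left"].sort_values("id")
    rows = [
        (k + 1, int(r["id"]), int(r["homolog_id"]), r["name"], bool(r["supratentorial"]))
        for k, (_, r) in enumerate(left.iterrows())
    ]
    return pd.DataFrame(
        rows, columns=["pair_id", "left_id", "right_id", "name", "supratentorial"]
    )


def roi_asymmetry_table(cohort: CohortMatrices) -> pd.DataFrame:
    """Per homologous ROI pair: AI distribution across subjects and its t-test.

    Subjects where both hemispheres have zero strength for the pair are
    excluded (AI undefined); pairs left with fewer than two usable subjects or
    zero variance are flagged untestable rather than dropped.
    """
    pairs = _homolog_pairs(cohort.roi_table)
    records = []
    for _, pair in pairs.iterrows():
        ais = []
        for m in cohort.matrices:
            left = roi_strength(m, pair["left_id"])
            right = roi_strength(m, pair["right_id"])
            if left + right > 0:
                ais.append(asymmetry_index(left, right))
        t = df = p = np.nan
        untestable = True
        if len(ais) >= 2:
            try:
                t, df, p = one_sample_t(np.asarray(ais))
                untestable = False
            except UntestableSample:
                pass
        records.append(
            {
                "pair_id": int(pair["pair_id"]),
                "name": pair["name"],
                "n": len(ais),
                "mean_ai": float(np.mean(ais)) if ais else np.nan,
                "t": t,
                "df": df,
                "p": p,
                "untestable": untestable,
            }
        )
    table = pd.DataFrame(records)
    table["p_fdr_bh"] = _benjamini_hochberg(table["p"])
    return _ordered(table)


def link_asymmetry_table(
    cohort: CohortMatrices, presence_fraction: float = 0.75
) -> pd.DataFrame:
    """Per intra-hemispheric link: AI across subjects, presence filter, t-test.

    Candidate units are unordered side-free pairs (a, b) of supratentorial
    homologous-pair indices; a unit is "tracked" in a subject iff the left or
    right realisation of the link has nonzero weight, and units tracked in
    fewer than ceil(presence_fraction * n_subjects) subjects are excluded.
    """
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must lie in (0, 1]")
    pairs = _homolog_pairs(cohort.roi_table)
    pairs = pairs[pairs["supratentorial"]].reset_index(drop=True)
    threshold = math.ceil(presence_fraction * cohort.n_subjects)
    records = []
    for ka in range(len(pairs)):
        for kb in range(ka + 1, len(pairs)):
            pa, pb = pairs.iloc[ka], pairs.iloc[kb]
            ais = []
            for m in cohort.matrices:
                left = m.weight(int(pa["left_id"]), int(pb["left_id"]))
                right = m.weight(int(pa["right_id"]), int(pb["right_id"]))
                if left + right > 0:
                    ais.append(asymmetry_index(left, right))
            if len(ais) < threshold:
                continue
            t = df = p = np.nan
            untestable = True
            if len(ais) >= 2:
                try:
                    t, df, p = one_sample_t(np.asarray(ais))
                    untestable = False
                except UntestableSample:
                    pass
            records.append(
                {
                    "pair_a": int(pa["pair_id"]),
                    "pair_b": int(pb["pair_id"]),
                    "name_a": pa["name"],
                    "name_b": pb["name"],
                    "n": len(ais),
                    "mean_ai": float(np.mean(ais)),
                    "t": t,
                    "df": df,
                    "p": p,
                    "untestable": untestable,
                }
            )
    table = pd.DataFrame(
        records,
        columns=[
            "pair_a",
            "pair_b",
            "name_a",
            "name_b",
            "n",
            "mean_ai",
            "t",
            "df",
            "p",
            "untestable",
        ],
    )
    table["p_fdr_bh"] = _benjamini_hochberg(table["p"])
    return _ordered(table) if len(table) else table


def link_ai_matrices(
    cohort: CohortMatrices, presence_fraction: float = 0.75
) -> dict[str, pd.DataFrame]:
    """Symmetric side-free matrices (mean AI, T, p, n) over homologous pairs.

    Rows/columns are side-free pair ids (one per homologous ROI pair,
    supratentorial only); cells of excluded or untestable links hold NaN.
    """
    pairs = _homolog_pairs(cohort.roi_table)
    pairs = pairs[pairs["supratentorial"]]
    ids = pairs["pair_id"].to_numpy()
    table = link_asymmetry_table(cohort, presence_fraction)
    frames = {
        key: pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
        for key in ("mean_ai", "t", "p", "n")
    }
    for _, row in table.iterrows():
        a, b = int(row["pair_a"]), int(row["pair_b"])
        for key in frames:
            frames[key].loc[a, b] = row[key]
            frames[key].loc[b, a] = row[key]
    return frames


def swap_hemispheres(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Relabel every ROI as its contralateral homolog (left/right swap)."""
    table = matrix.roi_table
    homolog = dict(zip(table["id"], table["homolog_id"]))
    perm = np.array([matrix.index_of(homolog[int(r)]) for r in matrix.roi_ids])
    weights = matrix.weights[np.ix_(perm, perm)]
    return ConnectivityMatrix(weights, matrix.roi_ids, table)


def save_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=TSV_FLOAT_FORMAT)
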