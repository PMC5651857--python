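"""Per-miRNA confirmation statistics and cohort comparisons.

Candidates from the array screen are confirmed on individual-sample
qPCR expression: an assay survives only if it is detected in at least
``min_detection`` of samples, differs significantly between AAAD+ and
AAAD- (two-sided t-test, p < alpha), and changes in the same direction
as in the screen — in the overall contrast and in the hypertensive
stratum, in every phase tested (the parallel-trend requirement).

Also provides Table-1-style demographics: Student's t on continuous
covariates, uncorrected Pearson chi-square on binary ones.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import PHASES, SampleMetadata
from .qpcr import ExpressionMatrix, detection_rate
from .screening import CandidateSet

RESULT_COLUMNS = [
    "assay_id",
    "phase",
    "contrast",
    "n_case",
    "n_control",
    "mean_case",
    "mean_control",
    "sd_case",
    "sd_control",
    "fc",
    "t",
    "p",
    "p_adj",
    "direction",
    "detection_rate",
    "kept",
    "drop_reason",
]


def t_test_groups(
    values_a: Sequence[float], values_b: Sequence[float], variant: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test on raw values.

    ``student`` pools variance (df = n_a + n_b - 2); ``welch`` does not.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant: {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def t_test_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variant: str = "student",
) -> tuple[float, float]:
    """Two-sided t-test from group summary statistics (mean, SD, n)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant: {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "student")
    )
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Raises on a zero row or column margin (statistic undefined).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be >= 0")
    if table.sum() < 1:
        raise ValueError("table total must be >= 1")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def cohort_comparison(
    meta: pd.DataFrame,
    group_col: str = "aaad",
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
) -> pd.DataFrame:
    """Demographics table comparing the two levels of ``group_col``.

    Continuous covariates get Student's t (mean +/- SD per group);
    binary covariates get an uncorrected chi-square on the 2x2 counts.
    Variables with a zero margin are reported with p = NaN, matching the
    dash convention of clinical tables.
    """
    cases = meta[meta[group_col].astype(bool)]
    controls = meta[~meta[group_col].astype(bool)]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("each group needs n >= 2")
    rows = []
    for var in continuous:
        t, p = t_test_groups(cases[var], controls[var], variant="student")
        rows.append(
            {
                "variable": var,
                "test": "t",
                "case_summary": f"{cases[var].mean():.2f} +/- {cases[var].std(ddof=1):.2f}",
                "control_summary": f"{controls[var].mean():.2f} +/- {controls[var].std(ddof=1):.2f}",
                "statistic": t,
                "p": p,
            }
        )
    for var in binary:
        a = int(cases[var].astype(bool).sum())
        b = int(len(cases) - a)
        c = int(controls[var].astype(bool).sum())
        d = int(len(controls) - c)
        try:
            stat, p = chi2_2x2(a, b, c, d)
        except ValueError:
            stat, p = float("nan"), float("nan")
        rows.append(
            {
                "variable": var,
                "test": "chi2",
                "case_summary": str(a),
                "control_summary": str(c),
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _contrast_row(
    matrix: ExpressionMatrix,
    assay: str,
    case_ids: list[str],
    control_ids: list[str],
    variant: str,
) -> dict:
    case = matrix.assay_values(assay, case_ids, detected_only=True)
    control = matrix.assay_values(assay, control_ids, detected_only=True)
    row = {
        "n_case": int(case.size),
        "n_control": int(control.size),
        "mean_case": float(case.mean()) if case.size else float("nan"),
        "mean_control": float(control.mean()) if control.size else float("nan"),
        "sd_case": float(case.std(ddof=1)) if case.size > 1 else float("nan"),
        "sd_control": float(control.std(ddof=1)) if control.size > 1 else float("nan"),
    }
    if case.size >= 2 and control.size >= 2:
        # relative expression is log-normal; test on the log2 (dCt) scale
        lcase, lcontrol = np.log2(case), np.log2(control)
        t, p = t_test_groups(lcase, lcontrol, variant=variant)
        log2fc = float(lcase.mean() - lcontrol.mean())
        row.update(
            t=t, p=p, fc=float(2.0**log2fc), direction=1 if log2fc >= 0 else -1
        )
    else:
        row.update(t=float("nan"), p=float("nan"), fc=float("nan"), direction=0)
    return row


def _mean_log2(matrix: ExpressionMatrix, assay: str, ids: list[str]) -> float:
    vals = matrix.assay_values(assay, ids, detected_only=True)
    return float(np.log2(vals).mean()) if vals.size else float("nan")


def _parallel_trend(
    matrix: ExpressionMatrix,
    assay: str,
    direction: int,
    hp_case: list[str],
    hn_case: list[str],
    hp_control: list[str],
    hn_control: list[str],
) -> bool:
    # the three array-screen contrasts, on per-sample group means:
    # each AAAD+ group vs the pooled AAAD- reference, and the HPT+
    # stratum contrast; all must move in the candidate's direction
    ref = 0.5 * (
        _mean_log2(matrix, assay, hn_control) + _mean_log2(matrix, assay, hp_control)
    )
    diffs = (
        _mean_log2(matrix, assay, hp_case) - ref,
        _mean_log2(matrix, assay, hn_case) - ref,
        _mean_log2(matrix, assay, hp_case) - _mean_log2(matrix, assay, hp_control),
    )
    return all(np.isfinite(d) and (1 if d >= 0 else -1) == direction for d in diffs)


def confirm_candidates(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    candidates: CandidateSet,
    alpha: float = 0.05,
    min_detection: float = 0.75,
    variant: str = "student",
) -> pd.DataFrame:
    """Confirm screened candidates on per-sample expression, phase by phase.

    Returns one row per (assay, phase, contrast) with group statistics,
    raw and Benjamini-Hochberg-adjusted p values, plus assay-level
    ``kept`` and ``drop_reason`` columns (empty reason when kept).

    An assay is kept when, in every phase tested, (a) its detection rate
    is at least ``min_detection``, (b) the overall AAAD+ vs AAAD- t-test
    has raw p < alpha, and (c) the parallel-trend requirement holds: the
    same three group contrasts used by the array screen (each AAAD+
    group vs the pooled AAAD- reference, and HPT+/AAAD+ vs HPT+/AAAD-)
    all move in the candidate's direction. The HPT+ stratum t-test is
    reported alongside but does not gate the filter. Because relative
    expression is log-normal, t-tests run on log2 expression; group
    means and SDs are reported on the linear scale and ``fc`` is the
    geometric-mean fold change, whose sign defines the direction.
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    phases = [p for p in PHASES if p in set(meta.data["phase"])]
    phases = [p for p in phases if p in ("training", "validation")]
    if not phases:
        raise ValueError("metadata contains no training or validation phase")
    directions = candidates.directions()
    assays = sorted(directions)

    rows = []
    reasons: dict[str, str] = {}
    for phase in phases:
        pmeta = meta.phase(phase).data
        case_ids = list(pmeta.loc[pmeta["aaad"] == 1, "sample_id"])
        control_ids = list(pmeta.loc[pmeta["aaad"] == 0, "sample_id"])
        strat_case = list(
            pmeta.loc[(pmeta["aaad"] == 1) & (pmeta["hypertension"] == 1), "sample_id"]
        )
        strat_control = list(
            pmeta.loc[(pmeta["aaad"] == 0) & (pmeta["hypertension"] == 1), "sample_id"]
        )
        hn_control = list(
            pmeta.loc[(pmeta["aaad"] == 0) & (pmeta["hypertension"] == 0), "sample_id"]
        )
        hn_case = list(
            pmeta.loc[(pmeta["aaad"] == 1) & (pmeta["hypertension"] == 0), "sample_id"]
        )
        for name, ids in (
            ("HPT-/AAAD-", hn_control),
            ("HPT+/AAAD-", strat_control),
            ("HPT-/AAAD+", hn_case),
            ("HPT+/AAAD+", strat_case),
        ):
            if not ids:
                raise ValueError(f"phase {phase!r} has no samples in group {name}")
        all_ids = case_ids + control_ids
        for assay in assays:
            rate = detection_rate(matrix, assay, all_ids)
            overall = None
            for contrast, cids, gids in (
                ("overall", case_ids, control_ids),
                ("hpt_stratum", strat_case, strat_control),
            ):
                row = _contrast_row(matrix, assay, cids, gids, variant)
                row.update(
                    assay_id=assay,
                    phase=phase,
                    contrast=contrast,
                    detection_rate=rate,
                )
                rows.append(row)
                if contrast == "overall":
                    overall = row
            if assay in reasons:
                continue
            if rate < min_detection:
                reasons[assay] = "detection_rate"
            elif not (overall["p"] < alpha):  # NaN p also fails
                reasons[assay] = "not_significant"
            elif not _parallel_trend(
                matrix,
                assay,
                directions[assay],
                strat_case,
                hn_case,
                strat_control,
                hn_control,
            ):
                reasons[assay] = "trend"

    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for (_, _), idx in out.groupby(["phase", "contrast"]).groups.items():
        pvals = out.loc[idx, "p"]
        ok = pvals.notna()
        if ok.any():
            out.loc[idx[ok], "p_adj"] = multipletests(pvals[ok], method="fdr_bh")[1]
    out["kept"] = ~out["assay_id"].isin(reasons)
    out["drop_reason"] = out["assay_id"].map(reasons).fillna("")
    out = out.sort_values(["assay_id", "phase", "contrast"], kind="mergesort")
    return out[RESULT_COLUMNS].reset_index(drop=True)


def kept_assays(results: pd.DataFrame, candidates: CandidateSet) -> list[str]:
    """Assays surviving confirmation, in candidate-set order."""
    kept = set(results.loc[results["kept"], "assay_id"])
    return [a for a in candidates.assay_ids if a in kept]
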