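"""Array-phase candidate screening on pooled group profiles.

The discovery stage profiles hundreds of miRNAs on pooled serum from each
of the four cohort groups, yielding one expression value per assay per
group. Candidates for qPCR follow-up must show a fold change of at least
``fc_threshold`` (default 2) in three comparisons — each AAAD+ group
against the pooled AAAD- reference, and HPT+/AAAD+ against HPT+/AAAD- —
with a concordant direction (all up or all down). Profile similarity
between groups is summarized by the squared Pearson correlation (R^2)
over assays detected in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GROUP_HN_AN, GROUP_HN_AP, GROUP_HP_AN, GROUP_HP_AP, GROUP_LABELS

_PROFILE_COLUMNS = ["assay_id", "group", "expression", "detected"]
_CANDIDATE_COLUMNS = ["assay_id", "fc_hptpos", "fc_hptneg", "fc_within_hpt", "direction"]


@dataclass
class ArrayProfile:
    """Pooled expression per assay per cohort group.

    ``data`` columns: assay_id, group, expression, detected. Groups are
    exactly the four cohort labels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PROFILE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"array profile missing columns: {missing}")
        bad = set(self.data["group"]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        det = self.data["detected"].to_numpy(dtype=bool)
        if np.any(self.data["expression"].to_numpy(dtype=float)[det] <= 0):
            raise ValueError("detected pooled expression must be positive")

    def pivot(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Wide (assay x group) expression and detected tables."""
        expr = self.data.pivot(index="assay_id", columns="group", values="expression")
        det = (
            self.data.pivot(index="assay_id", columns="group", values="detected")
            .fillna(False)
            .astype(bool)
        )
        return expr, det

    @property
    def assay_ids(self) -> list[str]:
        return list(pd.unique(self.data["assay_id"]))

    def n_detectable(self) -> int:
        """Number of assays detected in at least one group."""
        _, det = self.pivot()
        return int(det.any(axis=1).sum())

    def write_tsv(self, path) -> None:
        self.data[_PROFILE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ArrayProfile":
        data = pd.read_csv(path, sep="\t")
        data["detected"] = data["detected"].astype(bool)
        return cls(data)


@dataclass
class CandidateSet:
    """Assays surviving the array-phase fold-change screen.

    ``data`` columns: assay_id, fc_hptpos (HPT+/AAAD+ vs AAAD-),
    fc_hptneg (HPT-/AAAD+ vs AAAD-), fc_within_hpt (HPT+/AAAD+ vs
    HPT+/AAAD-), direction (+1 up, -1 down). Sorted by |log2 fc_hptpos|
    descending, ties broken by assay_id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CANDIDATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"candidate set missing columns: {missing}")
        if not set(self.data["direction"]) <= {-1, 1}:
            raise ValueError("direction must be +1 or -1")

    @property
    def assay_ids(self) -> list[str]:
        return list(self.data["assay_id"])

    def directions(self) -> dict[str, int]:
        return dict(zip(self.data["assay_id"], self.data["direction"].astype(int)))

    def write_tsv(self, path) -> None:
        self.data[_CANDIDATE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CandidateSet":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.data)


def fold_change(case_mean: float, control_mean: float) -> float:
    """Linear-scale expression ratio case / control."""
    if case_mean <= 0 or control_mean <= 0:
        raise ValueError("fold_change requires positive expression values")
    return float(case_mean / control_mean)


def select_candidates(profile: ArrayProfile, fc_threshold: float = 2.0) -> CandidateSet:
    """Apply the three fold-change criteria plus direction concordance.

    The AAAD- reference is the equal-weight mean of the two AAAD- pools.
    Assays undetected in any of the four groups are excluded (a ratio
    against a ceiling value is meaningless). An assay is a candidate when
    all three fold changes are >= fc_threshold, or all <= 1/fc_threshold.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    expr, det = profile.pivot()
    for grp in GROUP_LABELS:
        if grp not in expr.columns:
            raise ValueError(f"array profile missing group {grp!r}")
    usable = det[list(GROUP_LABELS)].all(axis=1)
    expr = expr.loc[usable]
    rows = []
    if usable.any():
        ref = (expr[GROUP_HN_AN] + expr[GROUP_HP_AN]) / 2.0
        fc1 = expr[GROUP_HP_AP] / ref
        fc2 = expr[GROUP_HN_AP] / ref
        fc3 = expr[GROUP_HP_AP] / expr[GROUP_HP_AN]
        up = (fc1 >= fc_threshold) & (fc2 >= fc_threshold) & (fc3 >= fc_threshold)
        down = (
            (fc1 <= 1 / fc_threshold)
            & (fc2 <= 1 / fc_threshold)
            & (fc3 <= 1 / fc_threshold)
        )
        for assay in expr.index[up | down]:
            rows.append(
                {
                    "assay_id": assay,
                    "fc_hptpos": float(fc1[assay]),
                    "fc_hptneg": float(fc2[assay]),
                    "fc_within_hpt": float(fc3[assay]),
                    "direction": 1 if up[assay] else -1,
                }
            )
    data = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    if len(data):
        data["abs_log2_fc1"] = np.abs(np.log2(data["fc_hptpos"]))
        data = (
            data.sort_values(
                ["abs_log2_fc1", "assay_id"], ascending=[False, True], kind="mergesort"
            )
            .drop(columns="abs_log2_fc1")
            .reset_index(drop=True)
        )
    return CandidateSet(data)


def profile_r2(profile_a, profile_b) -> float:
    """Squared Pearson correlation between two expression vectors.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-d vectors of equal length")
    if a.size < 3:
        raise ValueError("profile_r2 requires at least 3 assays")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance: R^2 undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(a, b)
    return float(r * r)


def group_profile_r2(
    profile: ArrayProfile, group_a: str, group_b: str, log_scale: bool = True
) -> float:
    """R^2 between two group profiles over assays detected in both."""
    expr, det = profile.pivot()
    for grp in (group_a, group_b):
        if grp not in expr.columns:
            raise ValueError(f"array profile missing group {grp!r}")
    both = det[group_a] & det[group_b]
    a = expr.loc[both, group_a].to_numpy(dtype=float)
    b = expr.loc[both, group_b].to_numpy(dtype=float)
    if log_scale:
        a, b = np.log2(a), np.log2(b)
    return profile_r2(a, b)
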