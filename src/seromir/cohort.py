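"""Cohort labels and sample metadata.

Samples belong to one of four groups defined by hypertension (HPT) and
acute type A aortic dissection (AAAD) status, and to one of four study
phases: training, validation, blind, retrospective.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GROUP_HN_AN = "HPT-/AAAD-"
GROUP_HP_AN = "HPT+/AAAD-"
GROUP_HN_AP = "HPT-/AAAD+"
GROUP_HP_AP = "HPT+/AAAD+"

#: canonical ordering of the four cohort groups
GROUP_LABELS = (GROUP_HN_AN, GROUP_HP_AN, GROUP_HN_AP, GROUP_HP_AP)

PHASES = ("training", "validation", "blind", "retrospective")

_META_COLUMNS = ["sample_id", "hypertension", "aaad", "phase"]


def group_label(hypertension: bool, aaad: bool) -> str:
    """Return the canonical group label for an HPT/AAAD status pair."""
    return f"HPT{'+' if hypertension else '-'}/AAAD{'+' if aaad else '-'}"


def split_group_label(label: str) -> tuple[bool, bool]:
    """Invert :func:`group_label` -> (hypertension, aaad)."""
    if label not in GROUP_LABELS:
        raise ValueError(f"unknown group label: {label!r}")
    hpt, aaad = label.split("/")
    return hpt.endswith("+"), aaad.endswith("+")


@dataclass
class SampleMetadata:
    """Per-sample clinical labels: hypertension, disease status, study phase.

    ``data`` columns: sample_id, hypertension (0/1), aaad (0/1), phase,
    plus any optional covariates (age, sex, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_ids: {sorted(set(dups))}")
        bad = set(self.data["phase"]) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def group_labels(self) -> pd.Series:
        """Group label per sample, indexed by sample_id."""
        out = self.data.apply(
            lambda r: group_label(bool(r["hypertension"]), bool(r["aaad"])), axis=1
        )
        out.index = pd.Index(self.data["sample_id"])
        return out

    def subset(self, mask: pd.Series) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[mask.values].reset_index(drop=True))

    def phase(self, phase: str) -> "SampleMetadata":
        if phase not in PHASES:
            raise ValueError(f"unknown phase: {phase!r}")
        return self.subset(self.data["phase"] == phase)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.data)
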