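"""Spike-in-normalized RT-qPCR quantification.

Raw output of a qPCR run is a cycle-threshold (Ct) value per reaction;
lower Ct means more template. Technical replicates (typically triplicate)
are averaged on the Ct scale, and relative expression of a target miRNA
is computed against an external spike-in standard added at extraction:

    relative expression = 2^-(Ct_target - Ct_spikein)

The spike-in (a plant miRNA, MIR2911, with no human homolog) absorbs
per-sample technical variation in extraction and reverse transcription.
Assays that never amplify are recorded at a detection ceiling with a
``detected`` flag; the fraction of samples in which an assay is detected
drives a downstream detection-rate filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: default external spike-in assay identifier
DEFAULT_SPIKEIN = "MIR2911"

_CT_COLUMNS = ["sample_id", "assay_id", "replicate", "ct", "detected"]


@dataclass
class CtTable:
    """Long-format table of replicate Ct measurements.

    ``data`` columns: sample_id, assay_id, replicate, ct, detected.
    The spike-in assay must be present and detected for every sample.
    """

    data: pd.DataFrame
    spikein_assay_id: str = DEFAULT_SPIKEIN

    def __post_init__(self) -> None:
        missing = [c for c in _CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct < 0):
            raise ValueError("Ct values must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))

    @property
    def assay_ids(self) -> list[str]:
        return list(pd.unique(self.data["assay_id"]))

    def write_csv(self, path) -> None:
        self.data[_CT_COLUMNS].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, spikein_assay_id: str = DEFAULT_SPIKEIN) -> "CtTable":
        data = pd.read_csv(path)
        data["detected"] = data["detected"].astype(bool)
        return cls(data, spikein_assay_id=spikein_assay_id)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ExpressionMatrix:
    """Sample x assay relative-expression matrix (2^-dCt vs spike-in).

    ``values`` and ``detected`` share index (sample_id) and columns
    (assay_id). Undetected cells carry the ceiling-derived expression
    value but are flagged ``detected = False`` and are excluded from
    group statistics downstream.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    spikein_assay_id: str = DEFAULT_SPIKEIN
    provenance: str = field(default="")

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or not (
            self.values.columns.equals(self.detected.columns)
        ):
            raise ValueError("values and detected must be aligned")
        if self.provenance == "":
            self.provenance = f"normalized to spike-in {self.spikein_assay_id}"
        det = self.detected.to_numpy(dtype=bool)
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[det] <= 0):
            raise ValueError("detected expression values must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    def assay_values(
        self, assay_id: str, sample_ids: Sequence[str], detected_only: bool = True
    ) -> np.ndarray:
        """Expression values of one assay over the given samples."""
        if assay_id not in self.values.columns:
            raise KeyError(f"unknown assay: {assay_id!r}")
        vals = self.values.loc[list(sample_ids), assay_id]
        if detected_only:
            vals = vals[self.detected.loc[list(sample_ids), assay_id]]
        return vals.to_numpy(dtype=float)

    def write_tsv(self, path, detected_path=None) -> None:
        self.values.rename_axis("sample_id").to_csv(path, sep="\t")
        if detected_path is not None:
            self.detected.rename_axis("sample_id").to_csv(detected_path, sep="\t")

    @classmethod
    def read_tsv(
        cls, path, detected_path, spikein_assay_id: str = DEFAULT_SPIKEIN
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="sample_id")
        detected = pd.read_csv(detected_path, sep="\t", index_col="sample_id")
        return cls(values, detected.astype(bool), spikein_assay_id=spikein_assay_id)


def mean_ct(replicate_cts: Iterable[float]) -> float:
    """Arithmetic mean of replicate Ct values.

    Raises ``ValueError`` on an empty or non-finite input.
    """
    cts = np.asarray(list(replicate_cts), dtype=float)
    if cts.size == 0:
        raise ValueError("mean_ct requires at least one replicate")
    if not np.all(np.isfinite(cts)):
        raise ValueError("replicate Ct values must be finite")
    return float(cts.mean())


def relative_expression(ct_target: float, ct_spikein: float) -> float:
    """Relative expression 2^-(Ct_target - Ct_spikein).

    Strictly positive; halves for every extra cycle of the target.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_spikein)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_spikein))


def build_expression_matrix(ct: CtTable) -> ExpressionMatrix:
    """Collapse replicates and normalize every assay to the spike-in.

    Each (sample, assay) cell is 2^-(mean Ct - mean spike-in Ct) for that
    sample. Undetected cells keep their ceiling-derived value with
    ``detected = False``. Raises if any sample lacks the spike-in assay.
    """
    spike = ct.spikein_assay_id
    mean_cts = (
        ct.data.groupby(["sample_id", "assay_id"], sort=False)["ct"].mean().unstack()
    )
    detected = (
        ct.data.groupby(["sample_id", "assay_id"], sort=False)["detected"]
        .all()
        .unstack(fill_value=False)
        .astype(bool)
    )
    if spike not in mean_cts.columns:
        raise ValueError(f"spike-in assay {spike!r} absent from Ct table")
    missing = mean_cts.index[mean_cts[spike].isna()].tolist()
    if missing or mean_cts.isna().any().any():
        if missing:
            raise ValueError(f"samples missing spike-in assay: {missing}")
        raise ValueError("Ct table is not rectangular: some sample x assay cells missing")
    if not detected[spike].all():
        bad = detected.index[~detected[spike]].tolist()
        raise ValueError(f"spike-in undetected in samples: {bad}")
    values = np.power(2.0, -(mean_cts.sub(mean_cts[spike], axis=0)))
    # keep column order of first appearance in the table
    order = list(pd.unique(ct.data["assay_id"]))
    values = values[order]
    detected = detected[order].reindex(values.index)
    return ExpressionMatrix(values, detected, spikein_assay_id=spike)


def detection_rate(
    matrix: ExpressionMatrix, assay_id: str, sample_ids: Iterable[str]
) -> float:
    """Fraction of the given samples in which the assay is detected."""
    samples = list(sample_ids)
    if not samples:
        raise ValueError("detection_rate requires at least one sample")
    if assay_id not in matrix.detected.columns:
        raise KeyError(f"unknown assay: {assay_id!r}")
    flags = matrix.detected.loc[samples, assay_id]
    return float(flags.to_numpy(dtype=bool).mean())
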