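"""Synthetic serum-miRNA cohort generator.

Emulates a four-group case-control study of acute type A aortic
dissection (AAAD) stratified by hypertension (HPT): triplicate qPCR Ct
tables with an external spike-in, pooled array profiles for the
discovery phase, and sample metadata. The statistical structure is the
one the downstream analysis assumes: Gaussian noise on the Ct scale
(log-normal expression), replicate noise nested inside sample noise, a
detection ceiling for failed assays, and a group-neutral spike-in.

Four marker miRNAs are planted by default — miR-25, miR-29a and miR-155
up-regulated and miR-26b down-regulated in AAAD+ serum — on a background
of null miRNAs. A log2 effect of e cycles shifts the Ct of a marker in
AAAD+ samples down by e (lower Ct = more template).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import GROUP_LABELS, SampleMetadata, split_group_label
from .qpcr import DEFAULT_SPIKEIN, CtTable
from .screening import ArrayProfile

#: technical replicates per reaction, as in standard triplicate qPCR
N_REPLICATES = 3

#: default planted log2 fold changes (AAAD+ vs AAAD-), in cycles.
#: Magnitude 3.75 with a between-sample SD of 1.5 cycles separates the
#: groups by d = 2.5, so a marker binarized at the 95% control limit
#: flags about 80% of cases — strong markers, matching a panel whose
#: training operating point reaches ~96% sensitivity at ~100%
#: specificity from four binary indicators.
DEFAULT_MARKER_EFFECTS: dict[str, float] = {
    "miR-25": 3.75,
    "miR-29a": 3.75,
    "miR-155": 3.75,
    "miR-26b": -3.75,
}


def _null_ids(n: int) -> list[str]:
    return [f"null-{i:02d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a synthetic cohort; a (design, seed) pair fully
    determines the generated data.

    group_sizes maps each of the four cohort labels to a sample count.
    marker_effects maps marker id -> signed log2 fold change in AAAD+
    vs AAAD- samples. Ct parameters are in cycles.
    """

    group_sizes: Mapping[str, int]
    n_null_mirnas: int = 18
    marker_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_EFFECTS)
    )
    baseline_ct_mean: float = 30.0
    baseline_ct_sd: float = 1.5
    spikein_ct_mean: float = 22.0
    spikein_ct_sd: float = 0.5
    detection_ceiling: float = 40.0
    dropout_rate: float = 0.02
    replicate_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.group_sizes) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        for name in ("baseline_ct_sd", "spikein_ct_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_null_mirnas < 0:
            raise ValueError("n_null_mirnas must be >= 0")
        overlap = set(self.marker_effects) & set(_null_ids(self.n_null_mirnas))
        if overlap:
            raise ValueError(f"marker ids collide with null ids: {sorted(overlap)}")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.get(g, 0) for g in GROUP_LABELS)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_effects)

    @property
    def target_assay_ids(self) -> list[str]:
        return self.marker_ids + _null_ids(self.n_null_mirnas)

    def with_seed(self, seed: int) -> "CohortDesign":
        return replace(self, seed=seed)


def _rng(seed: int, stream: str) -> np.random.Generator:
    # independent, reproducible stream per (seed, stream label)
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stream.encode())])
    )


def generate_cohort(
    design: CohortDesign, phase_label: str
) -> tuple[CtTable, SampleMetadata]:
    """Generate triplicate Ct data and metadata for one study phase.

    Marker assays in AAAD+ samples are shifted by -(log2 fold change)
    cycles relative to AAAD- samples. Dropout assays are recorded at the
    detection ceiling with ``detected = False``; the spike-in is always
    detected and independent of disease group.
    """
    n_samples = design.n_samples
    if n_samples == 0:
        raise ValueError("design has zero total samples; nothing to generate")
    rng = _rng(design.seed, f"cohort:{phase_label}")

    groups: list[str] = []
    for g in GROUP_LABELS:
        groups.extend([g] * design.group_sizes.get(g, 0))
    sample_ids = [f"{phase_label}-{i + 1:03d}" for i in range(n_samples)]
    hpt_aaad = [split_group_label(g) for g in groups]
    aaad = np.array([a for _, a in hpt_aaad], dtype=float)

    assays = design.target_assay_ids
    n_assays = len(assays)
    effects = np.array(
        [design.marker_effects.get(a, 0.0) for a in assays], dtype=float
    )

    # per-sample, per-assay biological mean Ct; effect lowers case Ct
    mean_ct = (
        design.baseline_ct_mean
        + rng.normal(0.0, design.baseline_ct_sd, size=(n_samples, n_assays))
        - np.outer(aaad, effects)
    )
    rep_ct = mean_ct[:, :, None] + rng.normal(
        0.0, design.replicate_sd, size=(n_samples, n_assays, N_REPLICATES)
    )
    dropout = rng.random(size=(n_samples, n_assays)) < design.dropout_rate
    undetected = dropout | (rep_ct.mean(axis=2) >= design.detection_ceiling)
    rep_ct = np.minimum(rep_ct, design.detection_ceiling)
    rep_ct[undetected, :] = design.detection_ceiling

    spike_mean = design.spikein_ct_mean + rng.normal(
        0.0, design.spikein_ct_sd, size=n_samples
    )
    spike_rep = spike_mean[:, None] + rng.normal(
        0.0, design.replicate_sd, size=(n_samples, N_REPLICATES)
    )

    all_assays = assays + [DEFAULT_SPIKEIN]
    reps = np.arange(1, N_REPLICATES + 1)
    ct_all = np.concatenate([rep_ct, spike_rep[:, None, :]], axis=1)
    det_all = np.concatenate(
        [~undetected, np.ones((n_samples, 1), dtype=bool)], axis=1
    )
    data = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, len(all_assays) * N_REPLICATES),
            "assay_id": np.tile(np.repeat(all_assays, N_REPLICATES), n_samples),
            "replicate": np.tile(reps, n_samples * len(all_assays)),
            "ct": ct_all.reshape(-1),
            "detected": np.repeat(det_all.reshape(-1), N_REPLICATES),
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "hypertension": [int(h) for h, _ in hpt_aaad],
            "aaad": [int(a) for _, a in hpt_aaad],
            "phase": phase_label,
        }
    )
    return CtTable(data, spikein_assay_id=DEFAULT_SPIKEIN), SampleMetadata(meta)


def generate_array_pools(
    design: CohortDesign,
    n_assays_total: int = 760,
    n_detectable: int = 313,
    pool_noise_sd: float = 0.1,
    base_log2_sd: float = 1.5,
) -> ArrayProfile:
    """Generate a pooled discovery-array profile: one expression value
    per assay per group.

    Marker assays are placed first in the detectable set and carry the
    design's planted effects in both AAAD+ pools (hence also in the
    HPT+/AAAD+ vs HPT+/AAAD- contrast). Exactly ``n_detectable`` assays
    are detectable; the rest are flagged undetected in every group.
    ``pool_noise_sd`` is the log2-scale technical noise of a single
    pooled measurement.
    """
    if n_detectable > n_assays_total:
        raise ValueError("n_detectable cannot exceed n_assays_total")
    rng = _rng(design.seed, "array")
    markers = design.marker_ids
    n_fill = n_assays_total - len(markers)
    if n_fill < 0:
        raise ValueError("n_assays_total smaller than the number of markers")
    assays = markers + [f"array-{i:04d}" for i in range(1, n_fill + 1)]
    detectable = np.zeros(n_assays_total, dtype=bool)
    detectable[:n_detectable] = True

    base = rng.normal(0.0, base_log2_sd, size=n_assays_total)
    effects = np.array(
        [design.marker_effects.get(a, 0.0) for a in assays], dtype=float
    )
    rows = []
    for grp in GROUP_LABELS:
        _, is_aaad = split_group_label(grp)
        noise = rng.normal(0.0, pool_noise_sd, size=n_assays_total)
        log2_expr = base + noise + (effects if is_aaad else 0.0)
        expr = np.where(detectable, np.exp2(log2_expr), 2.0**-10)
        rows.append(
            pd.DataFrame(
                {
                    "assay_id": assays,
                    "group": grp,
                    "expression": expr,
                    "detected": detectable,
                }
            )
        )
    return ArrayProfile(pd.concat(rows, ignore_index=True))


def training_design(seed: int = 0, **overrides) -> CohortDesign:
    """Training phase: 25 AAAD+ (15 HPT+) vs 30 AAAD- (15 HPT+)."""
    sizes = {
        "HPT-/AAAD-": 15,
        "HPT+/AAAD-": 15,
        "HPT-/AAAD+": 10,
        "HPT+/AAAD+": 15,
    }
    return CohortDesign(group_sizes=sizes, seed=seed, **overrides)


def validation_design(seed: int = 0, **overrides) -> CohortDesign:
    """Validation phase: 64 AAAD+ (44 HPT+) vs 58 AAAD- (29 HPT+)."""
    sizes = {
        "HPT-/AAAD-": 29,
        "HPT+/AAAD-": 29,
        "HPT-/AAAD+": 20,
        "HPT+/AAAD+": 44,
    }
    return CohortDesign(group_sizes=sizes, seed=seed, **overrides)


def blind_design(seed: int = 0, **overrides) -> CohortDesign:
    """Blind trial: 15 HPT+/AAAD+ vs 15 HPT+/AAAD-."""
    sizes = {"HPT+/AAAD-": 15, "HPT+/AAAD+": 15}
    return CohortDesign(group_sizes=sizes, seed=seed, **overrides)


def retrospective_design(seed: int = 0, **overrides) -> CohortDesign:
    """Retrospective prediction: 4 prediagnosis AAAD cases vs 10
    hypertensive controls."""
    sizes = {"HPT+/AAAD-": 10, "HPT+/AAAD+": 4}
    return CohortDesign(group_sizes=sizes, seed=seed, **overrides)
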