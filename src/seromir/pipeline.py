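"""Four-phase study orchestration: train, validate, blind test,
retrospective prediction.

The training phase confirms screened candidates, estimates reference
limits on training controls, fits indicator weights and the percentage
calibration, and picks the cutoff maximizing sensitivity + specificity.
The frozen model is then applied unchanged to the validation phase. A
second model instance is refit on the hypertensive stratum of the pooled
training + validation samples and applied to the blind and retrospective
phases, mirroring a design where a separate cutoff is reported for
discriminating hypertensive AAAD+ patients from hypertensive controls.
Reference limits, weights, calibration and cutoff never consult samples
outside the fitting set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .cohort import SampleMetadata
from .diffexp import confirm_candidates, kept_assays
from .qpcr import DEFAULT_SPIKEIN, CtTable, ExpressionMatrix, build_expression_matrix
from .risk import (
    RiskModel,
    calibrate_percentage,
    fit_weights,
    indicator_matrix,
    reference_limit,
    risk_score,
)
from .roc import ConfusionCounts, ROCResult, auc_ci, confusion_metrics, roc_curve
from .screening import CandidateSet
from . import synthetic


@dataclass(frozen=True)
class PipelineConfig:
    """Every analysis choice surfaced as a recorded setting."""

    seed: int
    spikein_id: str = DEFAULT_SPIKEIN
    alpha: float = 0.05
    alpha_ref: float = 0.05
    fc_threshold: float = 2.0
    min_detection: float = 0.75
    quantile_method: str = "linear"
    min_controls: int = 10
    n_boot: int = 500
    indicator_rule: str = "direction_aware"
    t_variant: str = "student"
    refit_hpt_stratum: bool = True


@dataclass
class PhaseReport:
    """Per-phase evaluation: confusion counts, metrics, ROC summary and
    per-sample risk-score results."""

    phase: str
    model_id: str
    counts: ConfusionCounts
    metrics: dict[str, float]
    roc: Optional[ROCResult]
    samples: pd.DataFrame
    log: list[str] = field(default_factory=list)


def fit_risk_model(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    markers: list[str],
    directions: list[int],
    config: PipelineConfig,
    training_phase_id: str = "training",
) -> RiskModel:
    """Fit limits, weights, calibration and cutoff on the given samples.

    Reference limits come from control (AAAD-) samples only; weights from
    univariate logistic fits of status on each indicator; the cutoff is
    the percentage maximizing sensitivity + specificity on these samples.
    """
    ids = meta.sample_ids
    labels = meta.data.set_index("sample_id").loc[ids, "aaad"].to_numpy(dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError(f"{training_phase_id}: both classes required to fit a model")
    control_ids = [i for i, y in zip(ids, labels) if y == 0]

    limits = []
    for m, d in zip(markers, directions):
        controls = matrix.assay_values(m, control_ids, detected_only=True)
        limit_dir = -1 if config.indicator_rule == "lower_tail" else d
        limits.append(
            reference_limit(
                controls, limit_dir, alpha_ref=config.alpha_ref,
                min_n=config.min_controls,
            )
        )

    # provisional model to materialize indicators; calibration/cutoff next
    model = RiskModel(
        markers=list(markers),
        directions=list(directions),
        limits=limits,
        weights=[0.0] * len(markers),
        calibration=(0.0, 1.0),
        cutoff=50.0,
        quantile_method=config.quantile_method,
        alpha_ref=config.alpha_ref,
        indicator_rule=config.indicator_rule,
        training_phase_id=training_phase_id,
    )
    ind = indicator_matrix(matrix.values.loc[ids], model)
    weights, flags = fit_weights(ind.to_numpy(), labels)
    rsf = ind.to_numpy(dtype=float) @ weights
    intercept, slope = calibrate_percentage(rsf, labels)
    model.weights = [float(w) for w in weights]
    model.separation_flags = flags
    model.calibration = (intercept, slope)

    scored = risk_score(ind, model)
    roc = roc_curve(scored["percentage"].to_numpy(), labels)
    model.cutoff = max(0.0, min(100.0, roc.optimal_cutoff))
    return model


def apply_model(
    model: RiskModel,
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    phase: str,
    model_id: str,
    ci_seed: int | None = None,
    n_boot: int = 500,
) -> PhaseReport:
    """Score a sample set with a frozen model and report metrics.

    Scoring never consults the labels; they enter only the evaluation.
    """
    ids = meta.sample_ids
    if not ids:
        raise ValueError(f"phase {phase!r} contains no samples")
    missing = [m for m in model.markers if m not in matrix.values.columns]
    if missing:
        raise ValueError(f"assays missing from expression matrix: {missing}")
    ind = indicator_matrix(matrix.values.loc[ids], model)
    scored = risk_score(ind, model)
    samples = meta.data.set_index("sample_id").loc[ids].join(scored)
    samples.insert(0, "group", meta.group_labels())

    labels = samples["aaad"].to_numpy(dtype=int)
    predicted = samples["predicted"].to_numpy(dtype=int)
    counts = ConfusionCounts.from_predictions(labels, predicted)
    metrics = confusion_metrics(counts)
    roc = None
    log = []
    if len(set(labels.tolist())) == 2:
        pct = samples["percentage"].to_numpy(dtype=float)
        ci = (
            auc_ci(pct, labels, n_boot=n_boot, seed=ci_seed)
            if ci_seed is not None
            else None
        )
        roc = roc_curve(pct, labels, ci=ci)
    else:
        log.append("single-class phase: ROC not computed")
    for sid, row in samples.iterrows():
        log.append(
            f"{sid}: rsf={row['rsf']:.4f} pct={row['percentage']:.2f} "
            f"predicted={'+' if row['predicted'] else '-'} cutoff={model.cutoff:.2f}"
        )
    return PhaseReport(
        phase=phase,
        model_id=model_id,
        counts=counts,
        metrics=metrics,
        roc=roc,
        samples=samples.reset_index(),
        log=log,
    )


def run_training(
    ct: CtTable,
    meta: SampleMetadata,
    candidates: CandidateSet,
    config: PipelineConfig,
) -> tuple[RiskModel, PhaseReport, pd.DataFrame]:
    """Confirm candidates and fit the all-comers model.

    Panel membership follows the study's two-phase selection: candidates
    are confirmed in every training/validation phase present in the
    metadata. Reference limits, weights, calibration and the cutoff are
    then fitted on training-phase samples only. Returns (model, training
    report, confirmation table)."""
    matrix = build_expression_matrix(ct)
    train_meta = meta.phase("training")
    if len(train_meta) == 0:
        raise ValueError("no training-phase samples in metadata")
    confirm_meta = meta.subset(meta.data["phase"].isin(["training", "validation"]))
    confirmation = confirm_candidates(
        matrix,
        confirm_meta,
        candidates,
        alpha=config.alpha,
        min_detection=config.min_detection,
        variant=config.t_variant,
    )
    markers = kept_assays(confirmation, candidates)
    if not markers:
        dropped = (
            confirmation[["assay_id", "drop_reason"]]
            .drop_duplicates()
            .to_dict("records")
        )
        raise ValueError(f"no markers survived confirmation: {dropped}")
    dirs = candidates.directions()
    directions = [dirs[m] for m in markers]
    model = fit_risk_model(
        matrix, train_meta, markers, directions, config, training_phase_id="training"
    )
    report = apply_model(
        model,
        matrix,
        train_meta,
        phase="training",
        model_id="all-comers",
        ci_seed=config.seed,
        n_boot=config.n_boot,
    )
    return model, report, confirmation


def run_validation(
    model: RiskModel,
    ct: CtTable,
    meta: SampleMetadata,
    phase: str = "validation",
    config: Optional[PipelineConfig] = None,
) -> PhaseReport:
    """Apply a frozen model (no refitting) to a later phase."""
    matrix = build_expression_matrix(ct)
    pmeta = meta.phase(phase)
    if len(pmeta) == 0:
        raise ValueError(f"no {phase}-phase samples in metadata")
    seed = config.seed if config is not None else None
    n_boot = config.n_boot if config is not None else 500
    return apply_model(
        model, matrix, pmeta, phase=phase, model_id=model.training_phase_id,
        ci_seed=seed, n_boot=n_boot,
    )


def run_blind(
    model: RiskModel,
    ct: CtTable,
    meta: SampleMetadata,
    config: Optional[PipelineConfig] = None,
) -> PhaseReport:
    """Blind-trial evaluation, restricted to the hypertensive stratum."""
    pmeta = meta.phase("blind")
    pmeta = pmeta.subset(pmeta.data["hypertension"] == 1)
    if len(pmeta) == 0:
        raise ValueError("no hypertensive blind-phase samples in metadata")
    matrix = build_expression_matrix(ct)
    seed = config.seed if config is not None else None
    n_boot = config.n_boot if config is not None else 500
    return apply_model(
        model, matrix, pmeta, phase="blind", model_id=model.training_phase_id,
        ci_seed=seed, n_boot=n_boot,
    )


def run_retrospective(
    model: RiskModel, ct: CtTable, meta: SampleMetadata
) -> PhaseReport:
    """Score prediagnosis samples against the frozen model cutoff and
    produce a per-sample listing."""
    pmeta = meta.phase("retrospective")
    if len(pmeta) == 0:
        raise ValueError("no retrospective-phase samples in metadata")
    matrix = build_expression_matrix(ct)
    return apply_model(
        model, matrix, pmeta, phase="retrospective",
        model_id=model.training_phase_id,
    )


def fit_stratum_model(
    ct: CtTable,
    meta: SampleMetadata,
    markers: list[str],
    directions: list[int],
    config: PipelineConfig,
) -> RiskModel:
    """Refit the panel on the hypertensive stratum of the pooled
    training + validation samples (separate limits, weights, calibration
    and cutoff for the HPT+/AAAD+ vs HPT+/AAAD- question)."""
    matrix = build_expression_matrix(ct)
    mask = meta.data["phase"].isin(["training", "validation"]) & (
        meta.data["hypertension"] == 1
    )
    sub = meta.subset(mask)
    if len(sub) == 0:
        raise ValueError("no hypertensive training/validation samples")
    return fit_risk_model(
        matrix, sub, markers, directions, config,
        training_phase_id="training+validation/HPT+",
    )


def marker_roc_table(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    model: RiskModel,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Table-2-style report: panel and per-marker ROC on the given
    samples.

    Per-marker scores are relative-expression values oriented by the
    marker's direction (down-regulated markers are negated so that
    higher always means more disease-like); reported cutoffs are on the
    attained relative-expression scale, with the orientation recorded.
    """
    ids = meta.sample_ids
    labels = meta.data.set_index("sample_id").loc[ids, "aaad"].to_numpy(dtype=int)
    rows = []

    ind = indicator_matrix(matrix.values.loc[ids], model)
    pct = risk_score(ind, model)["percentage"].to_numpy()
    entries = [("panel", pct, 1, model.cutoff, True)]
    for m, d in zip(model.markers, model.directions):
        expr = matrix.values.loc[ids, m].to_numpy(dtype=float)
        entries.append((m, expr * d, d, None, False))

    for name, score, direction, fixed_cutoff, is_panel in entries:
        roc = roc_curve(score, labels)
        low, high = auc_ci(score, labels, n_boot=config.n_boot, seed=config.seed)
        if fixed_cutoff is None:
            cut = roc.optimal_cutoff
            pred = (score > cut).astype(int)
            cut_report = cut * direction  # back to the expression scale
        else:
            pred = (score > fixed_cutoff).astype(int)
            cut_report = fixed_cutoff
        counts = ConfusionCounts.from_predictions(labels, pred)
        metrics = confusion_metrics(counts)
        rows.append(
            {
                "score": name,
                "scale": "risk percentage" if is_panel else "relative expression",
                "direction": direction,
                "auc": roc.auc,
                "ci_low": low,
                "ci_high": high,
                "cutoff": cut_report,
                "sensitivity": metrics["sensitivity"],
                "specificity": metrics["specificity"],
                "ppv": metrics["ppv"],
                "npv": metrics["npv"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """End-to-end synthetic study: candidates, confirmation, both model
    instances, and one report per phase."""

    candidates: CandidateSet
    confirmation: pd.DataFrame
    model: RiskModel
    stratum_model: RiskModel
    reports: dict[str, PhaseReport]


def run_full_study(
    config: PipelineConfig,
    designs: Optional[dict[str, synthetic.CohortDesign]] = None,
) -> StudyResult:
    """Simulate and analyze all four phases end to end.

    Default designs mirror the per-phase cohort sizes of the study this
    pipeline emulates (training 25/30, validation 64/58, blind 15/15
    hypertensive, retrospective 4/10 hypertensive).
    """
    from .screening import select_candidates

    if designs is None:
        designs = {
            "training": synthetic.training_design(seed=config.seed),
            "validation": synthetic.validation_design(seed=config.seed),
            "blind": synthetic.blind_design(seed=config.seed),
            "retrospective": synthetic.retrospective_design(seed=config.seed),
        }
    profile = synthetic.generate_array_pools(designs["training"])
    candidates = select_candidates(profile, fc_threshold=config.fc_threshold)
    if len(candidates) == 0:
        raise ValueError("array screen produced no candidates")

    tables, metas = {}, {}
    for phase, design in designs.items():
        tables[phase], metas[phase] = synthetic.generate_cohort(design, phase)
    all_ct = CtTable(
        pd.concat([t.data for t in tables.values()], ignore_index=True),
        spikein_assay_id=config.spikein_id,
    )
    all_meta = SampleMetadata(
        pd.concat([m.data for m in metas.values()], ignore_index=True)
    )

    model, train_report, confirmation = run_training(
        all_ct, all_meta, candidates, config
    )
    reports = {"training": train_report}
    reports["validation"] = run_validation(model, all_ct, all_meta, config=config)

    stratum_model = fit_stratum_model(
        all_ct, all_meta, model.markers, model.directions, config
    ) if config.refit_hpt_stratum else replace_phase_id(model)
    reports["blind"] = run_blind(stratum_model, all_ct, all_meta, config=config)
    reports["retrospective"] = run_retrospective(stratum_model, all_ct, all_meta)
    return StudyResult(
        candidates=candidates,
        confirmation=confirmation,
        model=model,
        stratum_model=stratum_model,
        reports=reports,
    )


def replace_phase_id(model: RiskModel) -> RiskModel:
    """Reuse the all-comers model for the stratum question (no refit)."""
    clone = RiskModel.from_json(model.to_json())
    clone.training_phase_id = model.training_phase_id + "/no-refit"
    return clone
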