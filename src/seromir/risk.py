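"""Binary-indicator weighted risk score.

Each marker miRNA j is binarized against a reference-interval limit
estimated on control samples: for a marker down-regulated in disease the
limit is the lower 5% quantile of controls and S_ij = 1 when expression
falls below it; for an up-regulated marker the upper 95% quantile is
used and S_ij = 1 when expression exceeds it. The marker weight W_j is
the coefficient of a univariate logistic regression of disease status on
the indicator — for a binary predictor this is exactly the log
odds-ratio of the 2x2 indicator-by-label table. A sample's risk score is
the weighted sum

    rsf_i = sum_j W_j * S_ij

mapped to a percentage through a logistic calibration fitted on the
training phase, and classified against a percentage cutoff (strictly
greater than the cutoff = predicted positive).

The literal lower-tail rule (S = 1 only below the lower limit, for every
marker regardless of direction) is kept available via
``indicator_rule="lower_tail"`` for auditability; it cannot flag
up-regulated markers and is not the default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

INDICATOR_RULES = ("direction_aware", "lower_tail")


@dataclass
class RiskModel:
    """Frozen scoring model: markers, directions, limits, weights,
    percentage calibration and decision cutoff."""

    markers: list[str]
    directions: list[int]
    limits: list[float]
    weights: list[float]
    calibration: tuple[float, float]  # (intercept, slope) of logit map
    cutoff: float  # percentage in [0, 100]
    quantile_method: str = "linear"
    alpha_ref: float = 0.05
    indicator_rule: str = "direction_aware"
    training_phase_id: str = "training"
    separation_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.markers)
        if not (len(self.directions) == len(self.limits) == len(self.weights) == n):
            raise ValueError("markers, directions, limits, weights must align")
        if not set(self.directions) <= {-1, 1}:
            raise ValueError("directions must be +1 or -1")
        if not 0 <= self.cutoff <= 100:
            raise ValueError("cutoff must be a percentage in [0, 100]")
        if self.indicator_rule not in INDICATOR_RULES:
            raise ValueError(f"unknown indicator rule: {self.indicator_rule!r}")
        if self.calibration[1] < 0:
            raise ValueError("calibration slope must be >= 0")
        if not self.separation_flags:
            self.separation_flags = [False] * n

    def to_json(self, path=None) -> str:
        payload = {
            "markers": self.markers,
            "directions": self.directions,
            "limits": self.limits,
            "weights": self.weights,
            "calibration": {
                "intercept": self.calibration[0],
                "slope": self.calibration[1],
            },
            "cutoff": self.cutoff,
            "quantile_method": self.quantile_method,
            "alpha_ref": self.alpha_ref,
            "indicator_rule": self.indicator_rule,
            "training_phase_id": self.training_phase_id,
            "separation_flags": self.separation_flags,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RiskModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        cal = payload.pop("calibration")
        return cls(calibration=(cal["intercept"], cal["slope"]), **payload)


def reference_limit(
    control_values: Sequence[float],
    direction: int,
    alpha_ref: float = 0.05,
    min_n: int = 10,
) -> float:
    """Reference-interval limit from control expression values.

    Down-regulated markers (direction -1) use the empirical ``alpha_ref``
    quantile; up-regulated markers (direction +1) the ``1 - alpha_ref``
    quantile. Quantiles interpolate linearly between order statistics.
    """
    vals = np.asarray(list(control_values), dtype=float)
    if vals.size < min_n:
        raise ValueError(f"need >= {min_n} control values, got {vals.size}")
    if np.any(vals <= 0):
        raise ValueError("control expression values must be positive")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    q = alpha_ref if direction == -1 else 1.0 - alpha_ref
    return float(np.quantile(vals, q, method="linear"))


def risk_indicator(
    expression, limit: float, direction: int, indicator_rule: str = "direction_aware"
):
    """Binary indicator S for one marker; strict inequalities, so a value
    exactly at the limit scores 0. Accepts scalars or arrays."""
    expr = np.asarray(expression, dtype=float)
    if indicator_rule == "lower_tail":
        out = expr < limit
    elif direction == -1:
        out = expr < limit
    else:
        out = expr > limit
    out = out.astype(int)
    return int(out) if np.isscalar(expression) else out


def log_odds_ratio(n11: float, n10: float, n01: float, n00: float) -> float:
    """log[(n11 * n00) / (n10 * n01)] for the indicator-by-label table
    (first index: indicator, second: label)."""
    if min(n11, n10, n01, n00) <= 0:
        raise ValueError("all cells must be positive")
    return float(np.log(n11 * n00 / (n10 * n01)))


def fit_weights(indicators, labels) -> tuple[np.ndarray, list[bool]]:
    """Univariate logistic-regression weight per marker.

    For a single binary predictor the maximum-likelihood slope equals the
    log odds-ratio of the 2x2 indicator-by-label table, which is used in
    closed form. A zero cell (separation) gets the Haldane-Anscombe
    continuity correction (+0.5 to every cell) and a flag.
    """
    ind = np.asarray(indicators, dtype=float)
    if ind.ndim == 1:
        ind = ind[:, None]
    y = np.asarray(labels, dtype=int)
    if ind.shape[0] != y.size:
        raise ValueError("indicators and labels length mismatch")
    if len(set(y.tolist())) < 2:
        raise ValueError("both label classes must be present")
    weights = np.empty(ind.shape[1])
    flags = []
    for j in range(ind.shape[1]):
        s = ind[:, j].astype(int)
        n11 = float(np.sum((s == 1) & (y == 1)))
        n10 = float(np.sum((s == 1) & (y == 0)))
        n01 = float(np.sum((s == 0) & (y == 1)))
        n00 = float(np.sum((s == 0) & (y == 0)))
        if min(n11, n10, n01, n00) == 0:
            warnings.warn(
                f"separation in marker column {j}: applying Haldane-Anscombe "
                "0.5-cell correction",
                RuntimeWarning,
                stacklevel=2,
            )
            weights[j] = log_odds_ratio(n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5)
            flags.append(True)
        else:
            weights[j] = log_odds_ratio(n11, n10, n01, n00)
            flags.append(False)
    return weights, flags


def indicator_matrix(values: pd.DataFrame, model: RiskModel) -> pd.DataFrame:
    """Indicator columns S_<marker> for a sample x assay expression table."""
    missing = [m for m in model.markers if m not in values.columns]
    if missing:
        raise ValueError(f"expression table missing model markers: {missing}")
    out = {}
    for m, lim, d in zip(model.markers, model.limits, model.directions):
        out[m] = risk_indicator(
            values[m].to_numpy(dtype=float), lim, d, model.indicator_rule
        )
    return pd.DataFrame(out, index=values.index)


def calibrate_percentage(raw_scores, labels) -> tuple[float, float]:
    """Fit the rsf -> percentage map: a univariate logistic regression of
    label on raw score (mildly ridge-penalized so the map stays finite
    under perfect separation; the intercept is unpenalized).

    A negative fitted slope (anti-predictive scores) triggers a warning
    and the identity map (0, 1) as fallback.
    """
    x = np.asarray(raw_scores, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both label classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("degenerate scores: all raw rsf values equal")
    fit = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000).fit(x, y)
    intercept = float(fit.intercept_[0])
    slope = float(fit.coef_[0, 0])
    if slope < 0:
        warnings.warn(
            "negative calibration slope; falling back to identity map",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    return intercept, slope


def risk_score(indicators, model: RiskModel) -> pd.DataFrame:
    """Score samples: raw rsf = sum_j W_j * S_ij, percentage through the
    model calibration, predicted label at the model cutoff.

    ``indicators`` is a sample x marker 0/1 DataFrame (columns must
    match the model markers) or a single aligned 0/1 vector.
    """
    if isinstance(indicators, pd.DataFrame):
        if list(indicators.columns) != list(model.markers):
            raise ValueError(
                f"indicator columns {list(indicators.columns)} do not match "
                f"model markers {model.markers}"
            )
        ind = indicators.to_numpy(dtype=float)
        index = indicators.index
    else:
        ind = np.atleast_2d(np.asarray(indicators, dtype=float))
        if ind.shape[1] != len(model.markers):
            raise ValueError("indicator vector misaligned with model markers")
        index = pd.RangeIndex(ind.shape[0])
    if not set(np.unique(ind)) <= {0.0, 1.0}:
        raise ValueError("indicators must be 0/1")
    w = np.asarray(model.weights, dtype=float)
    rsf = ind @ w
    intercept, slope = model.calibration
    pct = 100.0 * expit(intercept + slope * rsf)
    out = pd.DataFrame(
        {f"S_{m}": ind[:, j].astype(int) for j, m in enumerate(model.markers)},
        index=index,
    )
    out["rsf"] = rsf
    out["percentage"] = pct
    out["predicted"] = classify(pct, model.cutoff)
    return out


def classify(percentage, cutoff: float):
    """Predicted label: positive iff percentage is strictly above cutoff."""
    if not 0 <= cutoff <= 100:
        raise ValueError("cutoff must be in [0, 100]")
    pct = np.asarray(percentage, dtype=float)
    out = (pct > cutoff).astype(int)
    return int(out) if np.isscalar(percentage) else out
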