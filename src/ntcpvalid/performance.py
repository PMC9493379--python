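"""Discrimination and calibration metrics for validated NTCP models.

Discrimination — does the model rank events above non-events? — is measured
by the AUC (pairwise concordance) with a DeLong or bootstrap confidence
interval, plus sensitivity/specificity at a reported threshold.

Calibration — do predicted probabilities match observed event rates? — is
measured by the Brier score, the Hosmer-Lemeshow grouped chi-square test,
and a flexible (lowess) calibration curve from which the E-statistics
(Emax / Eavg / E90: maximum / mean / 90th-percentile absolute difference
between predicted and curve-calibrated probabilities) are derived.

``validation_report`` assembles the full battery for every level of the
closed-testing update hierarchy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import RunConfig
from .model import CohortTable, LogisticModel, NTCPError, PredictionSet
from .updating import ctp_select, level_predictions

__all__ = [
    "DiscriminationSummary",
    "CalibrationCurve",
    "CalibrationSummary",
    "auc",
    "auc_ci",
    "sens_spec",
    "youden_threshold",
    "brier_score",
    "hosmer_lemeshow",
    "flexible_calibration_curve",
    "e_statistics",
    "validation_report",
    "report_to_json",
]


@dataclass(frozen=True)
class DiscriminationSummary:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "threshold": float(self.threshold),
        }


@dataclass(frozen=True, eq=False)
class CalibrationCurve:
    """Smoothed observed proportion as a function of predicted probability."""

    grid: np.ndarray  # predicted probabilities, evenly spaced over the data range
    values: np.ndarray  # smoothed observed proportion c(p), truncated to [0, 1]
    smoother: str = "lowess"
    span: float = 0.75

    def to_dict(self) -> dict:
        return {
            "grid": [float(v) for v in self.grid],
            "values": [float(v) for v in self.values],
            "smoother": self.smoother,
            "span": float(self.span),
        }


@dataclass(frozen=True)
class CalibrationSummary:
    brier: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    n_groups: int
    emax: float
    eavg: float
    e90: float

    def to_dict(self) -> dict:
        return {
            "brier": float(self.brier),
            "hl_statistic": float(self.hl_statistic),
            "hl_df": int(self.hl_df),
            "hl_p": float(self.hl_p),
            "n_groups": int(self.n_groups),
            "emax": float(self.emax),
            "eavg": float(self.eavg),
            "e90": float(self.e90),
        }


def _split_classes(predictions: PredictionSet) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(predictions.outcome)
    p = np.asarray(predictions.prob, dtype=float)
    pos, neg = p[y == 1], p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise NTCPError("AUC undefined: cohort contains a single outcome class")
    return pos, neg


def auc(predictions: PredictionSet) -> float:
    """Concordance probability P(p_event > p_nonevent) + 0.5 P(tie).

    Computed by the midrank (Mann-Whitney) identity, which equals exhaustive
    enumeration over all event/non-event pairs.
    """
    pos, neg = _split_classes(predictions)
    m, n = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    # DeLong structural components via midranks
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n  # per-event placement values
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m  # per-non-event
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(
    predictions: PredictionSet,
    level: float = 0.95,
    method: str = "delong",
    n_resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``method="delong"`` uses the DeLong asymptotic variance of the
    Mann-Whitney statistic; ``method="bootstrap"`` stratified-resamples
    events and non-events separately (percentile interval, seeded).
    """
    pos, neg = _split_classes(predictions)
    point = auc(predictions)
    if method == "delong":
        se = float(np.sqrt(_delong_variance(pos, neg)))
        z = norm.ppf(0.5 + level / 2.0)
        low, high = point - z * se, point + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        m, n = len(pos), len(neg)
        stats = np.empty(n_resamples)
        for b in range(n_resamples):
            bp = pos[rng.integers(0, m, m)]
            bn = neg[rng.integers(0, n, n)]
            ranks = rankdata(np.concatenate([bp, bn]))
            stats[b] = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        low, high = np.quantile(stats, [(1 - level) / 2.0, 0.5 + level / 2.0])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (float(max(0.0, min(low, point))), float(min(1.0, max(high, point))))


def sens_spec(predictions: PredictionSet, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity classifying ``p >= threshold`` as positive."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    y = np.asarray(predictions.outcome)
    pred_pos = np.asarray(predictions.prob) >= threshold
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise NTCPError(
            "sensitivity/specificity undefined: cohort contains a single outcome class"
        )
    sensitivity = float((pred_pos & (y == 1)).sum() / n_pos)
    specificity = float((~pred_pos & (y == 0)).sum() / n_neg)
    return sensitivity, specificity


def youden_threshold(predictions: PredictionSet) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity - 1."""
    candidates = np.unique(predictions.prob)
    best_t, best_j = 0.5, -np.inf
    for t in candidates:
        if not 0.0 < t < 1.0:
            continue
        sens, spec = sens_spec(predictions, float(t))
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def brier_score(predictions: PredictionSet) -> float:
    """Mean squared difference between predicted probability and outcome."""
    if predictions.n == 0:
        raise ValueError("Brier score of an empty prediction set is undefined")
    p = np.asarray(predictions.prob, dtype=float)
    y = np.asarray(predictions.outcome, dtype=float)
    return float(np.mean((p - y) ** 2))


def hosmer_lemeshow(
    predictions: PredictionSet, g: int = 10, df: int | None = None
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow grouped goodness-of-fit chi-square.

    Patients are sorted by predicted probability and split into ``g``
    near-equal-size groups. For each group the observed event count ``O_g``
    is compared with the expected count ``E_g = sum p``:

        X2 = sum_g (O_g - E_g)^2 / E_g + ((n_g - O_g) - (n_g - E_g))^2 / (n_g - E_g)

    Groups with expected counts of 0 or n_g (which would divide by zero)
    are merged into their neighbour with a warning. ``df`` defaults to
    ``g - 2``, the external-validation convention ``g`` is also accepted.
    """
    if g < 2:
        raise ValueError("need at least 2 groups")
    if predictions.n < g:
        raise ValueError(f"n = {predictions.n} < g = {g} groups")
    p = np.asarray(predictions.prob, dtype=float)
    y = np.asarray(predictions.outcome, dtype=float)
    order = np.argsort(p, kind="stable")
    groups = [idx for idx in np.array_split(order, g) if len(idx)]

    merged = True
    while merged and len(groups) > 1:
        merged = False
        for i, idx in enumerate(groups):
            e = p[idx].sum()
            if e < 1e-9 or (len(idx) - e) < 1e-9:
                j = i + 1 if i + 1 < len(groups) else i - 1
                groups[j] = np.concatenate([groups[j], idx])
                del groups[i]
                warnings.warn(
                    "Hosmer-Lemeshow group with degenerate expected count merged "
                    "into its neighbour",
                    stacklevel=2,
                )
                merged = True
                break

    x2 = 0.0
    for idx in groups:
        n_g = len(idx)
        e_g = p[idx].sum()
        o_g = y[idx].sum()
        x2 += (o_g - e_g) ** 2 / e_g + (o_g - e_g) ** 2 / (n_g - e_g)
    n_groups = len(groups)
    dof = (n_groups - 2) if df is None else df
    dof = max(dof, 1)
    return float(x2), int(dof), float(chi2.sf(x2, dof))


def flexible_calibration_curve(
    predictions: PredictionSet,
    span: float = 0.75,
    grid_size: int = 101,
) -> CalibrationCurve:
    """Locally weighted (lowess) regression of outcome on predicted probability.

    Evaluated on an evenly spaced grid over the observed prediction range and
    truncated to [0, 1]. Robustness iterations are disabled: residuals of a
    binary outcome are Bernoulli, not outlier-contaminated. Requires at least
    20 observations with non-constant predictions.
    """
    if predictions.n < 20:
        raise NTCPError(
            f"flexible calibration needs >= 20 observations, got {predictions.n}; "
            "use grouped observed/expected comparisons instead"
        )
    p = np.asarray(predictions.prob, dtype=float)
    y = np.asarray(predictions.outcome, dtype=float)
    if np.ptp(p) < 1e-12:
        raise NTCPError("flexible calibration undefined for constant predictions")
    grid = np.linspace(p.min(), p.max(), grid_size)
    values = lowess(y, p, frac=span, it=0, xvals=grid)
    return CalibrationCurve(
        grid=grid, values=np.clip(values, 0.0, 1.0), smoother="lowess", span=span
    )


def e_statistics(
    curve: CalibrationCurve, predictions: PredictionSet
) -> tuple[float, float, float]:
    """Emax, Eavg and E90 from a calibration curve.

    Per patient, ``d_i = |p_i - c(p_i)|`` with the curve linearly
    interpolated at each predicted probability; Emax/Eavg/E90 are the
    maximum, mean and 90th linear-interpolation percentile of the ``d_i``.
    Predictions outside the curve grid use the nearest endpoint.
    """
    p = np.asarray(predictions.prob, dtype=float)
    if p.min() < curve.grid[0] - 1e-12 or p.max() > curve.grid[-1] + 1e-12:
        warnings.warn(
            "predictions outside the calibration-curve grid; using nearest endpoint",
            stacklevel=2,
        )
    c_hat = np.interp(p, curve.grid, curve.values)
    d = np.abs(p - c_hat)
    return (
        float(d.max()),
        float(d.mean()),
        float(np.quantile(d, 0.9, method="linear")),
    )


def _roc_points(predictions: PredictionSet, max_points: int = 256) -> dict:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(predictions.outcome, predictions.prob)
    if len(fpr) > max_points:
        keep = np.linspace(0, len(fpr) - 1, max_points).round().astype(int)
        fpr, tpr = fpr[keep], tpr[keep]
    return {"fpr": [float(v) for v in fpr], "tpr": [float(v) for v in tpr]}


def _level_battery(predictions: PredictionSet, config: RunConfig) -> dict:
    if isinstance(config.threshold, str):  # "youden"
        threshold = youden_threshold(predictions)
    else:
        threshold = float(config.threshold)
    sens, spec = sens_spec(predictions, threshold)
    ci = auc_ci(
        predictions,
        level=config.ci_level,
        method=config.ci_method,
        n_resamples=config.bootstrap_resamples,
        seed=config.seed,
    )
    disc = DiscriminationSummary(
        auc=auc(predictions),
        auc_ci=ci,
        sensitivity=sens,
        specificity=spec,
        threshold=threshold,
    )
    x2, dof, p_val = hosmer_lemeshow(predictions, g=config.hl_groups, df=config.hl_df)
    curve = flexible_calibration_curve(
        predictions, span=config.span, grid_size=config.curve_grid_size
    )
    emax, eavg, e90 = e_statistics(curve, predictions)
    cal = CalibrationSummary(
        brier=brier_score(predictions),
        hl_statistic=x2,
        hl_df=dof,
        hl_p=p_val,
        n_groups=config.hl_groups,
        emax=emax,
        eavg=eavg,
        e90=e90,
    )
    return {
        "discrimination": disc.to_dict(),
        "calibration": cal.to_dict(),
        "curve": curve.to_dict(),
        "roc": _roc_points(predictions),
    }


def validation_report(
    model: LogisticModel, cohort: CohortTable, config: RunConfig | None = None
) -> dict:
    """Full external-validation report for one model on one cohort.

    Runs the closed testing procedure, then computes the discrimination and
    calibration battery (AUC with CI, sensitivity/specificity, Brier,
    Hosmer-Lemeshow, calibration curve, E-statistics) for each of the four
    update levels. Deterministic given cohort, model and config.
    """
    config = config or RunConfig()
    ctp = ctp_select(model, cohort, alpha_sig=config.alpha_sig, tree=config.ctp_tree)
    levels = {}
    for level, fit in ctp.fits.items():
        try:
            preds = level_predictions(fit, model, cohort)
            levels[level] = {"params": fit.to_dict(), **_level_battery(preds, config)}
        except NTCPError as exc:
            raise NTCPError(f"metric battery failed at level {level!r}: {exc}") from exc
    return {
        "schema": "ntcpvalid.validation_report/1",
        "config": config.to_dict(),
        "model": model.to_dict(),
        "cohort": {
            "n": int(cohort.n),
            "events": int(cohort.n_events),
            "event_rate": float(cohort.n_events / cohort.n),
        },
        "ctp": ctp.to_dict(),
        "selected": ctp.selected,
        "levels": levels,
    }


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, 2-space indent)."""
    return json.dumps(report, indent=2, sort_keys=True)
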