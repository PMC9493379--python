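"""Model updating via a four-level calibration hierarchy and closed testing.

External validation of a prediction model rarely ends at "good AUC": the
model may be miscalibrated in the new cohort. The standard remedy is a
nested hierarchy of updates of increasing flexibility:

1. ``original``               — the model as published (no free parameters);
2. ``intercept_update``       — re-calibration in the large: a new intercept
   ``alpha`` is estimated with the original linear predictor ``S`` entering
   as a fixed offset (slope fixed at 1);
3. ``logistic_recalibration`` — intercept and one overall slope
   ``(alpha, beta_cal)`` estimated on ``S``;
4. ``revision``               — all predictor coefficients and the intercept
   re-estimated on the validation cohort.

The closed testing procedure (CTP) selects the simplest adequate level while
controlling the family-wise error rate: each simpler level is tested against
the full revision with a likelihood-ratio (LR) test, walking from the
simplest level upward and stopping at the first non-significant test. A
stepwise variant (each level against the next) is available via
``tree="stepwise"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .model import (
    CohortTable,
    FitFailureError,
    LogisticModel,
    PredictionSet,
    log_likelihood,
    predict_ntcp,
)

__all__ = [
    "LEVELS",
    "UpdateFit",
    "LRTest",
    "CTPResult",
    "evaluate_original",
    "fit_intercept_update",
    "fit_logistic_recalibration",
    "fit_revision",
    "lr_test",
    "ctp_select",
    "level_predictions",
]

LEVELS = ("original", "intercept_update", "logistic_recalibration", "revision")

_MAXITER = 100
_TOL = 1e-8
#: LR statistics more negative than this indicate a genuine nesting violation
#: rather than optimizer noise.
_LR_SLACK = 1e-6


@dataclass(frozen=True)
class UpdateFit:
    """One fitted level of the calibration hierarchy.

    ``alpha`` and ``slope`` are the calibration intercept and slope applied
    to the original linear predictor; they are fixed at (0, 1) for the
    original model and (alpha, 1) for the intercept update. The revision
    level re-estimates every coefficient, so its calibration parameters are
    reported as ``None`` and the refitted model is in ``revised_model``.
    """

    level: str
    alpha: float | None
    slope: float | None
    log_lik: float
    n_free_params: int
    revised_model: LogisticModel | None = None
    std_errors: dict[str, float] | None = None  # revision level only

    def to_dict(self) -> dict:
        out = {
            "level": self.level,
            "alpha": None if self.alpha is None else float(self.alpha),
            "slope": None if self.slope is None else float(self.slope),
            "log_lik": float(self.log_lik),
            "n_free_params": int(self.n_free_params),
        }
        if self.revised_model is not None:
            out["revised_model"] = self.revised_model.to_dict()
        if self.std_errors is not None:
            out["std_errors"] = {k: float(v) for k, v in self.std_errors.items()}
        return out


@dataclass(frozen=True)
class LRTest:
    """Likelihood-ratio test of a simpler update level against a richer one."""

    comparison: tuple[str, str]  # (simple level, complex level)
    statistic: float
    df: int
    p_value: float
    used: bool = True  # False when the CTP stopped before this test

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "used": bool(self.used),
        }


@dataclass(frozen=True)
class CTPResult:
    """The four fits, the LR tests performed, and the selected level."""

    fits: dict[str, UpdateFit]
    tests: list[LRTest]
    selected: str
    alpha_sig: float
    tree: str = "revision_anchored"

    @property
    def selected_fit(self) -> UpdateFit:
        return self.fits[self.selected]

    def to_dict(self) -> dict:
        return {
            "fits": {level: fit.to_dict() for level, fit in self.fits.items()},
            "tests": [t.to_dict() for t in self.tests],
            "selected": self.selected,
            "alpha_sig": float(self.alpha_sig),
            "tree": self.tree,
        }


def _check_outcome_mix(y: np.ndarray, level: str) -> None:
    if y.sum() == 0 or y.sum() == len(y):
        raise FitFailureError(
            f"{level}: cohort has no {'events' if y.sum() == 0 else 'non-events'}; "
            "the intercept MLE is not finite"
        )


def _fit_glm(y, exog, offset, level: str):
    glm = sm.GLM(y, exog, family=sm.families.Binomial(), offset=offset)
    with warnings.catch_warnings():
        # expit overflow on diverging coefficients is benign; separation is
        # detected explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = glm.fit(maxiter=_MAXITER, tol=_TOL)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise FitFailureError(f"{level}: perfect separation — {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise FitFailureError(f"{level}: singular IRLS system — {exc}") from exc
    if not res.converged:
        raise FitFailureError(
            f"{level}: IRLS did not converge in {_MAXITER} iterations"
        )
    if np.abs(res.params).max() > 1e3:
        raise FitFailureError(
            f"{level}: runaway coefficients (|beta| > 1e3), likely separation"
        )
    return res


def evaluate_original(model: LogisticModel, cohort: CohortTable) -> UpdateFit:
    """Level 1: the published model evaluated as-is (zero free parameters)."""
    ll = log_likelihood(predict_ntcp(model, cohort))
    return UpdateFit("original", alpha=0.0, slope=1.0, log_lik=ll, n_free_params=0)


def fit_intercept_update(model: LogisticModel, cohort: CohortTable) -> UpdateFit:
    """Level 2: re-calibration in the large.

    The original linear predictor enters as a fixed per-patient offset and
    only a new intercept ``alpha`` is estimated, i.e. the MLE of
    ``y ~ Bernoulli(expit(alpha + S))``. Corrects an overall over- or
    under-estimation of risk without touching discrimination.
    """
    y = cohort.outcome
    _check_outcome_mix(y, "intercept_update")
    S = predict_ntcp(model, cohort).linear
    res = _fit_glm(y, np.ones((cohort.n, 1)), offset=S, level="intercept_update")
    alpha = float(res.params[0])
    ll = log_likelihood(PredictionSet(alpha + S, expit(alpha + S), y))
    return UpdateFit("intercept_update", alpha=alpha, slope=1.0, log_lik=ll, n_free_params=1)


def fit_logistic_recalibration(model: LogisticModel, cohort: CohortTable) -> UpdateFit:
    """Level 3: logistic recalibration.

    Estimates the calibration intercept and slope ``(alpha, beta_cal)``
    jointly: ``y ~ Bernoulli(expit(alpha + beta_cal * S))``. A slope below 1
    indicates predictions that are too extreme in the validation cohort;
    (0, 1) indicates a calibrated model.
    """
    y = cohort.outcome
    _check_outcome_mix(y, "logistic_recalibration")
    S = predict_ntcp(model, cohort).linear
    if np.ptp(S) < 1e-12:
        raise FitFailureError(
            "logistic_recalibration: linear predictor is constant, slope unidentifiable"
        )
    exog = np.column_stack([np.ones_like(S), S])
    res = _fit_glm(y, exog, offset=None, level="logistic_recalibration")
    alpha, slope = (float(v) for v in res.params)
    lin = alpha + slope * S
    ll = log_likelihood(PredictionSet(lin, expit(lin), y))
    return UpdateFit(
        "logistic_recalibration", alpha=alpha, slope=slope, log_lik=ll, n_free_params=2
    )


def _rank_deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # columns with (numerically) zero diagonal in the QR factor are linearly
    # dependent on earlier columns
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in np.nonzero(diag <= tol)[0]]


def fit_revision(
    cohort: CohortTable, predictor_names: tuple[str, ...], name: str = "revised model"
) -> UpdateFit:
    """Level 4: model revision — full logistic refit of all coefficients."""
    y = cohort.outcome
    _check_outcome_mix(y, "revision")
    X = cohort.predictor_matrix(predictor_names)
    design = np.column_stack([np.ones(len(y)), X])
    colnames = ["intercept", *predictor_names]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        offenders = _rank_deficient_columns(design, colnames)
        raise FitFailureError(
            f"revision: design matrix rank deficient; dependent column(s): {offenders}"
        )
    res = _fit_glm(y, design, offset=None, level="revision")
    params = np.asarray(res.params, dtype=float)
    revised = LogisticModel(
        name=name,
        intercept=float(params[0]),
        coefficients={n: float(b) for n, b in zip(predictor_names, params[1:])},
    )
    ll = log_likelihood(predict_ntcp(revised, cohort))
    return UpdateFit(
        "revision",
        alpha=None,
        slope=None,
        log_lik=ll,
        n_free_params=len(predictor_names) + 1,
        revised_model=revised,
        std_errors={n: float(se) for n, se in zip(colnames, res.bse)},
    )


def lr_test(simple: UpdateFit, complex: UpdateFit, used: bool = True) -> LRTest:
    """Likelihood-ratio test of two nested update fits.

    ``statistic = 2 (l_complex - l_simple)``, floored at zero when optimizer
    noise makes it marginally negative; the p-value is the upper tail of the
    chi-square distribution with ``df`` equal to the difference in free
    parameters.
    """
    if LEVELS.index(simple.level) >= LEVELS.index(complex.level):
        raise ValueError(
            f"{simple.level!r} is not nested below {complex.level!r}"
        )
    df = complex.n_free_params - simple.n_free_params
    if df <= 0:
        raise ValueError("complex fit must have strictly more free parameters")
    stat = 2.0 * (complex.log_lik - simple.log_lik)
    if stat < 0.0:
        msg = (
            f"LR statistic {stat:.3g} for {simple.level} vs {complex.level} "
            "is negative; floored to 0"
        )
        if stat < -_LR_SLACK:
            msg += " (beyond optimizer slack — check the fits)"
        warnings.warn(msg, stacklevel=2)
        stat = 0.0
    return LRTest(
        comparison=(simple.level, complex.level),
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        used=used,
    )


def ctp_select(
    model: LogisticModel,
    cohort: CohortTable,
    alpha_sig: float = 0.05,
    tree: str = "revision_anchored",
) -> CTPResult:
    """Run the closed testing procedure and select an update level.

    With the default revision-anchored tree, each simpler level is tested
    against the full revision, walking up from the original model; the first
    non-significant test stops the walk and selects that simpler level. If
    every test is significant the revision is selected. All three tests are
    reported; those past the stopping point are flagged ``used=False``.
    """
    if not 0.0 < alpha_sig < 1.0:
        raise ValueError("alpha_sig must lie strictly in (0, 1)")
    if tree not in ("revision_anchored", "stepwise"):
        raise ValueError(f"unknown CTP tree {tree!r}")

    fits = {
        "original": evaluate_original(model, cohort),
        "intercept_update": fit_intercept_update(model, cohort),
        "logistic_recalibration": fit_logistic_recalibration(model, cohort),
        "revision": fit_revision(cohort, model.predictor_names),
    }

    if tree == "revision_anchored":
        pairs = [
            ("original", "revision"),
            ("intercept_update", "revision"),
            ("logistic_recalibration", "revision"),
        ]
    else:
        pairs = [
            ("original", "intercept_update"),
            ("intercept_update", "logistic_recalibration"),
            ("logistic_recalibration", "revision"),
        ]

    tests: list[LRTest] = []
    selected: str | None = None
    for simple, complex_ in pairs:
        test = lr_test(fits[simple], fits[complex_], used=selected is None)
        tests.append(test)
        if selected is None and test.p_value >= alpha_sig:
            selected = simple
    if selected is None:
        selected = "revision"

    return CTPResult(fits=fits, tests=tests, selected=selected, alpha_sig=alpha_sig, tree=tree)


def level_predictions(
    fit: UpdateFit, model: LogisticModel, cohort: CohortTable
) -> PredictionSet:
    """Per-patient predictions from one update level applied to a cohort."""
    if fit.level == "revision":
        return predict_ntcp(fit.revised_model, cohort)
    S = predict_ntcp(model, cohort).linear
    lin = fit.alpha + fit.slope * S
    return PredictionSet(lin, expit(lin), cohort.outcome)
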