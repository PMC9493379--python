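"""Logistic NTCP models, patient cohorts and per-patient predictions.

A normal tissue complication probability (NTCP) model maps per-patient
dosimetric and clinical predictors to the probability of a radiation-induced
complication through a logistic link:

    S = b0 + sum_j b_j * x_j,        p = 1 / (1 + exp(-S))

where ``S`` is the linear predictor on the log-odds scale. The complication
modelled here is physician-rated grade II-IV dysphagia six months after
(chemo)radiotherapy for head-and-neck cancer. The predictors are the mean
doses (Gy) to the oral cavity and the superior/middle/inferior pharyngeal
constrictor muscles (PCM), a tumour-location indicator (1 = pharynx,
0 = larynx) and a baseline-dysphagia indicator (1 = baseline grade >= 2).

The national indication protocol for proton therapy (NIPP) publishes one
such model for the model-based selection of proton-therapy patients; it
ships with this package as a JSON model spec (see :func:`ntcpvalid.io.load_nipp_model`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PREDICTOR_NAMES",
    "DOSE_PREDICTORS",
    "INDICATOR_PREDICTORS",
    "MODALITIES",
    "PROB_EPS",
    "DEFAULT_DOSE_CEILING",
    "NTCPError",
    "ModelSpecError",
    "CohortError",
    "FitFailureError",
    "LogisticModel",
    "CohortTable",
    "PredictionSet",
    "linear_predictor",
    "predict_ntcp",
    "delta_ntcp",
    "log_likelihood",
]

#: Canonical cohort predictor columns, in model order.
DOSE_PREDICTORS = (
    "dmean_oral_cavity",
    "dmean_pcm_superior",
    "dmean_pcm_medium",
    "dmean_pcm_inferior",
)
INDICATOR_PREDICTORS = ("tumour_location", "baseline_dysphagia")
PREDICTOR_NAMES = DOSE_PREDICTORS + INDICATOR_PREDICTORS

MODALITIES = ("photon", "photon_chemo", "proton")

#: Probabilities are clipped to [PROB_EPS, 1 - PROB_EPS] inside likelihood
#: evaluation so that extreme linear predictors keep the log-likelihood finite.
PROB_EPS = 1e-12

#: Mean doses above this ceiling (Gy) trigger a validation warning: they are
#: implausible for head-and-neck organ-at-risk mean doses but not impossible.
DEFAULT_DOSE_CEILING = 80.0

DEFAULT_CODING = {
    "tumour_location": {"1": "pharynx", "0": "larynx"},
    "baseline_dysphagia": {"1": "baseline grade >= 2", "0": "baseline grade < 2"},
}


class NTCPError(Exception):
    """Base class for ntcpvalid errors."""


class ModelSpecError(NTCPError):
    """A model specification is malformed or incompatible with the data."""


class CohortError(NTCPError):
    """A cohort table violates the complete-case / binary-outcome contract."""


class FitFailureError(NTCPError):
    """A maximum-likelihood fit has no usable solution (degenerate outcome,
    separation, rank deficiency, or non-convergence)."""


@dataclass(frozen=True, eq=False)
class LogisticModel:
    """A logistic model on the log-odds scale: intercept plus named coefficients.

    Parameters
    ----------
    name
        Human-readable label, carried into reports.
    intercept
        Intercept on the log-odds scale.
    coefficients
        Ordered mapping ``predictor name -> log-odds per unit``.
    coding
        Optional documentation of the indicator coding (reference levels).
        Purely descriptive; predictions use the numeric values as stored.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    coding: dict | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise ModelSpecError(f"model {self.name!r}: non-finite intercept")
        if not self.coefficients:
            raise ModelSpecError(f"model {self.name!r}: empty coefficient map")
        for key, value in self.coefficients.items():
            if not math.isfinite(value):
                raise ModelSpecError(
                    f"model {self.name!r}: non-finite coefficient for {key!r}"
                )

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def coefficient_vector(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
        }
        if self.coding is not None:
            out["coding"] = self.coding
        return out

    @classmethod
    def from_dict(cls, spec: Mapping) -> "LogisticModel":
        allowed = {"name", "intercept", "coefficients", "coding"}
        unknown = set(spec) - allowed
        if unknown:
            raise ModelSpecError(f"unknown model-spec fields: {sorted(unknown)}")
        missing = {"name", "intercept", "coefficients"} - set(spec)
        if missing:
            raise ModelSpecError(f"model spec missing fields: {sorted(missing)}")
        try:
            intercept = float(spec["intercept"])
            coefficients = {str(k): float(v) for k, v in spec["coefficients"].items()}
        except (TypeError, ValueError) as exc:
            raise ModelSpecError(f"non-numeric value in model spec: {exc}") from exc
        return cls(
            name=str(spec["name"]),
            intercept=intercept,
            coefficients=coefficients,
            coding=spec.get("coding"),
        )


def _check_predictor_names(model: LogisticModel, available: Iterable[str]) -> None:
    available = set(available)
    wanted = set(model.coefficients)
    missing = sorted(wanted - available)
    extra = sorted(available - wanted)
    if missing or extra:
        raise ModelSpecError(
            f"model {model.name!r} predictor mismatch: "
            f"missing from data {missing or 'none'}, not in model {extra or 'none'}"
        )


REQUIRED_COHORT_COLUMNS = ("patient_id",) + PREDICTOR_NAMES + ("modality", "outcome")


@dataclass(frozen=True, eq=False)
class CohortTable:
    """Complete-case validation cohort: predictors, treatment modality, outcome.

    The outcome is a strict 0/1 indicator (grade II-IV dysphagia at six
    months). Rows with missing values are rejected outright — validation is
    complete-case by contract, never silently imputed.
    """

    data: pd.DataFrame
    dose_ceiling: float = DEFAULT_DOSE_CEILING

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortError(f"cohort missing columns: {missing_cols}")
        if len(df) < 1:
            raise CohortError("cohort is empty")
        na = df[list(REQUIRED_COHORT_COLUMNS)].isna()
        if na.to_numpy().any():
            cells = [
                (int(df.index[i]), na.columns[j])
                for i, j in zip(*np.nonzero(na.to_numpy()))
            ]
            raise CohortError(
                f"missing values (complete cases required) at (row, column): {cells[:10]}"
            )
        for col in ("outcome",) + INDICATOR_PREDICTORS:
            vals = np.asarray(df[col], dtype=float)
            if not np.isin(vals, (0.0, 1.0)).all():
                bad = df.index[~np.isin(vals, (0.0, 1.0))].tolist()
                raise CohortError(
                    f"column {col!r} must be binary 0/1; offending rows: {bad[:10]}"
                )
        doses = df[list(DOSE_PREDICTORS)].to_numpy(dtype=float)
        if not np.isfinite(doses).all() or (doses < 0).any():
            raise CohortError("doses must be finite and non-negative")
        if (doses > self.dose_ceiling).any():
            warnings.warn(
                f"doses above the {self.dose_ceiling:g} Gy plausibility ceiling",
                stacklevel=2,
            )
        bad_mod = set(df["modality"].astype(str)) - set(MODALITIES)
        if bad_mod:
            raise CohortError(f"unknown treatment modality values: {sorted(bad_mod)}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return np.asarray(self.data["outcome"], dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    def predictor_matrix(self, names: Iterable[str] = PREDICTOR_NAMES) -> np.ndarray:
        names = list(names)
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise CohortError(f"cohort lacks predictor columns: {missing}")
        return self.data[names].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.data.loc[mask].reset_index(drop=True), self.dose_ceiling)


@dataclass(frozen=True, eq=False)
class PredictionSet:
    """Per-patient linear predictors, probabilities and outcomes."""

    linear: np.ndarray  # S, log-odds
    prob: np.ndarray  # p = expit(S), unclipped
    outcome: np.ndarray  # y in {0, 1}

    def __post_init__(self) -> None:
        if not (len(self.linear) == len(self.prob) == len(self.outcome)):
            raise ValueError("prediction arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.prob)

    def clipped_prob(self, eps: float = PROB_EPS) -> np.ndarray:
        return np.clip(self.prob, eps, 1.0 - eps)


def linear_predictor(model: LogisticModel, x: Mapping[str, float]) -> float:
    """Evaluate ``S = intercept + sum_j b_j x_j`` for one predictor vector.

    The predictor names of ``x`` must match the model's coefficient names
    exactly; a mismatch raises :class:`ModelSpecError` naming the offending
    predictors.
    """
    _check_predictor_names(model, x.keys())
    s = float(model.intercept)
    for name, coef in model.coefficients.items():
        value = float(x[name])
        if not math.isfinite(value):
            raise ModelSpecError(f"non-finite value for predictor {name!r}")
        s += coef * value
    return s


def predict_ntcp(model: LogisticModel, cohort: CohortTable) -> PredictionSet:
    """Compute per-patient NTCP predictions for a whole cohort."""
    _check_predictor_names(model, [c for c in PREDICTOR_NAMES if c in cohort.data.columns])
    X = cohort.predictor_matrix(model.predictor_names)
    S = model.intercept + X @ model.coefficient_vector()
    return PredictionSet(linear=S, prob=expit(S), outcome=cohort.outcome)


def delta_ntcp(
    model: LogisticModel, x_photon: Mapping[str, float], x_proton: Mapping[str, float]
) -> float:
    """NTCP difference between a photon and a proton treatment plan.

    Positive values mean the proton plan is predicted to spare toxicity; the
    model-based approach selects patients for proton therapy when this
    difference exceeds a protocol threshold.
    """
    p_photon = expit(linear_predictor(model, x_photon))
    p_proton = expit(linear_predictor(model, x_proton))
    return float(p_photon - p_proton)


def log_likelihood(predictions: PredictionSet, eps: float = PROB_EPS) -> float:
    """Bernoulli log-likelihood ``sum_i y_i ln p_i + (1 - y_i) ln(1 - p_i)``.

    Probabilities are clipped to ``[eps, 1 - eps]`` so the result is always
    finite. This is the quantity differenced by the likelihood-ratio tests of
    the closed testing procedure.
    """
    if predictions.n == 0:
        raise ValueError("log-likelihood of an empty prediction set is undefined")
    p = predictions.clipped_prob(eps)
    y = np.asarray(predictions.outcome, dtype=float)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
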