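"""Synthetic dysphagia cohorts with configurable truth and miscalibration.

Real validation cohorts of head-and-neck radiotherapy patients cannot be
shared, so this module generates cohorts with the same statistical shape:

* treatment modality drawn from a photon / photon+chemo / proton mix
  (default 204 / 59 / 14 out of 277);
* the four organ-at-risk mean doses drawn from a Gaussian copula — a latent
  equicorrelated standard normal is mapped through the inverse CDF of each
  arm's truncated-normal marginal on [0, dose ceiling], so the marginals are
  exactly the configured (truncated) means/SDs while the doses remain
  positively correlated, as anatomy dictates;
* tumour-location and baseline-dysphagia indicators drawn as independent
  Bernoulli variables (default prevalences 0.68 and 0.15);
* the binary outcome drawn from a configurable *truth* model, optionally
  distorted by a :class:`MiscalibrationSpec` — an intercept shift ``delta``
  (what re-calibration in the large corrects), a slope factor ``gamma``
  (what logistic recalibration corrects) and per-coefficient overrides
  (what only a full revision corrects).

Everything is a deterministic function of the recipe, including the seed.
Draw order (fixed, documented for reproducibility): modality, latent dose
normals, tumour location, baseline dysphagia, outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import truncnorm

from .model import (
    DEFAULT_DOSE_CEILING,
    DOSE_PREDICTORS,
    CohortTable,
    FitFailureError,
    LogisticModel,
    ModelSpecError,
    NTCPError,
)
from .updating import LEVELS, ctp_select

__all__ = [
    "PHOTON_DOSE_MARGINALS",
    "PROTON_DOSE_MARGINALS",
    "DEFAULT_MODALITY_MIX",
    "DEVELOPMENT_BASELINE_PREVALENCE",
    "MiscalibrationSpec",
    "CohortRecipe",
    "apply_miscalibration",
    "generate_cohort",
    "SelectionFrequencies",
    "ctp_selection_frequencies",
]

#: (mean Gy, SD Gy) of the organ-at-risk mean doses by treatment arm.
PHOTON_DOSE_MARGINALS: dict[str, tuple[float, float]] = {
    "dmean_oral_cavity": (33.2, 15.4),
    "dmean_pcm_superior": (55.5, 17.7),
    "dmean_pcm_medium": (50.2, 17.4),
    "dmean_pcm_inferior": (38.2, 19.9),
}
PROTON_DOSE_MARGINALS: dict[str, tuple[float, float]] = {
    "dmean_oral_cavity": (24.1, 11.9),
    "dmean_pcm_superior": (35.1, 8.3),
    "dmean_pcm_medium": (41.2, 12.6),
    "dmean_pcm_inferior": (37.5, 17.9),
}

DEFAULT_MODALITY_MIX: dict[str, float] = {
    "photon": 204 / 277,
    "photon_chemo": 59 / 277,
    "proton": 14 / 277,
}

#: Baseline-dysphagia prevalence reported for the model's development
#: cohort; useful as a preset to emulate the case-mix shift between
#: development and validation populations.
DEVELOPMENT_BASELINE_PREVALENCE = 0.25


@dataclass(frozen=True)
class MiscalibrationSpec:
    """A controlled departure of the data-generating truth from a model.

    The outcome probability becomes ``expit(gamma * S + delta)`` after any
    coefficient overrides, where ``S`` is the model's linear predictor.
    The identity spec (delta 0, gamma 1, no overrides) leaves the model
    unchanged.
    """

    delta_intercept: float = 0.0
    slope_factor: float = 1.0
    coefficient_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slope_factor > 0.0:
            raise ValueError("slope_factor must be > 0")

    def to_dict(self) -> dict:
        return {
            "delta_intercept": float(self.delta_intercept),
            "slope_factor": float(self.slope_factor),
            "coefficient_overrides": {
                k: float(v) for k, v in self.coefficient_overrides.items()
            },
        }

    @classmethod
    def from_dict(cls, spec: Mapping) -> "MiscalibrationSpec":
        return cls(
            delta_intercept=float(spec.get("delta_intercept", 0.0)),
            slope_factor=float(spec.get("slope_factor", 1.0)),
            coefficient_overrides=dict(spec.get("coefficient_overrides", {})),
        )


def apply_miscalibration(
    model: LogisticModel, spec: MiscalibrationSpec
) -> LogisticModel:
    """Return the model distorted by a miscalibration spec.

    Coefficients are scaled by the slope factor, the intercept becomes
    ``gamma * intercept + delta``, then coefficient overrides replace
    individual (already-scaled) coefficients. Overriding a predictor the
    model does not contain is an error.
    """
    unknown = set(spec.coefficient_overrides) - set(model.coefficients)
    if unknown:
        raise ModelSpecError(
            f"overrides reference unknown predictors: {sorted(unknown)}"
        )
    coefficients = {
        name: spec.slope_factor * value for name, value in model.coefficients.items()
    }
    coefficients.update({k: float(v) for k, v in spec.coefficient_overrides.items()})
    return LogisticModel(
        name=model.name,
        intercept=spec.slope_factor * model.intercept + spec.delta_intercept,
        coefficients=coefficients,
        coding=model.coding,
    )


def _default_truth() -> LogisticModel:
    from .io import load_nipp_model

    return load_nipp_model()


@dataclass(frozen=True, eq=False)
class CohortRecipe:
    """Generative parameters for one synthetic cohort."""

    n: int = 277
    modality_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_MIX)
    )
    dose_marginals: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "photon": dict(PHOTON_DOSE_MARGINALS),
            "proton": dict(PROTON_DOSE_MARGINALS),
        }
    )
    dose_correlation: float = 0.4
    p_pharynx: float = 0.68
    p_baseline_dysphagia: float = 0.15
    truth: LogisticModel | None = None  # None -> packaged NIPP dysphagia model
    miscalibration: MiscalibrationSpec = field(default_factory=MiscalibrationSpec)
    seed: int = 0
    dose_ceiling: float = DEFAULT_DOSE_CEILING

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if set(self.modality_mix) != {"photon", "photon_chemo", "proton"}:
            raise ValueError("modality_mix must cover photon/photon_chemo/proton")
        if abs(sum(self.modality_mix.values()) - 1.0) > 1e-9:
            raise ValueError("modality_mix proportions must sum to 1")
        if any(v < 0 for v in self.modality_mix.values()):
            raise ValueError("modality_mix proportions must be non-negative")
        for arm in ("photon", "proton"):
            if arm not in self.dose_marginals:
                raise ValueError(f"dose_marginals missing arm {arm!r}")
            for oar in DOSE_PREDICTORS:
                mean, sd = self.dose_marginals[arm][oar]
                if sd <= 0:
                    raise ValueError(f"SD for {arm}/{oar} must be > 0, got {sd}")
                if not 0 <= mean <= self.dose_ceiling:
                    raise ValueError(f"mean for {arm}/{oar} outside [0, ceiling]")
        if not 0.0 <= self.dose_correlation <= 0.95:
            raise ValueError("dose_correlation must lie in [0, 0.95]")
        for name in ("p_pharynx", "p_baseline_dysphagia"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")

    def resolved_truth(self) -> LogisticModel:
        return self.truth if self.truth is not None else _default_truth()

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "modality_mix": {k: float(v) for k, v in self.modality_mix.items()},
            "dose_marginals": {
                arm: {oar: [float(m), float(s)] for oar, (m, s) in margins.items()}
                for arm, margins in self.dose_marginals.items()
            },
            "dose_correlation": float(self.dose_correlation),
            "p_pharynx": float(self.p_pharynx),
            "p_baseline_dysphagia": float(self.p_baseline_dysphagia),
            "truth": None if self.truth is None else self.truth.to_dict(),
            "miscalibration": self.miscalibration.to_dict(),
            "seed": int(self.seed),
            "dose_ceiling": float(self.dose_ceiling),
        }

    @classmethod
    def from_dict(cls, spec: Mapping) -> "CohortRecipe":
        kwargs: dict = {}
        for key in (
            "n",
            "dose_correlation",
            "p_pharynx",
            "p_baseline_dysphagia",
            "seed",
            "dose_ceiling",
        ):
            if key in spec:
                kwargs[key] = spec[key]
        if "modality_mix" in spec:
            kwargs["modality_mix"] = {k: float(v) for k, v in spec["modality_mix"].items()}
        if "dose_marginals" in spec:
            kwargs["dose_marginals"] = {
                arm: {oar: (float(ms[0]), float(ms[1])) for oar, ms in margins.items()}
                for arm, margins in spec["dose_marginals"].items()
            }
        if spec.get("truth") is not None:
            kwargs["truth"] = LogisticModel.from_dict(spec["truth"])
        if "miscalibration" in spec:
            kwargs["miscalibration"] = MiscalibrationSpec.from_dict(
                spec["miscalibration"]
            )
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CohortRecipe":
        return cls.from_dict(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _truncnorm_ppf(u: np.ndarray, mean: np.ndarray, sd: np.ndarray, hi: float) -> np.ndarray:
    a = (0.0 - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_cohort(recipe: CohortRecipe) -> CohortTable:
    """Draw one synthetic cohort; a pure function of the recipe (incl. seed)."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n
    modalities = np.array(["photon", "photon_chemo", "proton"])
    modality = rng.choice(
        modalities, size=n, p=[recipe.modality_mix[m] for m in modalities]
    )

    # Gaussian copula: equicorrelated latent normals -> uniforms -> exact
    # truncated-normal marginals per treatment arm.
    k = len(DOSE_PREDICTORS)
    corr = np.full((k, k), recipe.dose_correlation)
    np.fill_diagonal(corr, 1.0)
    z = rng.standard_normal((n, k)) @ np.linalg.cholesky(corr).T
    u = ndtr(z)
    is_proton = modality == "proton"
    doses = np.empty((n, k))
    for j, oar in enumerate(DOSE_PREDICTORS):
        mean = np.where(
            is_proton,
            recipe.dose_marginals["proton"][oar][0],
            recipe.dose_marginals["photon"][oar][0],
        )
        sd = np.where(
            is_proton,
            recipe.dose_marginals["proton"][oar][1],
            recipe.dose_marginals["photon"][oar][1],
        )
        doses[:, j] = _truncnorm_ppf(u[:, j], mean, sd, recipe.dose_ceiling)

    tumour_location = (rng.random(n) < recipe.p_pharynx).astype(int)
    baseline = (rng.random(n) < recipe.p_baseline_dysphagia).astype(int)

    df = pd.DataFrame(doses, columns=list(DOSE_PREDICTORS))
    df.insert(0, "patient_id", [f"SYN-{i:05d}" for i in range(n)])
    df["tumour_location"] = tumour_location
    df["baseline_dysphagia"] = baseline
    df["modality"] = modality
    df["outcome"] = 0  # placeholder until the truth model is applied

    effective = apply_miscalibration(recipe.resolved_truth(), recipe.miscalibration)
    X = df[list(effective.predictor_names)].to_numpy(dtype=float)
    p_true = expit(effective.intercept + X @ effective.coefficient_vector())
    df["outcome"] = (rng.random(n) < p_true).astype(int)
    return CohortTable(df, dose_ceiling=recipe.dose_ceiling)


@dataclass(frozen=True)
class SelectionFrequencies:
    """Monte-Carlo selection frequencies of the closed testing procedure."""

    counts: dict[str, int]
    n_failures: int
    reps: int
    alpha_sig: float

    @property
    def proportions(self) -> dict[str, float]:
        return {level: self.counts[level] / self.reps for level in LEVELS}

    def mc_standard_error(self, level: str) -> float:
        p = self.counts[level] / self.reps
        return float(np.sqrt(p * (1.0 - p) / self.reps))

    @property
    def modal_level(self) -> str:
        return max(LEVELS, key=lambda lv: self.counts[lv])

    def to_dict(self) -> dict:
        return {
            "counts": {lv: int(self.counts[lv]) for lv in LEVELS},
            "proportions": {lv: float(p) for lv, p in self.proportions.items()},
            "mc_standard_errors": {lv: self.mc_standard_error(lv) for lv in LEVELS},
            "n_failures": int(self.n_failures),
            "reps": int(self.reps),
            "alpha_sig": float(self.alpha_sig),
        }


def ctp_selection_frequencies(
    recipe: CohortRecipe,
    reps: int,
    alpha_sig: float = 0.05,
    model: LogisticModel | None = None,
) -> SelectionFrequencies:
    """Replicate generate-then-select and tabulate the chosen levels.

    ``model`` is the model being evaluated by the CTP (default: the recipe's
    truth before miscalibration — the published model under test). Per-rep
    seeds are derived from the recipe seed by a counter-based scheme
    (``numpy.random.SeedSequence.generate_state``), so replicates are
    independent and individually reproducible. Fit failures are counted
    separately, never silently dropped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    evaluated = model if model is not None else recipe.resolved_truth()
    child_seeds = np.random.SeedSequence(recipe.seed).generate_state(reps)
    counts = {level: 0 for level in LEVELS}
    failures = 0
    for r in range(reps):
        rep_recipe = replace(recipe, seed=int(child_seeds[r]))
        try:
            cohort = generate_cohort(rep_recipe)
            result = ctp_select(evaluated, cohort, alpha_sig=alpha_sig)
        except (FitFailureError, NTCPError):
            failures += 1
            continue
        counts[result.selected] += 1
    return SelectionFrequencies(
        counts=counts, n_failures=failures, reps=reps, alpha_sig=alpha_sig
    )
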