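"""Reading and writing cohort CSVs, model specs and reports.

Cohort files are plain UTF-8 CSVs with a header row and "." decimals:

    patient_id,dmean_oral_cavity,dmean_pcm_superior,dmean_pcm_medium,
    dmean_pcm_inferior,tumour_location,baseline_dysphagia,modality,outcome

Doses are in Gy; ``tumour_location`` (1 = pharynx), ``baseline_dysphagia``
(1 = baseline grade >= 2) and ``outcome`` are strict 0/1 indicators;
``modality`` is one of photon / photon_chemo / proton. Missing cells are
rejected with their (row, column) coordinates — validation is complete-case,
never imputed.

Model specs are JSON objects ``{name, intercept, coefficients, coding}``;
the NIPP grade II-IV dysphagia model ships with the package.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .model import (
    CohortError,
    CohortTable,
    LogisticModel,
    ModelSpecError,
    REQUIRED_COHORT_COLUMNS,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_model",
    "write_model",
    "load_nipp_model",
    "RunConfig",
]

_PACKAGED_MODEL = "nipp_dysphagia_grade2_6m.json"


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV.

    Raises :class:`CohortError` naming the offending rows/columns on any
    missing value, non-binary indicator or unknown modality.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise CohortError(f"could not parse cohort CSV {path}: {exc}") from exc
    missing_cols = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort {path} missing columns: {missing_cols}")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical column order."""
    cohort.data[list(REQUIRED_COHORT_COLUMNS)].to_csv(path, index=False)


def read_model(path: str | Path) -> LogisticModel:
    """Read a logistic model spec from JSON; unknown fields are rejected."""
    path = Path(path)
    if not path.exists():
        raise ModelSpecError(f"model spec not found: {path}")
    try:
        spec = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelSpecError(f"malformed JSON in {path}: {exc}") from exc
    model = LogisticModel.from_dict(spec)
    if not math.isfinite(model.intercept):
        raise ModelSpecError(f"non-finite intercept in {path}")
    return model


def write_model(model: LogisticModel, path: str | Path) -> None:
    """Write a model spec as JSON (lossless round trip)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def load_nipp_model() -> LogisticModel:
    """The packaged NIPP grade II-IV dysphagia model (primary setting)."""
    text = resources.files("ntcpvalid.data").joinpath(_PACKAGED_MODEL).read_text()
    return LogisticModel.from_dict(json.loads(text))
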