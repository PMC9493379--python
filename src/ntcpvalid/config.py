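"""Run configuration shared by the report builder and the CLI."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RunConfig:
    """Resolved analysis settings, embedded verbatim in every report.

    ``threshold`` is either a probability in (0, 1) used to dichotomise
    predictions for sensitivity/specificity, or the string ``"youden"`` to
    pick the threshold maximising sensitivity + specificity - 1 (the chosen
    threshold is always reported alongside the metrics).
    """

    alpha_sig: float = 0.05
    hl_groups: int = 10
    hl_df: int | None = None  # None -> hl_groups - 2
    threshold: float | str = 0.5
    span: float = 0.75
    curve_grid_size: int = 101
    ci_method: str = "delong"  # or "bootstrap"
    ci_level: float = 0.95
    bootstrap_resamples: int = 2000
    ctp_tree: str = "revision_anchored"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_sig < 1.0:
            raise ValueError("alpha_sig must be in (0, 1)")
        if self.hl_groups < 2:
            raise ValueError("hl_groups must be >= 2")
        if isinstance(self.threshold, str):
            if self.threshold != "youden":
                raise ValueError("threshold must be a probability or 'youden'")
        elif not 0.0 < float(self.threshold) < 1.0:
            raise ValueError("numeric threshold must be in (0, 1)")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if self.ci_method not in ("delong", "bootstrap"):
            raise ValueError("ci_method must be 'delong' or 'bootstrap'")
        if not 0.5 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0.5, 1)")

    def to_dict(self) -> dict:
        return {
            "alpha_sig": float(self.alpha_sig),
            "hl_groups": int(self.hl_groups),
            "hl_df": None if self.hl_df is None else int(self.hl_df),
            "threshold": self.threshold
            if isinstance(self.threshold, str)
            else float(self.threshold),
            "span": float(self.span),
            "curve_grid_size": int(self.curve_grid_size),
            "ci_method": self.ci_method,
            "ci_level": float(self.ci_level),
            "bootstrap_resamples": int(self.bootstrap_resamples),
            "ctp_tree": self.ctp_tree,
            "seed": int(self.seed),
            "verbosity": int(self.verbosity),
        }
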