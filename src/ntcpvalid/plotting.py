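"""Plots derived from a validation report (the JSON is the source of truth)."""

from __future__ import annotations

from pathlib import Path

from .updating import LEVELS

_LEVEL_LABELS = {
    "original": "Original model",
    "intercept_update": "Re-calibration in the large",
    "logistic_recalibration": "Logistic recalibration",
    "revision": "Model revision",
}


def plot_calibration_curves(report: dict, path: str | Path) -> None:
    """Calibration curves (smoothed observed vs predicted) for all levels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="Ideal")
    for level in LEVELS:
        curve = report["levels"][level]["curve"]
        ax.plot(curve["grid"], curve["values"], label=_LEVEL_LABELS[level])
    ax.set_xlabel("Predicted NTCP")
    ax.set_ylabel("Smoothed observed proportion")
    ax.set_title("Calibration of the CTP update levels")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc_curves(report: dict, path: str | Path) -> None:
    """ROC curves for all update levels, AUC in the legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    for level in LEVELS:
        entry = report["levels"][level]
        roc = entry["roc"]
        auc_value = entry["discrimination"]["auc"]
        ax.plot(roc["fpr"], roc["tpr"], label=f"{_LEVEL_LABELS[level]} (AUC {auc_value:.2f})")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title("Discrimination of the CTP update levels")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
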