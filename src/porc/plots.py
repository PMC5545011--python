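"""Simple ROC and risk-curve figures."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .diagnostics import RocResult
from .risk import RiskCurve


def plot_roc(curves: Mapping[str, RocResult], path: str | Path,
             title: str = "ROC") -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, rc in curves.items():
        ax.plot(rc.fpr, rc.tpr, marker="o", ms=3,
                label=f"{label} (AUC = {rc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_risk_curves(curves: Mapping[str, RiskCurve], path: str | Path,
                     title: str = "Risk of overlooking residual block") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, rc in curves.items():
        (line,) = ax.plot(rc.prevalence, rc.risk, label=label)
        if rc.lower is not None and rc.upper is not None:
            ax.fill_between(rc.prevalence, rc.lower, rc.upper,
                            color=line.get_color(), alpha=0.15)
    ax.set_xlabel("prevalence of residual block")
    ax.set_ylabel("P(block | tool passes)")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
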