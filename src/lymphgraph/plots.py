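"""Optional figure export: ROC curves, decision curves, training history.

Thin matplotlib wrappers over the evaluation tables; every function takes
already-computed data and writes one PNG. Nothing in the pipeline depends
on these — tabular CSV/JSON artifacts are the primary outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_roc(curves: dict[str, pd.DataFrame], aucs: dict[str, float], path: str | Path) -> Path:
    """Overlayed ROC curves, one per model, AUC in the legend."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, df in curves.items():
        ax.plot(df["fpr"], df["tpr"], label=f"{name} (AUC {aucs[name]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_decision_curves(dca_by_model: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Net benefit vs threshold probability with treat-all / treat-none."""
    fig, ax = plt.subplots(figsize=(6, 4))
    first = next(iter(dca_by_model.values()))
    ax.plot(first["p_t"], first["net_benefit_all"], color="gray", lw=1, label="treat all")
    ax.plot(first["p_t"], first["net_benefit_none"], color="black", lw=1, label="treat none")
    for name, df in dca_by_model.items():
        ax.plot(df["p_t"], df["net_benefit_model"], label=name)
    ax.set_ylim(bottom=-0.05)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_history(history, path: str | Path) -> Path:
    """Training/monitor loss and accuracy curves for one model."""
    epochs = np.arange(len(history.train_loss))
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(epochs, history.train_loss, label="train")
    ax1.plot(epochs, history.mask_loss, label="early-stop mask")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("cross-entropy")
    ax1.legend(fontsize=8)
    ax2.plot(epochs, history.train_acc, label="train")
    ax2.plot(epochs, history.mask_acc, label="early-stop mask")
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("accuracy")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
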