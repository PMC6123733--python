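"""Static plot writers (PNG/SVG/PDF) for the CLI engines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_growth_fit",
    "plot_pred_scatter",
    "plot_roc",
    "plot_accuracy_by_size",
    "plot_embedding",
]


def _save(fig, outdir, stem, formats):
    paths = []
    for fmt in formats:
        p = Path(outdir) / f"{stem}.{fmt}"
        fig.savefig(p, dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths


def plot_growth_fit(fit, outdir, stem, formats=("png",)):
    tr = fit.trajectory
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(tr.times, tr.values, "o", color="0.3", label="observed")
    grid = np.linspace(tr.times[0] if fit.model_id != "bell_loggauss"
                       else max(tr.times[0], 1e-6), tr.times[-1], 200)
    ax.plot(grid, fit.predict(grid), "-", color="tab:green",
            label=f"{fit.model_id} (R²={fit.rsquared_original:.3f})")
    ax.set_xlabel("day")
    ax.set_ylabel("trait value")
    ax.legend(frameon=False)
    fig.tight_layout()
    return _save(fig, outdir, stem, formats)


def plot_pred_scatter(observed, predicted, outdir, stem, formats=("png",)):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(observed, predicted, s=12, alpha=0.6)
    lo, hi = min(np.min(observed), np.min(predicted)), max(np.max(observed), np.max(predicted))
    ax.plot([lo, hi], [lo, hi], "--", color="0.5")
    ax.set_xlabel("observed")
    ax.set_ylabel("predicted")
    fig.tight_layout()
    return _save(fig, outdir, stem, formats)


def plot_roc(roc_points, auc, outdir, stem, formats=("png",)):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc_points[:, 0], roc_points[:, 1], "-", label=f"AUC={auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="0.5")
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(frameon=False)
    fig.tight_layout()
    return _save(fig, outdir, stem, formats)


def plot_accuracy_by_size(accuracy_by_size, outdir, stem, formats=("png",)):
    sizes = sorted(accuracy_by_size)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([accuracy_by_size[s] for s in sizes],
               tick_labels=[str(s) for s in sizes])
    ax.set_xlabel("number of features")
    ax.set_ylabel("cross-validation accuracy")
    fig.tight_layout()
    return _save(fig, outdir, stem, formats)


def plot_embedding(result, outdir, stem, formats=("png",), labels=None):
    coords = result.coordinates
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if labels is not None:
        for lab in sorted(set(labels)):
            idx = [i for i, l in enumerate(labels) if l == lab]
            ax.scatter(coords[idx, 0], coords[idx, 1], s=14, label=str(lab))
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(coords[:, 0], coords[:, 1], s=14)
    ax.set_xlabel(f"{result.method} 1")
    ax.set_ylabel(f"{result.method} 2")
    fig.tight_layout()
    return _save(fig, outdir, stem, formats)
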