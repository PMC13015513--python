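"""Diagnostic plots: M-A scatters and the noise-cutoff density crossing."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

__all__ = ["ma_plot", "noise_density_plot"]


def ma_plot(M: np.ndarray, A: np.ndarray, highlight: np.ndarray,
            path: str | Path, highlight_label: str = "removed") -> None:
    """Scatter of M vs A with a highlighted subset (outliers or calls)."""
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    highlight = np.asarray(highlight, dtype=bool)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(A[~highlight], M[~highlight], s=6, alpha=0.5, color="#4477aa",
               label="kept" if highlight_label == "removed" else "unchanged")
    if highlight.any():
        ax.scatter(A[highlight], M[highlight], s=10, alpha=0.8, color="#cc3311",
                   label=highlight_label)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("A (mean log2 signal)")
    ax.set_ylabel("M (log2 target/control)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def noise_density_plot(bg_log2: np.ndarray, sig_log2: np.ndarray,
                       log2_cutoff: float | None, path: str | Path) -> None:
    """Background vs signal log2 densities with the estimated crossing."""
    bg_log2 = np.asarray(bg_log2, dtype=float)
    sig_log2 = np.asarray(sig_log2, dtype=float)
    grid = np.linspace(min(bg_log2.min(), sig_log2.min()) - 1,
                       max(bg_log2.max(), sig_log2.max()) + 1, 512)
    fig, ax = plt.subplots(figsize=(5, 4))
    for vals, label, color in ((bg_log2, "background", "#4477aa"),
                               (sig_log2, "signal", "#cc3311")):
        if vals.std(ddof=0) > 1e-12:
            ax.plot(grid, stats.gaussian_kde(vals, bw_method="silverman")(grid),
                    color=color, label=label)
    if log2_cutoff is not None:
        ax.axvline(log2_cutoff, color="black", lw=1.0, ls="--",
                   label=f"noise cutoff (log2 = {log2_cutoff:.2f})")
    ax.set_xlabel("log2(signal + pseudocount)")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
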