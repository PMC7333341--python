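"""Agreement plots: Bland-Altman scatter, regression LoA band, histograms.

Axis convention throughout: x is the pairwise average A, y is the
difference D (first-listed method minus second).  The regression band is
drawn over the observed range of A only; no extrapolation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .agreement import BAStats, PairedScores, RegLoA, differences_and_means

__all__ = ["ba_plot", "regression_loa_plot", "difference_histogram"]


def ba_plot(pair: PairedScores, stats: BAStats, path) -> None:
    """Bland-Altman scatter with horizontal mean-difference and LoA lines."""
    D, A = differences_and_means(pair)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(A, D, s=14, alpha=0.6, edgecolors="none")
    ax.axhline(stats.d, color="k", lw=1.2, label=f"d = {stats.d:.1f}")
    for y, lab in ((stats.loa_upper, f"upper LoA = {stats.loa_upper:.1f}"),
                   (stats.loa_lower, f"lower LoA = {stats.loa_lower:.1f}")):
        ax.axhline(y, color="k", lw=0.9, ls="--", label=lab)
    ax.set_xlabel(f"average of {pair.method_a} and {pair.method_b}")
    ax.set_ylabel(f"{pair.method_a} − {pair.method_b}")
    ax.set_title(stats.comparison)
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def regression_loa_plot(pair: PairedScores, reg: RegLoA, path) -> None:
    """Bland-Altman scatter with the sloped regression-based LoA band."""
    D, A = differences_and_means(pair)
    grid = np.linspace(A.min(), A.max(), 100)
    lower, center, upper = reg.loa_band(grid)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(A, D, s=14, alpha=0.6, edgecolors="none")
    ax.plot(grid, center, "k-", lw=1.2,
            label=f"D = {reg.b1:.2f}·A + {reg.b0:.2f}")
    ax.plot(grid, upper, "k--", lw=0.9, label=f"± {reg.z:.2f}·SDres ({reg.sd_res:.2f})")
    ax.plot(grid, lower, "k--", lw=0.9)
    ax.set_xlabel(f"average of {pair.method_a} and {pair.method_b}")
    ax.set_ylabel(f"{pair.method_a} − {pair.method_b}")
    ax.set_title(f"{pair.label} (regression LoA)")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def difference_histogram(pair: PairedScores, path, bins: int = 15) -> None:
    """Histogram of the paired differences, for normality inspection."""
    D, _ = differences_and_means(pair)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.hist(D, bins=bins, edgecolor="white")
    ax.set_xlabel(f"{pair.method_a} − {pair.method_b}")
    ax.set_ylabel("count")
    ax.set_title(f"differences: {pair.label}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
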