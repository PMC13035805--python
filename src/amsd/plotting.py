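"""Best-effort figures: null-distance histograms, volcano plots, exposure bars.

Numeric outputs are the contract; plots exist for inspection only.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import AmsdResult
from .screening import ScreenTable


def plot_null_histogram(result: AmsdResult, path, bins: int = 40) -> None:
    """Histogram of the permutation null with the observed distance marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(result.null_distances, bins=bins, color="0.6", edgecolor="white")
    ax.axvline(result.observed_distance, color="seagreen", lw=2, label="observed")
    ax.set_xlabel(f"{result.distance_name} distance")
    ax.set_ylabel("permutations")
    p_text = result.summary()["p_text"]
    ax.set_title(f"d = {result.observed_distance:.3g}, p {'=' if not result.p_floored else ''} {p_text}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_screen_volcano(table: ScreenTable, path) -> None:
    """-log10(p) vs observed distance, with Bonferroni and BH threshold lines."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    d = [r.observed_distance for r in table.records]
    logp = [
        -math.log10(r.raw_p if not r.p_floored else 1.0 / r.result.n_permutations)
        for r in table.records
    ]
    ax.scatter(d, logp, s=18, color="steelblue")
    ax.axhline(-math.log10(table.alpha), ls=":", color="0.5", label=f"p = {table.alpha}")
    if np.isfinite(table.bonferroni_threshold):
        ax.axhline(table.bonferroni_threshold, ls="--", color="firebrick", label="Bonferroni")
    if table.bh_regression is not None:
        ax.axhline(table.bh_regression[2], ls="--", color="darkorange", label="BH (regression)")
    ax.set_xlabel("observed distance")
    ax.set_ylabel("-log10 raw p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_channel_volcano(table, path) -> None:
    """Per-channel rank-sum volcano: -log10 raw p vs mean frequency difference."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(table["mean_freq_diff"], -np.log10(table["raw_p"]), s=14, color="steelblue")
    ax.axhline(-math.log10(0.05), ls=":", color="0.5")
    ax.set_xlabel("mean frequency difference (A - B)")
    ax.set_ylabel("-log10 raw p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
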