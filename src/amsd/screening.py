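"""Multi-comparison screening: batched AMSD tests with multiple-testing control.

A screen runs many AMSD comparisons (e.g. each carcinogen-exposed tumor group
against tissue-matched controls, or each cancer type across ancestry pairs),
skips comparisons where either group is undersized, and adjusts raw
permutation p-values by Bonferroni and Benjamini–Hochberg across the executed
comparisons. For volcano plots it also fits the regression-estimated BH
threshold: the slope beta of -log10(adjusted p) on -log10(raw p) gives the
significance line at -log10(alpha) * beta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AmsdResult, amsd_test
from .spectra import SpectrumMatrix


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def bh_threshold_regression(raw_p, adjusted_p, alpha: float = 0.05) -> tuple[float, float, float]:
    """Estimate the volcano-plot BH threshold by regression.

    Ordinary least squares (free intercept) of y = -log10(adjusted p) on
    x = -log10(raw p); returns (slope beta, R^2, threshold = -log10(alpha)*beta).
    Zero or non-finite p-values (e.g. floored permutation p's) are excluded,
    with a warning, since their logs are undefined.
    """
    raw_p = np.asarray(raw_p, dtype=float)
    adjusted_p = np.asarray(adjusted_p, dtype=float)
    if raw_p.shape != adjusted_p.shape:
        raise ValueError("raw and adjusted vectors differ in length")
    ok = (raw_p > 0) & (adjusted_p > 0) & np.isfinite(raw_p) & np.isfinite(adjusted_p)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero/non-finite p-values from BH regression")
    x = -np.log10(raw_p[ok])
    y = -np.log10(adjusted_p[ok])
    if x.size < 2:
        raise ValueError("need at least two usable p-value pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all raw p-values equal")
    fit = stats.linregress(x, y)
    beta = float(fit.slope)
    r2 = float(fit.rvalue**2)
    return beta, r2, float(-math.log10(alpha) * beta)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Uses the probability-mass convention: the sum over hypergeometric tables
    whose probability does not exceed the observed table's.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cells must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


@dataclass
class ComparisonRecord:
    """One executed AMSD comparison within a screen."""

    comparison_id: str
    label_a: str
    label_b: str
    group_sizes: tuple[int, int]
    observed_distance: float
    raw_p: float
    p_floored: bool
    bh_p: float = float("nan")
    bonferroni_p: float = float("nan")
    result: AmsdResult | None = None


@dataclass
class ScreenTable:
    """All executed comparisons plus screen-wide thresholds.

    ``bonferroni_threshold`` is -log10(alpha / n_comparisons), the volcano
    FWER line; ``bh_regression`` holds (beta, R^2, threshold) from
    :func:`bh_threshold_regression`, or None when too few comparisons ran.
    Skipped comparisons (undersized groups) are listed with reasons.
    """

    records: list[ComparisonRecord]
    skipped: list[tuple[str, str]]
    n_comparisons: int
    alpha: float
    bonferroni_threshold: float
    bh_regression: tuple[float, float, float] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "comparison": [r.comparison_id for r in self.records],
                "group_a": [r.label_a for r in self.records],
                "group_b": [r.label_b for r in self.records],
                "n_a": [r.group_sizes[0] for r in self.records],
                "n_b": [r.group_sizes[1] for r in self.records],
                "distance": [r.observed_distance for r in self.records],
                "raw_p": [r.raw_p for r in self.records],
                "p_floored": [r.p_floored for r in self.records],
                "bh_p": [r.bh_p for r in self.records],
                "bonferroni_p": [r.bonferroni_p for r in self.records],
            }
        )


def run_screen(
    spectra: SpectrumMatrix,
    groups: dict[str, str],
    plan: list[tuple[str, str, str]],
    min_group: int = 5,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "mean",
    alpha: float = 0.05,
    p_convention: str = "fraction_ge",
) -> ScreenTable:
    """Run a planned batch of AMSD comparisons with multiple-testing control.

    ``groups`` maps sample id -> group label; ``plan`` lists
    (label_a, label_b, comparison_id) pairs to test. Comparisons where either
    group has fewer than ``min_group`` samples are skipped and recorded.
    Raw p-values floored at zero enter adjustment as 1/n_perm (flagged); they
    are excluded from the BH threshold regression. Per-comparison permutation
    seeds derive deterministically from ``seed``.
    """
    if not plan:
        raise ValueError("empty screen plan")
    by_label: dict[str, list[str]] = {}
    for s in spectra.sample_ids:
        if s in groups:
            by_label.setdefault(groups[s], []).append(s)
    root = np.random.default_rng(seed)

    records: list[ComparisonRecord] = []
    skipped: list[tuple[str, str]] = []
    for label_a, label_b, cid in plan:
        for lab in (label_a, label_b):
            if lab not in by_label:
                raise ValueError(f"label {lab!r} has no samples in the spectrum matrix")
        ids_a, ids_b = by_label[label_a], by_label[label_b]
        comp_seed = int(root.integers(2**31))  # drawn unconditionally: plan order fixes seeds
        if len(ids_a) < min_group or len(ids_b) < min_group:
            skipped.append((cid, f"group sizes {len(ids_a)} vs {len(ids_b)} below min_group={min_group}"))
            continue
        res = amsd_test(
            spectra.select(ids_a),
            spectra.select(ids_b),
            n_perm=n_perm,
            mode=mode,
            seed=comp_seed,
            p_convention=p_convention,
        )
        records.append(
            ComparisonRecord(
                comparison_id=cid,
                label_a=label_a,
                label_b=label_b,
                group_sizes=res.group_sizes,
                observed_distance=res.observed_distance,
                raw_p=res.p_value,
                p_floored=res.p_floored,
                result=res,
            )
        )

    m = len(records)
    bh_regression = None
    bonf_threshold = float("nan")
    if m > 0:
        # floored p's (0 exceedances) enter adjustment at their resolution limit
        adj_input = np.array([r.raw_p if not r.p_floored else 1.0 / r.result.n_permutations for r in records])
        bh = adjust_pvalues(adj_input, "bh")
        bonf = adjust_pvalues(adj_input, "bonferroni")
        for r, pb, pf in zip(records, bh, bonf):
            r.bh_p, r.bonferroni_p = float(pb), float(pf)
        bonf_threshold = -math.log10(alpha / m)
        usable = np.array([not r.p_floored for r in records])
        if usable.sum() >= 2 and np.ptp(adj_input[usable]) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bh_regression = bh_threshold_regression(adj_input[usable], bh[usable], alpha)
    return ScreenTable(records, skipped, m, alpha, bonf_threshold, bh_regression)
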