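"""The aggregate mutation spectrum distance (AMSD) permutation test.

Two groups of mutation spectra are each aggregated into a single spectrum —
by default the per-channel mean of per-sample frequency vectors, so every
sample counts equally regardless of mutation load; alternatively the raw
per-channel count sum, which upweights heavily mutated samples. The cosine
distance between the two aggregates is the test statistic. Significance comes
from a permutation null: group labels are reshuffled over the pooled samples
(preserving group sizes), the aggregate distance recomputed for each
reshuffle, and the p-value is the fraction of reshuffles whose distance is
greater than or equal to the observed one. For small cohorts the null can be
enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np

from .spectra import SpectrumMatrix

#: Distances are compared for >= after rounding to this many decimals, so that
#: permutations reproducing the observed split tie with it despite float noise.
_TIE_DECIMALS = 12

#: Permutations are processed in blocks of this many to bound the memory of
#: the vectorised index-gather; block size does not affect the draw sequence.
_PERM_BLOCK = 1024


def cosine_distance(u, v) -> float:
    """1 - cos(u, v); in [0, 1] for non-negative vectors.

    Symmetric and invariant to positive rescaling of either argument.
    Raises on a zero vector, whose direction is undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (u @ v) / (nu * nv))


#: Registry of distance functions on pairs of non-negative channel vectors.
#: Contract: symmetric, non-negative, defined wherever both vectors are nonzero.
DISTANCES: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "cosine": cosine_distance,
    "euclidean": lambda u, v: float(np.linalg.norm(np.asarray(u, float) - np.asarray(v, float))),
}


def aggregate_spectrum(m: SpectrumMatrix, mode: str = "mean") -> np.ndarray:
    """Aggregate a group of spectra into one channel vector.

    ``mean`` averages per-sample frequency vectors (sums to 1; every sample
    weighted equally); ``sum`` adds raw counts (mutation-rich samples weigh
    more; cosine is scale-invariant so no normalisation is applied).
    Zero-total samples are dropped under ``mean`` with a warning.
    """
    if m.n_samples == 0:
        raise ValueError("cannot aggregate an empty matrix")
    if mode == "sum":
        return m.counts.sum(axis=0)
    if mode != "mean":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    totals = m.totals()
    if np.any(totals == 0):
        dropped = [s for s, t in zip(m.sample_ids, totals) if t == 0]
        warnings.warn(f"dropping {len(dropped)} zero-total samples under mean aggregation: {dropped[:5]}")
    nz = totals > 0
    if not np.any(nz):
        raise ValueError("all samples have zero total; mean aggregation undefined")
    return (m.counts[nz] / totals[nz, None]).mean(axis=0)


@dataclass
class AmsdResult:
    """Outcome of one AMSD comparison.

    ``p_value`` follows ``p_convention``: ``fraction_ge`` is the fraction of
    null distances >= observed (0 is possible and flagged via ``p_floored``;
    the honest statement is then p < 1/n_permutations); ``plus_one`` adds the
    observed labelling to the null, (k+1)/(n+1), and can never be 0.
    """

    observed_distance: float
    null_distances: np.ndarray
    p_value: float
    p_convention: str
    n_permutations: int
    weighting: str
    distance_name: str
    seed: int | None
    group_sizes: tuple[int, int]
    p_floored: bool = False
    exhaustive: bool = False

    def summary(self) -> dict:
        p_text = f"< {1.0 / self.n_permutations:g}" if self.p_floored else f"{self.p_value:g}"
        return {
            "observed_distance": self.observed_distance,
            "p_value": self.p_value,
            "p_text": p_text,
            "p_convention": self.p_convention,
            "p_floored": self.p_floored,
            "n_permutations": self.n_permutations,
            "weighting": self.weighting,
            "distance": self.distance_name,
            "seed": self.seed,
            "group_sizes": list(self.group_sizes),
            "exhaustive": self.exhaustive,
        }


def _pooled_vectors(group_a: SpectrumMatrix, group_b: SpectrumMatrix, mode: str):
    """Pool both groups into per-sample vectors ready for aggregation.

    Under ``mean`` the rows are frequency vectors (zero-total samples dropped,
    with a warning); under ``sum`` the rows are raw counts. Aggregation of any
    index subset is then a row mean / row sum.
    """
    if group_a.schema is not group_b.schema and group_a.schema != group_b.schema:
        raise ValueError(
            f"schema mismatch: {group_a.schema.name!r} vs {group_b.schema.name!r}"
        )
    if group_a.n_samples == 0 or group_b.n_samples == 0:
        raise ValueError("both groups must be non-empty")
    counts = np.vstack([group_a.counts, group_b.counts])
    n_a = group_a.n_samples
    if mode == "mean":
        totals = counts.sum(axis=1)
        if np.any(totals == 0):
            warnings.warn(
                f"dropping {int((totals == 0).sum())} zero-total samples under mean aggregation"
            )
            keep = totals > 0
            n_a = int(keep[: n_a].sum())
            counts = counts[keep]
            totals = totals[keep]
            if n_a == 0 or n_a == counts.shape[0]:
                raise ValueError("a group is empty after dropping zero-total samples")
        rows = counts / totals[:, None]
    elif mode == "sum":
        rows = counts.astype(float)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return rows, n_a


def _pair_distances(agg_a: np.ndarray, agg_b: np.ndarray, distance: str) -> np.ndarray:
    """Row-wise distances between two stacks of aggregate vectors."""
    if distance == "cosine":
        na = np.linalg.norm(agg_a, axis=1)
        nb = np.linalg.norm(agg_b, axis=1)
        denom = na * nb
        if np.any(denom == 0):
            raise ValueError("cosine distance undefined for a zero aggregate")
        return 1.0 - np.einsum("ij,ij->i", agg_a, agg_b) / denom
    func = DISTANCES[distance]
    return np.array([func(a, b) for a, b in zip(agg_a, agg_b)])


def amsd_test(
    group_a: SpectrumMatrix,
    group_b: SpectrumMatrix,
    n_perm: int = 1000,
    mode: str = "mean",
    distance: str = "cosine",
    seed: int | None = None,
    p_convention: str = "fraction_ge",
) -> AmsdResult:
    """Monte-Carlo AMSD permutation test between two groups of spectra.

    Each permutation reshuffles the pooled sample indices uniformly at random
    and takes the first |A| as pseudo-group A, so pseudo-group sizes match the
    observed ones. Splits are sampled independently (duplicates possible).
    Deterministic for a given seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; registered: {sorted(DISTANCES)}")
    if p_convention not in ("fraction_ge", "plus_one"):
        raise ValueError(f"unknown p-value convention {p_convention!r}")
    rows, n_a = _pooled_vectors(group_a, group_b, mode)
    n = rows.shape[0]
    n_b = n - n_a
    reduce = np.mean if mode == "mean" else np.sum

    d_obs = DISTANCES[distance](reduce(rows[:n_a], axis=0), reduce(rows[n_a:], axis=0))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    col_sum = rows.sum(axis=0)
    done = 0
    while done < n_perm:
        block = min(_PERM_BLOCK, n_perm - done)
        # the n_a smallest of iid uniforms = a uniform random n_a-subset,
        # i.e. the first |A| entries of a uniform shuffle of the pooled indices
        idx_a = np.argpartition(rng.random((block, n)), n_a, axis=1)[:, :n_a]
        mask = np.zeros((block, n))
        np.put_along_axis(mask, idx_a, 1.0, axis=1)
        sum_a = mask @ rows
        sum_b = col_sum - sum_a
        if mode == "mean":
            agg_a, agg_b = sum_a / n_a, sum_b / n_b
        else:
            agg_a, agg_b = sum_a, sum_b
        null[done : done + block] = _pair_distances(agg_a, agg_b, distance)
        done += block

    return _finish(d_obs, null, p_convention, mode, distance, seed, (n_a, n_b))


def amsd_exhaustive(
    group_a: SpectrumMatrix,
    group_b: SpectrumMatrix,
    mode: str = "mean",
    distance: str = "cosine",
    max_splits: int = 10_000,
) -> AmsdResult:
    """Exact AMSD: enumerate every assignment of pooled samples to group A.

    The null distribution contains each of the C(|A|+|B|, |A|) splits once;
    the observed labelling is among them, so p >= 1/#splits. Intended as a
    small-cohort oracle for the Monte-Carlo test.
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    rows, n_a = _pooled_vectors(group_a, group_b, mode)
    n = rows.shape[0]
    n_splits = math.comb(n, n_a)
    if n_splits > max_splits:
        raise ValueError(f"C({n},{n_a}) = {n_splits} splits exceeds cap {max_splits}")
    reduce = np.mean if mode == "mean" else np.sum
    func = DISTANCES[distance]

    d_obs = func(reduce(rows[:n_a], axis=0), reduce(rows[n_a:], axis=0))
    col_sum = rows.sum(axis=0)
    null = np.empty(n_splits)
    for i, idx_a in enumerate(combinations(range(n), n_a)):
        sum_a = rows[list(idx_a)].sum(axis=0)
        sum_b = col_sum - sum_a
        if mode == "mean":
            null[i] = func(sum_a / n_a, sum_b / (n - n_a))
        else:
            null[i] = func(sum_a, sum_b)

    res = _finish(d_obs, null, "fraction_ge", mode, distance, None, (n_a, n - n_a))
    res.exhaustive = True
    return res


def _finish(d_obs, null, p_convention, mode, distance, seed, sizes) -> AmsdResult:
    n_perm = len(null)
    k = int(np.sum(np.round(null, _TIE_DECIMALS) >= round(d_obs, _TIE_DECIMALS)))
    if p_convention == "plus_one":
        p, floored = (k + 1) / (n_perm + 1), False
    else:
        p, floored = k / n_perm, k == 0
    return AmsdResult(
        observed_distance=float(d_obs),
        null_distances=null,
        p_value=float(p),
        p_convention=p_convention,
        n_permutations=n_perm,
        weighting=mode,
        distance_name=distance,
        seed=seed,
        group_sizes=sizes,
        p_floored=floored,
    )
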