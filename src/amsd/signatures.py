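"""Signature catalogs, exposure refitting, and signature-based comparison tests.

A mutational signature is a probability distribution over spectrum channels;
a catalog (e.g. COSMIC SBS) is an ordered set of signatures sharing one
channel schema. Refitting decomposes a sample's spectrum into non-negative
signature exposures by least squares, then iteratively prunes signatures whose
exposure fraction falls below a threshold (default 5%) and refits until the
retained set is stable — a transparent stand-in for assignment tools whose
exact heuristics are not reproducible.

The comparison baselines here are the per-signature Wilcoxon rank-sum test
(Bonferroni-corrected, overall p = the most significant corrected p) and the
per-channel rank-sum volcano table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spectra import ChannelSchema, SBS96, SpectrumMatrix, _read_cosmic_table


class SignatureCatalog:
    """Signatures x channels probability profiles under one schema."""

    def __init__(self, schema: ChannelSchema, signature_ids, profiles) -> None:
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape != (len(signature_ids), len(schema)):
            raise ValueError(
                f"profiles shape {profiles.shape} does not match "
                f"{len(signature_ids)} signatures x {len(schema)} channels"
            )
        if np.any(profiles < 0):
            raise ValueError("negative signature probabilities")
        sums = profiles.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1) > 1e-6)
        if bad.size:
            raise ValueError(
                f"signatures do not sum to 1: {[signature_ids[i] for i in bad[:5]]}"
            )
        if len(set(signature_ids)) != len(signature_ids):
            raise ValueError("duplicate signature ids")
        self.schema = schema
        self.signature_ids = list(signature_ids)
        self.profiles = profiles

    def __len__(self) -> int:
        return len(self.signature_ids)

    def profile(self, signature_id: str) -> np.ndarray:
        try:
            return self.profiles[self.signature_ids.index(signature_id)]
        except ValueError:
            raise KeyError(f"signature {signature_id!r} not in catalog") from None

    def subset(self, signature_ids) -> "SignatureCatalog":
        idx = [self.signature_ids.index(s) for s in signature_ids]
        return SignatureCatalog(self.schema, list(signature_ids), self.profiles[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles.T,
            index=pd.Index(self.schema.channels, name="MutationType"),
            columns=self.signature_ids,
        )

    def __repr__(self) -> str:
        return f"SignatureCatalog({len(self)} signatures over {self.schema.name})"


def read_signature_catalog(path, schema: ChannelSchema | None = None) -> SignatureCatalog:
    """Read a COSMIC-dialect catalog TSV (MutationType column + one column per signature)."""
    df = _read_cosmic_table(path)
    labels = [str(x) for x in df.index]
    if schema is None:
        schema = SBS96 if set(labels) == set(SBS96.channels) else ChannelSchema("catalog", tuple(labels))
    order = [labels.index(c) for c in schema.channels]
    profiles = df.to_numpy(dtype=float)[order].T
    return SignatureCatalog(schema, [str(c) for c in df.columns], profiles)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t")


class ExposureMatrix:
    """Samples x signatures exposure estimates, in mutation-count units."""

    def __init__(self, sample_ids, signature_ids, exposures) -> None:
        exposures = np.asarray(exposures, dtype=float)
        if exposures.shape != (len(sample_ids), len(signature_ids)):
            raise ValueError("exposures shape mismatch")
        if np.any(exposures < 0):
            raise ValueError("negative exposures")
        self.sample_ids = list(sample_ids)
        self.signature_ids = list(signature_ids)
        self.exposures = exposures

    def fractions(self) -> np.ndarray:
        """Row-normalised exposures; zero-total rows stay zero."""
        totals = self.exposures.sum(axis=1)
        out = np.zeros_like(self.exposures)
        nz = totals > 0
        out[nz] = self.exposures[nz] / totals[nz, None]
        return out

    def to_frame(self, fractions: bool = False) -> pd.DataFrame:
        data = self.fractions() if fractions else self.exposures
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="Sample"), columns=self.signature_ids)


def _nnls_sample(basis: np.ndarray, counts: np.ndarray, prune_below: float) -> np.ndarray:
    """NNLS refit of one sample with iterative low-fraction pruning.

    basis: channels x signatures. Signatures whose exposure fraction drops
    below ``prune_below`` are zeroed and the remainder refit, until the
    retained set is stable. If every fraction is below the threshold the
    single largest contributor is retained rather than returning an empty fit.
    """
    n_sig = basis.shape[1]
    active = np.arange(n_sig)
    exposures = np.zeros(n_sig)
    if counts.sum() == 0:
        return exposures
    while True:
        e, _ = optimize.nnls(basis[:, active], counts)
        total = e.sum()
        if total == 0:
            return exposures
        frac = e / total
        keep = frac >= prune_below
        if keep.all():
            exposures[active] = e
            return exposures
        if not keep.any():
            keep = frac == frac.max()
        active = active[keep]


def fit_exposures_nnls(
    m: SpectrumMatrix, catalog: SignatureCatalog, prune_below: float = 0.05
) -> ExposureMatrix:
    """Refit each sample's spectrum to the catalog by pruned NNLS.

    Solves min ||counts - basis @ e||_2 with e >= 0 per sample, then
    iteratively removes signatures with exposure fraction < ``prune_below``
    and refits until stable. Exposures are in mutation-count units.
    """
    if m.schema != catalog.schema:
        raise ValueError(f"schema mismatch: {m.schema.name!r} vs {catalog.schema.name!r}")
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    basis = catalog.profiles.T  # channels x signatures
    exposures = np.vstack([_nnls_sample(basis, row, prune_below) for row in m.counts])
    return ExposureMatrix(m.sample_ids, catalog.signature_ids, exposures)


def _ranksum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact when n_a + n_b <= 20 and tie-free.

    Larger samples (or tied data) use the normal approximation with tie and
    continuity corrections. Degenerate all-equal data gives p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass
class SignatureComparisonResult:
    """Per-signature rank-sum comparison with Bonferroni control.

    ``overall_p`` is the most significant Bonferroni-adjusted p across the
    tested set (signatures with nonzero exposure fraction in at least one
    sample of either group).
    """

    tested_signatures: list[str]
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    overall_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"signature": self.tested_signatures, "raw_p": self.raw_p, "bonferroni_p": self.adjusted_p}
        )


def wilcoxon_signature_comparison(
    expo_a: ExposureMatrix, expo_b: ExposureMatrix
) -> SignatureComparisonResult:
    """Compare two groups' signature exposure fractions signature-by-signature.

    Each tested signature gets a two-sided rank-sum test on exposure
    fractions; p-values are Bonferroni-corrected over the tested set and the
    overall significance is the minimum corrected p.
    """
    if expo_a.signature_ids != expo_b.signature_ids:
        raise ValueError("exposure matrices have different signature universes")
    if not expo_a.sample_ids or not expo_b.sample_ids:
        raise ValueError("both groups need at least one sample")
    fa, fb = expo_a.fractions(), expo_b.fractions()
    present = (fa > 0).any(axis=0) | (fb > 0).any(axis=0)
    tested = [s for s, p in zip(expo_a.signature_ids, present) if p]
    if not tested:
        return SignatureComparisonResult([], np.array([]), np.array([]), 1.0)
    idx = np.flatnonzero(present)
    raw = np.array([_ranksum(fa[:, j], fb[:, j]) for j in idx])
    adjusted = np.minimum(1.0, raw * len(tested))
    return SignatureComparisonResult(tested, raw, adjusted, float(adjusted.min()))


def per_channel_wilcoxon(group_a: SpectrumMatrix, group_b: SpectrumMatrix) -> pd.DataFrame:
    """Per-channel rank-sum comparison of per-sample frequencies (volcano table).

    Returns one row per schema channel with the raw two-sided p, the
    Benjamini–Hochberg adjusted p across channels, and the mean frequency
    difference (group A minus group B).
    """
    from statsmodels.stats.multitest import multipletests

    if group_a.schema != group_b.schema:
        raise ValueError("schema mismatch")
    if group_a.n_samples == 0 or group_b.n_samples == 0:
        raise ValueError("both groups must be non-empty")
    fa, fb = group_a.frequencies(), group_b.frequencies()
    raw = np.array([_ranksum(fa[:, j], fb[:, j]) for j in range(len(group_a.schema))])
    bh = multipletests(raw, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "channel": list(group_a.schema.channels),
            "raw_p": raw,
            "bh_p": bh,
            "mean_freq_diff": fa.mean(axis=0) - fb.mean(axis=0),
        }
    )
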