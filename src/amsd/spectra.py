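"""Mutation spectrum matrices: channel schemas, COSMIC-dialect I/O, SBS96 tallying.

A mutation spectrum is a vector of mutation counts over a fixed, ordered set of
mutation-type channels. The built-in schema is SBS96: single-base substitutions
classified by the substituted pyrimidine, its replacement, and the two flanking
bases, with purine-reference variants reverse-complemented before classification.
Arbitrary channel schemas (e.g. CNV or SV categories) are accepted as generic
matrices; only SBS96 tallying from variant calls is implemented here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = ("A", "C", "G", "T")

#: Accepted first-column headers for COSMIC-dialect spectrum / catalog TSVs.
_LABEL_HEADERS = ("MutationType", "Type", "")


def revcomp(seq: str) -> str:
    """Reverse-complement an ACGT string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered, named set of mutation-type channel labels.

    Order is significant: matrices, catalogs and aggregate vectors all follow
    the schema's channel order.
    """

    name: str
    channels: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"schema {self.name!r} has duplicate channel labels")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.channels)})

    def __len__(self) -> int:
        return len(self.channels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"channel {label!r} not in schema {self.name!r}") from None


def _build_sbs96() -> ChannelSchema:
    # COSMIC ordering: substitution class (C>A, C>G, C>T, T>A, T>C, T>G),
    # then 5' flank, then 3' flank, each alphabetical.
    labels = []
    for ref in ("C", "T"):
        for alt in _BASES:
            if alt == ref:
                continue
            for five in _BASES:
                for three in _BASES:
                    labels.append(f"{five}[{ref}>{alt}]{three}")
    return ChannelSchema("SBS96", tuple(labels))


#: The canonical 96-channel single-base-substitution schema, COSMIC-ordered.
SBS96 = _build_sbs96()


def sbs96_channel(trinucleotide: str, alt: str) -> str:
    """Classify an SNV into its SBS96 channel.

    ``trinucleotide`` is the reference context centred on the mutated base.
    If the central base is a purine, both context and substitution are
    reverse-complemented so the channel is pyrimidine-centred.
    """
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3:
        raise ValueError(f"trinucleotide must have length 3, got {tri!r}")
    if any(b not in _COMPLEMENT for b in tri) or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT base in {tri!r}>{alt!r}")
    ref = tri[1]
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r})")
    if ref in ("A", "G"):
        tri = revcomp(tri)
        ref = tri[1]
        alt = _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant call attributed to one sample.

    ``pos`` is 1-based, following VCF/MAF convention.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single ACGT bases, got {self.ref!r}>{self.alt!r}")


class SpectrumMatrix:
    """Non-negative mutation counts, samples x channels, under a fixed schema."""

    def __init__(self, schema: ChannelSchema, sample_ids: Sequence[str], counts) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape != (len(sample_ids), len(schema)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(schema)} channels"
            )
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        self.schema = schema
        self.sample_ids = list(sample_ids)
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def totals(self) -> np.ndarray:
        """Per-sample total mutation counts."""
        return self.counts.sum(axis=1)

    def frequencies(self) -> np.ndarray:
        """Per-sample frequency vectors (rows sum to 1; zero-total rows stay zero)."""
        totals = self.totals()
        out = np.zeros_like(self.counts)
        nz = totals > 0
        out[nz] = self.counts[nz] / totals[nz, None]
        return out

    def select(self, sample_ids: Sequence[str]) -> "SpectrumMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SpectrumMatrix(self.schema, list(sample_ids), self.counts[idx])

    def to_frame(self) -> pd.DataFrame:
        """Channels-as-rows DataFrame in schema order (COSMIC layout)."""
        return pd.DataFrame(
            self.counts.T, index=pd.Index(self.schema.channels, name="MutationType"),
            columns=self.sample_ids,
        )

    def __repr__(self) -> str:
        return f"SpectrumMatrix({self.n_samples} samples x {len(self.schema)} {self.schema.name} channels)"


def _read_cosmic_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    first = df.columns[0]
    if first not in _LABEL_HEADERS and not first.startswith("Unnamed"):
        logger.debug("treating first column %r as the label column", first)
    return df.set_index(df.columns[0])


def read_spectrum_matrix(
    path,
    orientation: str = "channels_as_rows",
    schema: ChannelSchema | None = None,
    fill_missing: bool = False,
) -> SpectrumMatrix:
    """Read a spectrum matrix from a COSMIC-dialect TSV.

    Parameters
    ----------
    path
        TSV with a header row; the first column holds channel labels
        (``channels_as_rows``, COSMIC layout) or sample ids (``samples_as_rows``).
    schema
        Declared channel schema. If omitted, SBS96 is used when the file's
        labels are exactly the SBS96 set; otherwise a generic schema is built
        from the file's own label order.
    fill_missing
        If True, schema channels absent from the file are zero-filled;
        otherwise their absence is an error.
    """
    if orientation not in ("channels_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_cosmic_table(path)
    if orientation == "samples_as_rows":
        df = df.T
    # now: rows = channels, columns = samples
    labels = [str(x) for x in df.index]
    if len(set(labels)) != len(labels):
        dups = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate channel labels in {path}: {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    if np.any(np.isnan(values)):
        raise ValueError(f"missing/non-numeric cells in {path}")
    if np.any(values < 0):
        raise ValueError(f"negative values in {path}")

    if schema is None:
        schema = SBS96 if set(labels) == set(SBS96.channels) else ChannelSchema(Path(str(path)).stem, tuple(labels))

    unknown = [l for l in labels if l not in schema.channels]
    if unknown:
        raise ValueError(f"labels not in schema {schema.name!r}: {unknown[:5]}")
    counts = np.zeros((df.shape[1], len(schema)))
    present = set(labels)
    missing = [c for c in schema.channels if c not in present]
    if missing and not fill_missing:
        raise ValueError(
            f"{len(missing)} schema channels missing from {path} "
            f"(e.g. {missing[:3]}); pass fill_missing=True to zero-fill"
        )
    for row_label, row in zip(labels, values):
        counts[:, schema.index_of(row_label)] = row
    return SpectrumMatrix(schema, [str(c) for c in df.columns], counts)


def write_spectrum_matrix(m: SpectrumMatrix, path) -> None:
    """Write a COSMIC-dialect TSV, channels as rows in schema order.

    Integer-valued matrices are written as integers so tallied counts
    round-trip without a float representation.
    """
    df = m.to_frame()
    if np.all(m.counts == np.floor(m.counts)):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t")


@dataclass
class TallyResult:
    """SBS96 tally output: the count matrix plus an audit of skipped records."""

    matrix: SpectrumMatrix
    skipped: Counter

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def tally_sbs96(variants: Iterable[VariantRecord], reference) -> TallyResult:
    """Tally SNVs into an SBS96 spectrum matrix per sample.

    ``reference`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> indexable
    sequence) or a path to a FASTA file. The reference trinucleotide centred on
    each variant is classified under the pyrimidine-centred convention.
    Records are skipped — and tallied by reason, not fatal — when the stated
    reference base disagrees with the FASTA, the context contains a non-ACGT
    base, the position lacks a flanking base, or the chromosome is absent.
    """
    if isinstance(reference, (str, Path)):
        import pyfaidx

        reference = pyfaidx.Fasta(str(reference))

    per_sample: dict[str, np.ndarray] = {}
    skipped: Counter = Counter()
    for v in variants:
        try:
            seq = reference[v.chrom]
        except KeyError:
            skipped["chrom_absent"] += 1
            continue
        if v.pos < 2 or v.pos + 1 > len(seq):
            skipped["sequence_edge"] += 1
            continue
        tri = str(seq[v.pos - 2 : v.pos + 1]).upper()
        if any(b not in _COMPLEMENT for b in tri):
            skipped["non_acgt_context"] += 1
            continue
        if tri[1] != v.ref:
            skipped["ref_mismatch"] += 1
            continue
        channel = sbs96_channel(tri, v.alt)
        row = per_sample.setdefault(v.sample, np.zeros(len(SBS96)))
        row[SBS96.index_of(channel)] += 1

    if skipped:
        logger.warning("tally_sbs96 skipped %d records: %s", sum(skipped.values()), dict(skipped))
    sample_ids = list(per_sample)
    counts = np.vstack([per_sample[s] for s in sample_ids]) if sample_ids else np.zeros((0, len(SBS96)))
    return TallyResult(SpectrumMatrix(SBS96, sample_ids, counts), skipped)


def read_variants_table(path) -> list[VariantRecord]:
    """Read a minimal MAF-like TSV with columns chrom, pos, ref, alt, sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "sample": str})
    required = {"chrom", "pos", "ref", "alt", "sample"}
    if not required.issubset(df.columns):
        raise ValueError(f"variant table {path} must have columns {sorted(required)}")
    return [
        VariantRecord(r.chrom, int(r.pos), r.ref.upper(), r.alt.upper(), r.sample)
        for r in df.itertuples(index=False)
    ]


def read_variants_vcf(path, sample: str | None = None) -> tuple[list[VariantRecord], Counter]:
    """Read SNV records from a VCF; non-SNVs are skipped with a tally.

    For multi-sample VCFs a record is attributed to every sample carrying a
    non-reference genotype; for site-only VCFs ``sample`` names the single
    sample all records belong to.
    """
    import pysam

    records: list[VariantRecord] = []
    skipped: Counter = Counter()
    with pysam.VariantFile(str(path)) as vcf:
        has_samples = len(vcf.header.samples) > 0
        for rec in vcf:
            for alt in rec.alts or ():
                if rec.ref is None or len(rec.ref) != 1 or len(alt) != 1 or alt not in _BASES or rec.ref not in _BASES:
                    skipped["non_snv"] += 1
                    continue
                if has_samples:
                    carriers = [
                        s for s in rec.samples
                        if any(a not in (0, None) for a in (rec.samples[s]["GT"] or ()))
                    ]
                else:
                    if sample is None:
                        raise ValueError("site-only VCF: pass sample= to attribute records")
                    carriers = [sample]
                for s in carriers:
                    records.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt, s))
    return records, skipped


def filter_min_mutations(m: SpectrumMatrix, min_total: int) -> tuple[SpectrumMatrix, list[str]]:
    """Drop samples with fewer than ``min_total`` mutations.

    Returns the filtered matrix (survivor order preserved) and the removed
    sample ids. The boundary is inclusive: a sample with exactly ``min_total``
    mutations survives.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = m.totals()
    keep = totals >= min_total
    removed = [s for s, k in zip(m.sample_ids, keep) if not k]
    if removed:
        logger.info("filter_min_mutations removed %d samples: %s", len(removed), removed[:10])
    kept_ids = [s for s, k in zip(m.sample_ids, keep) if k]
    return SpectrumMatrix(m.schema, kept_ids, m.counts[keep]), removed
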