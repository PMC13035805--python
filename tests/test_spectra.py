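"""Spectrum matrix I/O, the SBS96 schema, and variant tallying."""

import re

import numpy as np
import pytest

from amsd import (
    SBS96,
    ChannelSchema,
    SpectrumMatrix,
    VariantRecord,
    filter_min_mutations,
    read_spectrum_matrix,
    read_variants_table,
    read_variants_vcf,
    sbs96_channel,
    tally_sbs96,
    write_spectrum_matrix,
)
from amsd.spectra import revcomp


class TestSchema:
    def test_sbs96_has_96_wellformed_unique_labels(self):
        assert len(SBS96) == 96
        pattern = re.compile(r"^[ACGT]\[[CT]>[ACGT]\][ACGT]$")
        for label in SBS96.channels:
            assert pattern.match(label)
            ref, alt = label[2], label[4]
            assert ref != alt
        assert len(set(SBS96.channels)) == 96

    def test_sbs96_cosmic_ordering(self):
        # substitution class blocks of 16, then 5' flank, then 3' flank
        assert SBS96.channels[0] == "A[C>A]A"
        assert SBS96.channels[3] == "A[C>A]T"
        assert SBS96.channels[4] == "C[C>A]A"
        assert SBS96.channels[16] == "A[C>G]A"
        assert SBS96.channels[95] == "T[T>G]T"

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ChannelSchema("bad", ("a", "b", "a"))


class TestChannelClassification:
    @pytest.mark.parametrize(
        "tri,alt,expected",
        [
            ("TGC", "A", "G[C>T]A"),  # purine-centred: reverse-complement collapse
            ("ACA", "A", "A[C>A]A"),  # already pyrimidine-centred
            ("ATA", "G", "A[T>G]A"),
            ("AAA", "C", "T[T>G]T"),  # A>C maps to T>G on the other strand
            ("tgc", "a", "G[C>T]A"),  # soft-masked input uppercased
        ],
    )
    def test_strand_collapse(self, tri, alt, expected):
        assert sbs96_channel(tri, alt) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sbs96_channel("ANA", "G")
        with pytest.raises(ValueError):
            sbs96_channel("ACA", "C")


def _exemplar_genome():
    """One crafted SNV per SBS96 channel on a synthetic contig.

    The contig is the concatenation of the 96 pyrimidine-centred reference
    trinucleotides; the variant at each triplet's centre realises one channel.
    """
    tris, alts = [], []
    for label in SBS96.channels:
        tris.append(label[0] + label[2] + label[6])
        alts.append(label[4])
    genome = {"chr1": "".join(tris)}
    variants = [
        VariantRecord("chr1", 3 * i + 2, tri[1], alt, "s1")
        for i, (tri, alt) in enumerate(zip(tris, alts))
    ]
    return genome, variants


class TestTally:
    def test_one_exemplar_per_channel_gives_all_ones(self):
        genome, variants = _exemplar_genome()
        res = tally_sbs96(variants, genome)
        assert res.n_skipped == 0
        assert res.matrix.sample_ids == ["s1"]
        assert np.array_equal(res.matrix.counts[0], np.ones(96))

    def test_conservation_totals_equal_accepted_records(self, rng):
        genome, variants = _exemplar_genome()
        picks = [variants[i] for i in rng.integers(0, 96, size=40)]
        res = tally_sbs96(picks, genome)
        assert res.matrix.totals()[0] == 40 - res.n_skipped == 40

    def test_strand_symmetry_under_genome_reverse_complement(self):
        genome, variants = _exemplar_genome()
        seq = genome["chr1"]
        L = len(seq)
        rc_genome = {"chr1": revcomp(seq)}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_variants = [
            VariantRecord(v.chrom, L - v.pos + 1, comp[v.ref], comp[v.alt], v.sample)
            for v in variants
        ]
        a = tally_sbs96(variants, genome)
        b = tally_sbs96(rc_variants, rc_genome)
        assert np.array_equal(a.matrix.counts, b.matrix.counts)

    def test_skip_reasons(self):
        genome = {"chr1": "AACAA"}
        variants = [
            VariantRecord("chr1", 3, "C", "T", "s1"),  # good: ACA context
            VariantRecord("chr1", 3, "G", "T", "s1"),  # ref mismatch
            VariantRecord("chr1", 1, "A", "T", "s1"),  # edge, no 5' flank
            VariantRecord("chr1", 5, "A", "T", "s1"),  # edge, no 3' flank
            VariantRecord("chr2", 3, "C", "T", "s1"),  # absent chromosome
        ]
        res = tally_sbs96(variants, genome)
        assert res.matrix.totals()[0] == 1
        assert res.skipped == {"ref_mismatch": 1, "sequence_edge": 2, "chrom_absent": 1}

    def test_non_acgt_context_skipped(self):
        res = tally_sbs96([VariantRecord("chr1", 3, "C", "T", "s1")], {"chr1": "ANCAA"})
        assert res.skipped == {"non_acgt_context": 1}

    def test_soft_masked_fasta_accepted(self):
        res = tally_sbs96([VariantRecord("chr1", 2, "C", "A", "s1")], {"chr1": "aca"})
        assert res.matrix.counts[0][SBS96.index_of("A[C>A]A")] == 1

    def test_fasta_file_access(self, tmp_path):
        genome, variants = _exemplar_genome()
        fasta = tmp_path / "toy.fa"
        fasta.write_text(">chr1\n" + genome["chr1"] + "\n")
        res = tally_sbs96(variants[:10], str(fasta))
        assert res.matrix.totals()[0] == 10


class TestIO:
    def test_round_trip(self, random_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_spectrum_matrix(random_matrix, path)
        back = read_spectrum_matrix(path)
        assert back.sample_ids == random_matrix.sample_ids
        assert np.array_equal(back.counts, random_matrix.counts)
        assert back.schema.channels == SBS96.channels

    def test_integer_counts_stay_integers_in_file(self, random_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_spectrum_matrix(random_matrix, path)
        body = path.read_text().splitlines()[1:]
        assert not any("." in line.split("\t", 1)[1] for line in body)

    def test_permuted_rows_load_identically(self, random_matrix, tmp_path, rng):
        canonical = tmp_path / "canon.tsv"
        write_spectrum_matrix(random_matrix, canonical)
        lines = canonical.read_text().splitlines()
        header, rows = lines[0], lines[1:]
        perm = rng.permutation(len(rows))
        shuffled = tmp_path / "shuf.tsv"
        shuffled.write_text("\n".join([header] + [rows[i] for i in perm]) + "\n")
        a = read_spectrum_matrix(canonical)
        b = read_spectrum_matrix(shuffled)
        assert np.array_equal(a.counts, b.counts)

    def test_duplicate_channel_row_errors(self, random_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_spectrum_matrix(random_matrix, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectrum_matrix(path)

    def test_empty_sample_set_round_trips(self, tmp_path):
        m = SpectrumMatrix(SBS96, [], np.zeros((0, 96)))
        path = tmp_path / "empty.tsv"
        write_spectrum_matrix(m, path)
        back = read_spectrum_matrix(path)
        assert back.n_samples == 0

    def test_negative_and_nonnumeric_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("MutationType\ts1\nA[C>A]A\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_spectrum_matrix(path, schema=ChannelSchema("one", ("A[C>A]A",)))
        path.write_text("MutationType\ts1\nA[C>A]A\tx\n")
        with pytest.raises(ValueError):
            read_spectrum_matrix(path, schema=ChannelSchema("one", ("A[C>A]A",)))

    def test_missing_channels_need_fill_flag(self, random_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_spectrum_matrix(random_matrix, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop the last channel row
        with pytest.raises(ValueError, match="missing"):
            read_spectrum_matrix(path, schema=SBS96)
        back = read_spectrum_matrix(path, schema=SBS96, fill_missing=True)
        assert back.counts[:, -1].sum() == 0

    def test_samples_as_rows_orientation(self, random_matrix, tmp_path):
        path = tmp_path / "t.tsv"
        random_matrix.to_frame().T.rename_axis("Sample").to_csv(path, sep="\t")
        back = read_spectrum_matrix(path, orientation="samples_as_rows")
        assert np.array_equal(back.counts, random_matrix.counts)

    def test_generic_schema_inferred_for_non_sbs_channels(self, tmp_path):
        path = tmp_path / "cnv.tsv"
        path.write_text("MutationType\ts1\ts2\ncnvA\t1\t2\ncnvB\t3\t4\n")
        m = read_spectrum_matrix(path)
        assert m.schema.channels == ("cnvA", "cnvB")
        assert m.counts.tolist() == [[1, 3], [2, 4]]


class TestVariantReaders:
    def test_maf_like_table(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("chrom\tpos\tref\talt\tsample\nchr1\t3\tC\tT\ts1\nchr1\t4\ta\tg\ts2\n")
        records = read_variants_table(path)
        assert records[0] == VariantRecord("chr1", 3, "C", "T", "s1")
        assert records[1].ref == "A"

    def test_vcf_snvs_attributed_by_genotype(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\n"
            "chr1\t10\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "chr1\t20\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/1\n"
            "chr1\t30\t.\tC\tCT\t.\tPASS\t.\tGT\t0/1\t0/1\n"
        )
        records, skipped = read_variants_vcf(path)
        assert skipped["non_snv"] == 1
        by_sample = {}
        for r in records:
            by_sample.setdefault(r.sample, []).append(r.pos)
        assert by_sample == {"sA": [10, 20], "sB": [20]}


class TestFilterMinMutations:
    def test_inclusive_boundary(self):
        counts = np.zeros((3, 96))
        counts[0, 0], counts[1, 0], counts[2, 0] = 3, 10, 250
        m = SpectrumMatrix(SBS96, ["low", "edge", "high"], counts)
        kept, removed = filter_min_mutations(m, 10)
        assert kept.sample_ids == ["edge", "high"]
        assert removed == ["low"]

    def test_zero_threshold_is_identity(self, random_matrix):
        kept, removed = filter_min_mutations(random_matrix, 0)
        assert kept.sample_ids == random_matrix.sample_ids
        assert removed == []

    def test_matches_bruteforce_survivor_set(self, rng):
        counts = rng.integers(0, 30, size=(20, 96)).astype(float)
        m = SpectrumMatrix(SBS96, [f"s{i}" for i in range(20)], counts)
        kept, removed = filter_min_mutations(m, 700)
        expected = [s for s, t in zip(m.sample_ids, counts.sum(axis=1)) if t >= 700]
        assert kept.sample_ids == expected
        assert set(removed) == set(m.sample_ids) - set(expected)
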