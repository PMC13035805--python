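"""Tally SNV calls into an SBS96 spectrum against a reference sequence.

Builds a toy genome and a handful of variant calls, then classifies each SNV
by its reference trinucleotide context under the pyrimidine-centred
convention (purine-reference variants are reverse-complemented first).
"""

from amsd import VariantRecord, tally_sbs96

genome = {"chr1": "AACAGGTTACGT"}
variants = [
    VariantRecord("chr1", 3, "C", "T", "s1"),   # ACA context -> A[C>T]A
    VariantRecord("chr1", 5, "G", "A", "s1"),   # AGG -> revcomp CCT -> C[C>T]T
    VariantRecord("chr1", 9, "A", "C", "s1"),   # TAC -> revcomp GTA -> G[T>G]A
    VariantRecord("chr1", 3, "G", "T", "s1"),   # ref mismatch: skipped
    VariantRecord("chr1", 1, "A", "T", "s1"),   # no 5' flank: skipped
]
result = tally_sbs96(variants, genome)

nonzero = {
    ch: int(c)
    for ch, c in zip(result.matrix.schema.channels, result.matrix.counts[0])
    if c > 0
}
print("tallied channels:", nonzero)
print("skipped records: ", dict(result.skipped))

# Three records land in their trinucleotide channels; the mismatching and
# edge records are dropped but audited in the skip tally.
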