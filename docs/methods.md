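# Methods

## The permutation test

The test compares two groups of mutation spectra by reducing each group to a
single aggregate spectrum and measuring the cosine distance between the
aggregates. Two aggregation modes are provided:

- **mean** (default): the per-channel arithmetic mean of per-sample
  *frequency* vectors. Every sample contributes equally regardless of its
  mutation load, which makes the statistic robust to high-mutation outliers.
  The aggregate sums to 1. Samples with zero total mutations have no
  frequency vector; they are dropped with a warning (upstream filtering of
  low-count samples, e.g. `filter_min_mutations(m, 10)`, is recommended
  anyway so that near-empty spectra do not receive full weight).
- **sum**: the per-channel sum of raw counts. Mutation-rich samples dominate,
  which is the right sensitivity when the question is whether heavily mutated
  outliers are over-represented in one group. Cosine distance is invariant to
  positive rescaling, so the sum is not normalised.

The null distribution is built by relabeling: the pooled samples are
reshuffled uniformly at random, the first $|A|$ taken as pseudo-group A, and
the aggregate distance recomputed. Because the relabeling preserves group
sizes and per-sample mutation counts, the null automatically conditions on
unequal cohort sizes and loads. Splits are sampled independently across
permutations (duplicate splits can occur), which is the standard Monte-Carlo
estimator; `amsd_exhaustive` instead enumerates every split once and is exact.

**p-value conventions.** The default `fraction_ge` reports
$\#\{d_\mathrm{perm} \ge d_\mathrm{obs}\}/N$, matching how permutation
p-values are conventionally printed (e.g. $3\times10^{-5}$ at $N=10^5$ means
3 exceedances). When the count is zero the stored p is 0 with a
`p_floored` flag, and text output prints `< 1/N` — a permutation test cannot
resolve below its permutation count. The `plus_one` convention
$(k+1)/(N+1)$ counts the observed labeling as one split; it is never zero,
is exactly valid (sub-uniform under the null), and is what the calibration
tests use. The two differ by at most $\sim 1/N$.

**Ties.** Exceedance is "greater than or equal"; distances are rounded to
12 decimals before the comparison so that permutations reproducing the
observed split (inevitable in small cohorts) tie with it rather than falling
on either side by floating-point noise.

**Implementation.** Permutations are vectorised in blocks of 1024: a block
of iid uniforms per pooled sample is drawn, the $|A|$ smallest per row
selected by `argpartition` (a uniform random subset, i.e. the head of a
uniform shuffle), and group sums computed by a 0/1-mask matrix product. One
seeded generator drives all blocks, so results are independent of block size
and reproducible bit-for-bit. A 25-vs-25 test at 1000 permutations takes a
few milliseconds.

**Distance registry.** Cosine is the default and only distance the contract
requires; the registry accepts any symmetric non-negative function on pairs
of non-negative vectors (Euclidean is included as an example plug-in).

## SBS96 tallying

SNVs are classified by the reference trinucleotide centred on the variant.
If the central reference base is a purine, the trinucleotide and the
substitution are reverse-complemented first, so all 96 channels are
pyrimidine-centred, ordered by substitution class (C>A, C>G, C>T, T>A, T>C,
T>G) then 5' and 3' flank. Positions are 1-based (VCF/MAF convention);
lowercase (soft-masked) reference bases are uppercased before
classification. Records are *skipped, not fatal* — with a per-reason audit
tally — when the stated reference base disagrees with the FASTA, the context
contains a non-ACGT base, the variant sits at a sequence edge, or its
chromosome is absent. Skipping keeps the tally permissive on messy call sets
while leaving the losses visible; erroring on first mismatch was rejected
because real call sets routinely contain liftover and masking artifacts.

## The cohort simulator

The simulator emulates a two-arm exposure study built from signature
mixtures. A signature is a probability distribution over channels; a
sample with $n$ mutations is one multinomial draw of size $n$ from the
mixture distribution $\sum_i w_i \,\mathrm{sig}_i$. Control samples draw a
fixed $B$ mutations from the baseline mixture; exposed samples draw the same
$B$ baseline mutations plus $\mathrm{round}(f \cdot B)$ mutations from a
single exposure signature. Defaults follow the study design the simulator
reproduces: baseline weights 30/60/10 over three backbone signatures,
$B \in \{50, 2500\}$ bracketing exome- and genome-scale loads, exposure
fractions 2–20%, and 5–625 samples per group.

Choices and caveats:

- **Fixed per-sample totals.** $B$ does not vary across samples (no Poisson
  dispersion), matching a design that states exact per-sample counts. Real
  cohorts have heavy-tailed mutation loads; the mean-aggregation mode is the
  mitigation for that, but simulated power will be slightly optimistic for
  real data.
- **Rounding.** Extra mutations use round-half-even of $f\cdot B$
  (`np.rint`), consistent with the 2% of 2500 = 50 anchor case; the rule
  only matters at half-integers (e.g. 5% of 50 → 2).
- **No genomic positions.** Mutations are channel draws; trinucleotide
  opportunity (exome vs genome content), clonality and selection are not
  modelled. Passing tests therefore demonstrate the statistical machinery
  under the stated mixture model, not robustness to those real-data effects.
- **The synthetic catalog.** `make_fixture_catalog` emits five signatures:
  three sparse-Dirichlet backbones, a *spiky* signature with ≥80% of its
  mass on 4 channels (APOBEC-like concentration), and a *flat* one with
  maximum channel mass ≤3% (clock-like spread). It reproduces the structure
  that drives detection behaviour — spiky exposures are detectable at far
  lower counts than flat ones — without shipping any third-party catalog;
  real catalog TSVs load through the same reader when a user supplies them.

`run_power_grid` estimates power as the fraction of replicate cohort pairs a
method rejects. Rejection is $p \le \alpha$: permutation p-values are
discrete and can equal 1, and a level of 1 must reject everything; at
$\alpha=0.05$ with 1000 permutations no attainable p equals $\alpha$, so
$\le$ and $<$ coincide. The grid defaults to the `plus_one` convention so
that the null cell is calibrated rather than slightly anti-conservative.

## Signature refitting and the comparison baselines

`fit_exposures_nnls` decomposes each sample by non-negative least squares
against the catalog, then iteratively zeroes signatures whose exposure
fraction is below 5% and refits the survivors until the retained set is
stable. The 5% prune mirrors common refitting practice of discarding
trace attributions; it necessarily leaves the pruned residual at or above
the unconstrained one. If every fraction falls below the threshold the
single largest contributor is retained rather than returning an empty fit.
This fitter is a deliberately transparent stand-in for dedicated assignment
tools whose heuristics are not reproducible from their descriptions;
numerical equality with any specific tool's exposures is not claimed, and
all comparisons in this package use the in-repo fitter end to end.

The signature-based test refits both groups, takes the signatures with
nonzero exposure fraction in at least one sample, runs a two-sided Wilcoxon
rank-sum test on exposure fractions per signature, Bonferroni-corrects over
the tested set, and reports the most significant corrected p as the overall
significance. The rank-sum p is exact when the pooled sample count is ≤20
and tie-free (small cohorts are where exactness matters; the minimal
two-sided exact p at 5 vs 5 is $2/\binom{10}{5} \approx 0.0079$, so
Bonferroni over a handful of signatures can make significance unreachable —
the structural reason this baseline underperforms the permutation test at
small $n$); larger or tied data use the normal approximation with tie and
continuity corrections. `per_channel_wilcoxon` applies the same rank-sum
machinery per channel with BH adjustment across the 96 channels, for
volcano-style inspection of which contexts drive a difference.

## Screening and multiple testing

`run_screen` executes a planned list of comparisons, skipping (and
recording) any where either group has fewer than 5 samples (default),
then adjusts raw p-values across executed comparisons by Bonferroni and BH.
Floored raw p-values (zero exceedances) enter adjustment at their resolution
limit $1/N$ and are flagged; they are excluded from the BH threshold
regression, whose logs they would otherwise break. Per-comparison
permutation seeds are drawn from the screen seed *unconditionally in plan
order*, so adding a skipped comparison does not shift the seeds of later ones.

The **BH threshold regression** is a plotting device: regress
$-\log_{10}(\text{adjusted } p)$ on $-\log_{10}(\text{raw } p)$ by ordinary
least squares and draw the significance line at $-\log_{10}(0.05)\cdot\beta$.
The regression uses a free intercept — unqualified "linear regression"
defaults to one, and the through-origin variant was rejected because the BH
step-up map does not pass through the origin on the log scale; only the
slope is used for the threshold.

`fisher_exact_2x2` uses the two-sided probability-mass convention (summing
hypergeometric tables with probability ≤ the observed table's), the dominant
convention and scipy's default; conventions differ across software, hence
the explicit note. `sem` is the sample standard deviation (n−1 denominator)
over $\sqrt{n}$.

## Problem sizes in the test suite

The statistical acceptance tests use 1000 null replicates at 1000
permutations each for type-I calibration, a 24-cell reduced power grid at 50
replicates per cell, and 50,000-permutation Monte-Carlo-vs-exhaustive
comparisons on ≤8-sample cohorts — sizes at which the binomial tolerances
stated in each test are meaningful while the whole suite stays fast (the
vectorised kernel runs the full calibration in a few seconds).

## Known limitations

- Permutation tests assume exchangeability of samples across groups under
  the null; confounding covariates (batch, tissue, sex) are not adjusted
  for, and stratified or blocked permutation is out of scope.
- Only two-group comparisons are supported; no omnibus multi-group test.
- The tallier implements SBS96 only; CNV/SV/DBS/indel channel matrices are
  accepted as generic inputs but not constructed.
- Mean-mode aggregation gives every surviving sample equal weight, so a
  sample with 10 mutations carries the same weight as one with 10,000 —
  filter low-count samples first.
- The NNLS refit does not model exome/genome trinucleotide opportunity
  rescaling; catalogs must match the data's context normalisation.
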