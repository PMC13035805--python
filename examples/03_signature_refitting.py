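"""Interpret a spectrum difference by refitting signature exposures.

After the permutation test flags a difference, NNLS refitting attributes each
sample's spectrum to catalog signatures; the per-signature rank-sum test then
asks which signature's exposure fraction separates the groups.
"""

import numpy as np

from amsd import (
    SimulationSpec,
    default_baseline,
    fit_exposures_nnls,
    make_fixture_catalog,
    simulate_cohort_pair,
    wilcoxon_signature_comparison,
)

catalog = make_fixture_catalog(seed=0)
baseline = default_baseline(catalog)

spec = SimulationSpec(baseline_mutations=2500, exposure_signature="SIG_SPIKY",
                      exposure_fraction=0.2, samples_per_group=10, replicates=1)
control, exposed = simulate_cohort_pair(spec, baseline, catalog, np.random.default_rng(3))

expo_control = fit_exposures_nnls(control, catalog)
expo_exposed = fit_exposures_nnls(exposed, catalog)

j = catalog.signature_ids.index("SIG_SPIKY")
print(f"mean SIG_SPIKY fraction, control: {expo_control.fractions()[:, j].mean():.3f}")
print(f"mean SIG_SPIKY fraction, exposed: {expo_exposed.fractions()[:, j].mean():.3f}")
print(f"(truth for the exposed group: 0.2/1.2 = {0.2/1.2:.3f})")

res = wilcoxon_signature_comparison(expo_control, expo_exposed)
for sig, raw, adj in zip(res.tested_signatures, res.raw_p, res.adjusted_p):
    print(f"{sig:<12} raw p = {raw:.4g}   Bonferroni p = {adj:.4g}")
print(f"overall p (most significant corrected): {res.overall_p:.4g}")

# The spiked signature's exposure fraction is recovered near its true value
# and is the signature driving the overall significance.
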