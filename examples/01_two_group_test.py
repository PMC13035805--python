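"""Test whether an exposed cohort's mutation spectra differ from controls.

Simulates two 25-sample cohorts sharing a baseline signature mixture, spikes
10% extra mutations from one signature into the exposed group, and runs the
aggregate-spectrum-distance permutation test.
"""

import numpy as np

from amsd import SimulationSpec, amsd_test, default_baseline, make_fixture_catalog, simulate_cohort_pair

catalog = make_fixture_catalog(seed=0)
baseline = default_baseline(catalog)

spec = SimulationSpec(baseline_mutations=500, exposure_signature="SIG_SPIKY",
                      exposure_fraction=0.1, samples_per_group=25, replicates=1)
control, exposed = simulate_cohort_pair(spec, baseline, catalog, np.random.default_rng(1))

result = amsd_test(control, exposed, n_perm=10_000, seed=1)
print(f"observed cosine distance: {result.observed_distance:.4f}")
print(f"permutation p-value:      {result.summary()['p_text']}  ({result.n_permutations} permutations)")
print(f"null distance range:      [{result.null_distances.min():.4f}, {result.null_distances.max():.4f}]")

# The observed distance between the groups' mean spectra sits far outside the
# range reached by random relabelings, so the exposure's shift in the spectrum
# is significant; with no true difference p would be roughly uniform.
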