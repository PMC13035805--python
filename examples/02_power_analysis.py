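"""Estimate detection power across sample sizes for spiky vs flat exposures.

Runs a small simulation grid: each cell simulates 30 cohort pairs at a fixed
per-sample mutation count and exposure strength, and reports how often the
permutation test rejects at p <= 0.05.
"""

from amsd import SimulationSpec, default_baseline, make_fixture_catalog, run_power_grid

catalog = make_fixture_catalog(seed=0)
baseline = default_baseline(catalog)

grid = [
    SimulationSpec(baseline_mutations=50, exposure_signature=sig,
                   exposure_fraction=0.2, samples_per_group=n, replicates=30)
    for sig in ("SIG_SPIKY", "SIG_FLAT")
    for n in (5, 25, 125)
]
cells = run_power_grid(grid, baseline, catalog, n_perm=1000, seed=42)

print(f"{'exposure':<12}{'n/group':>8}{'power':>8}")
for cell in cells:
    print(f"{cell.spec.exposure_signature:<12}{cell.spec.samples_per_group:>8}{cell.power:>8.2f}")

# Power rises with sample size, and the spiky exposure (mass concentrated on a
# few channels) is detected at far smaller cohorts than the flat one, whose
# extra mutations spread thinly across all 96 channels.
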