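"""Signature-mixture cohort simulation and the power-analysis grid.

Simulated cohorts mirror a two-arm exposure study: every control sample draws
a fixed number B of mutations from a baseline mixture of signatures (one
multinomial over channels), and every exposed sample draws the same B baseline
mutations plus round(f*B) extra mutations from a single exposure signature.
Power for a detection method at a grid cell is the fraction of simulated
replicate cohort pairs the method rejects at level alpha.

The module also provides the repository's synthetic signature catalog, which
emulates the structure of a reference catalog (distinct backbone processes, a
spiky exposure signature concentrating its mass on a few channels, and a flat
one spreading mass near-uniformly) without requiring any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import amsd_test
from .signatures import SignatureCatalog, fit_exposures_nnls, wilcoxon_signature_comparison
from .spectra import SBS96, SpectrumMatrix


@dataclass(frozen=True)
class MixtureSpec:
    """A convex combination of catalog signatures, e.g. 30%/60%/10%."""

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        weights = np.array([w for _, w in self.components])
        if np.any(weights < 0):
            raise ValueError("negative mixture weight")
        if abs(weights.sum() - 1) > 1e-9:
            raise ValueError(f"mixture weights sum to {weights.sum()}, not 1")

    def channel_distribution(self, catalog: SignatureCatalog) -> np.ndarray:
        """The mixture's probability vector over channels, sum_i w_i * sig_i."""
        p = np.zeros(len(catalog.schema))
        for sig_id, w in self.components:
            p += w * catalog.profile(sig_id)
        return p

    @classmethod
    def parse(cls, text: str) -> "MixtureSpec":
        """Parse 'SIG_A:0.3,SIG_B:0.6,SIG_C:0.1' notation."""
        parts = []
        for piece in text.split(","):
            sig, _, w = piece.strip().rpartition(":")
            parts.append((sig, float(w)))
        return cls(tuple(parts))


@dataclass(frozen=True)
class SimulationSpec:
    """One cell of the power-analysis grid.

    ``baseline_mutations`` (B) is the fixed per-sample mutation count;
    exposed samples receive round(f*B) extra mutations (round half to even)
    from ``exposure_signature`` alone, so a 2% fraction at B=2500 adds 50.
    """

    baseline_mutations: int
    exposure_signature: str
    exposure_fraction: float
    samples_per_group: int
    replicates: int = 100
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_mutations < 1:
            raise ValueError("baseline_mutations must be >= 1")
        if self.exposure_fraction < 0:
            raise ValueError("exposure_fraction must be >= 0")
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def extra_mutations(self) -> int:
        return int(np.rint(self.exposure_fraction * self.baseline_mutations))


@dataclass
class PowerCell:
    """Estimated detection power of one method at one grid cell."""

    spec: SimulationSpec
    method: str
    p_values: np.ndarray
    power: float = field(init=False)

    def __post_init__(self) -> None:
        # reject at p <= alpha: permutation p-values are discrete and can
        # equal 1, and a level of 1 must reject everything
        self.power = float(np.mean(self.p_values <= self.spec.alpha))


def simulate_sample(
    mixture: MixtureSpec, catalog: SignatureCatalog, n_mutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw one sample's channel counts: a single multinomial from the mixture."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    p = mixture.channel_distribution(catalog)
    return rng.multinomial(n_mutations, p)


def simulate_cohort_pair(
    spec: SimulationSpec,
    baseline: MixtureSpec,
    catalog: SignatureCatalog,
    rng: np.random.Generator | None = None,
) -> tuple[SpectrumMatrix, SpectrumMatrix]:
    """Simulate a (control, exposed) cohort pair for one grid cell.

    Control samples carry B baseline-mixture mutations; exposed samples carry
    B baseline mutations plus round(f*B) mutations from the exposure
    signature alone. Per-sample totals are exact, not Poisson-dispersed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, B = spec.samples_per_group, spec.baseline_mutations
    p_base = baseline.channel_distribution(catalog)
    p_expo = catalog.profile(spec.exposure_signature)
    extra = spec.extra_mutations
    control = rng.multinomial(B, p_base, size=n).astype(float)
    exposed = rng.multinomial(B, p_base, size=n).astype(float)
    if extra > 0:
        exposed += rng.multinomial(extra, p_expo, size=n)
    schema = catalog.schema
    ctrl = SpectrumMatrix(schema, [f"control_{i}" for i in range(n)], control)
    expo = SpectrumMatrix(schema, [f"exposed_{i}" for i in range(n)], exposed)
    return ctrl, expo


def _apply_method(
    method: str,
    control: SpectrumMatrix,
    exposed: SpectrumMatrix,
    catalog: SignatureCatalog,
    n_perm: int,
    seed: int,
    p_convention: str,
) -> float:
    if method == "amsd":
        return amsd_test(
            control, exposed, n_perm=n_perm, seed=seed, p_convention=p_convention
        ).p_value
    if method == "wilcoxon_signatures":
        ea = fit_exposures_nnls(control, catalog)
        eb = fit_exposures_nnls(exposed, catalog)
        return wilcoxon_signature_comparison(ea, eb).overall_p
    raise ValueError(f"unknown method {method!r}")


def run_power_grid(
    grid: list[SimulationSpec],
    baseline: MixtureSpec,
    catalog: SignatureCatalog,
    methods: tuple[str, ...] = ("amsd",),
    n_perm: int = 1000,
    seed: int | None = None,
    p_convention: str = "plus_one",
) -> list[PowerCell]:
    """Estimate detection power for each grid cell and method.

    Every replicate simulates a fresh cohort pair, applies each method to the
    same pair, and records its p-value; power is the rejection rate at the
    cell's alpha. Fully reproducible: one seed sequence drives simulation and
    permutation seeds for all cells.
    """
    root = np.random.default_rng(seed)
    cells: list[PowerCell] = []
    for spec in grid:
        cell_rng = np.random.default_rng(
            spec.seed if spec.seed is not None else root.integers(2**31)
        )
        pvals: dict[str, list[float]] = {m: [] for m in methods}
        for _ in range(spec.replicates):
            control, exposed = simulate_cohort_pair(spec, baseline, catalog, cell_rng)
            perm_seed = int(cell_rng.integers(2**31))
            for m in methods:
                pvals[m].append(
                    _apply_method(m, control, exposed, catalog, n_perm, perm_seed, p_convention)
                )
        for m in methods:
            cells.append(PowerCell(spec, m, np.array(pvals[m])))
    return cells


#: Baseline mixture weights used throughout: 30% / 60% / 10% over the three
#: backbone signatures, emulating a dominant-clock-plus-minor-process profile.
DEFAULT_BASELINE_WEIGHTS = (0.3, 0.6, 0.1)


def make_fixture_catalog(seed: int = 0, schema=SBS96) -> SignatureCatalog:
    """Build the synthetic signature catalog used for simulation and testing.

    Emits five signatures over ``schema``:

    - ``SIG_BB1``..``SIG_BB3`` — distinct backbone processes (sparse Dirichlet
      draws), combined 30/60/10 as the default baseline mixture;
    - ``SIG_SPIKY`` — >=80% of mass on 4 channels (an APOBEC-like profile,
      easy to detect at low mutation counts);
    - ``SIG_FLAT`` — near-uniform, max channel mass <= 3% (a clock-like flat
      profile, hard to detect at low counts).

    Deterministic for a given seed. This is a synthetic stand-in with the
    structure, not the content, of a reference catalog.
    """
    rng = np.random.default_rng(seed)
    C = len(schema)
    profiles = []
    ids = []
    for i in range(3):
        profiles.append(rng.dirichlet(np.full(C, 0.15)))
        ids.append(f"SIG_BB{i + 1}")
    spiky = np.zeros(C)
    peaks = rng.choice(C, size=4, replace=False)
    spiky[peaks] = rng.dirichlet(np.ones(4)) * 0.9
    rest = np.setdiff1d(np.arange(C), peaks)
    spiky[rest] = rng.dirichlet(np.ones(rest.size)) * 0.1
    profiles.append(spiky / spiky.sum())
    ids.append("SIG_SPIKY")
    flat = 1.0 + 0.5 * rng.random(C)  # jittered uniform; max mass ~1.5/C << 3%
    profiles.append(flat / flat.sum())
    ids.append("SIG_FLAT")
    return SignatureCatalog(schema, ids, np.vstack(profiles))


def default_baseline(catalog: SignatureCatalog) -> MixtureSpec:
    """The 30/60/10 backbone mixture over the fixture catalog."""
    return MixtureSpec(
        tuple(zip(("SIG_BB1", "SIG_BB2", "SIG_BB3"), DEFAULT_BASELINE_WEIGHTS))
    )


__all__ = [
    "MixtureSpec",
    "SimulationSpec",
    "PowerCell",
    "simulate_sample",
    "simulate_cohort_pair",
    "run_power_grid",
    "make_fixture_catalog",
    "default_baseline",
    "DEFAULT_BASELINE_WEIGHTS",
]
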