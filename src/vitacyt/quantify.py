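"""Absolute quantification from gated counts.

Microbial load (cells per gram of feces) follows the bead-normalisation
formula: dilution factor x (SytoBC+ count / bead count) x bead stock
concentration, with an optional bead/sample volume-ratio correction (unity for
the standard equal 10 uL aliquots). One gram of feces is taken as one mL of
suspension-equivalent (density config, default 1 g/mL), so the per-mL bead
normalisation reads directly in cells/g.

When a sample is acquired at several dilutions, the run whose total acquired
bead count lies in [200, 1500] and is closest to 850 (the window midpoint) is
adopted; ties break toward the lower dilution factor (more cells acquired,
lower counting noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from vitacyt.gating import StainRunResult, living_rate

BEAD_WINDOW = (200, 1500)
BEAD_TARGET = 850


@dataclass(frozen=True)
class BeadSpec:
    """Counting-bead aliquot: stock concentration (particles/mL) and the bead
    and sample volumes (mL) pipetted into each well."""

    stock_concentration: float = 1.03e6
    bead_volume: float = 0.010
    sample_volume: float = 0.010
    density_g_per_ml: float = 1.0

    def __post_init__(self) -> None:
        if min(self.stock_concentration, self.bead_volume,
               self.sample_volume, self.density_g_per_ml) <= 0:
            raise ValueError("bead spec values must be > 0")

    @property
    def beads_per_well(self) -> float:
        return self.stock_concentration * self.bead_volume


@dataclass(frozen=True)
class DilutionSeries:
    """Stain runs of one sample ordered by strictly increasing dilution."""

    runs: tuple[StainRunResult, ...]

    def __post_init__(self) -> None:
        if len(self.runs) == 0:
            raise ValueError("dilution series needs >= 1 run")
        factors = [r.dilution_factor for r in self.runs]
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("dilution factors must be strictly increasing")


@dataclass(frozen=True)
class LoadResult:
    """Quantified sample: absolute load, living rate, viable load."""

    microbial_load: float
    viable_load: float
    living_rate: float
    selected_dilution: float
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.microbial_load < 0:
            raise ValueError("microbial_load must be >= 0")
        if self.viable_load > self.microbial_load * (1 + 1e-12):
            raise ValueError("viable_load cannot exceed microbial_load")


def microbial_load(run: StainRunResult, beads: BeadSpec = BeadSpec()) -> float:
    """Microbial load in cells per gram of feces.

    dilution x (SytoBC+ / beads) x stock concentration x (bead vol / sample
    vol) / density. The volume ratio is 1 under the standard equal 10 uL
    aliquots; density 1 g/mL maps cells/mL to cells/g.
    """
    if run.bead_count == 0:
        raise ValueError("no beads acquired")
    return (
        run.dilution_factor
        * (run.sytobc_count / run.bead_count)
        * beads.stock_concentration
        * (beads.bead_volume / beads.sample_volume)
        / beads.density_g_per_ml
    )


def select_dilution(series: DilutionSeries) -> StainRunResult:
    """Pick the run with bead count in [200, 1500] closest to 850.

    Ties (equal |bead_count - 850|) go to the lower dilution factor.
    Raises if no run falls in the bead window.
    """
    lo, hi = BEAD_WINDOW
    in_window = [r for r in series.runs if lo <= r.bead_count <= hi]
    if not in_window:
        raise ValueError("no valid dilution: no run with bead count in window")
    return min(in_window, key=lambda r: (abs(r.bead_count - BEAD_TARGET),
                                         r.dilution_factor))


def viable_load(load: float, rate: float) -> float:
    """Viable microbial load: total load x living bacterial rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if load < 0:
        raise ValueError("load must be >= 0")
    return load * rate


def total_living_count(total_count: float, rate: float) -> float:
    """Total living bacterial count (cells/mL): total count x living rate."""
    return viable_load(total_count, rate)


def cfu_per_ml(colonies: int, plated_volume: float, dilution_factor: float = 1.0) -> float:
    """Colony-forming units per mL: colonies / plated volume x dilution."""
    if plated_volume <= 0:
        raise ValueError("plated_volume must be > 0")
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    return colonies / plated_volume * dilution_factor


def quantify_series(
    series: DilutionSeries,
    beads: BeadSpec = BeadSpec(),
) -> LoadResult:
    """Full quantification of one sample's dilution series.

    Selects the in-window run, computes load from it, and the living rate from
    the same run's Eub338+/SytoBC+ counts.
    """
    flags: set[str] = set()
    try:
        run = select_dilution(series)
    except ValueError:
        flags.add("no_valid_dilution")
        raise
    load = microbial_load(run, beads)
    rate = living_rate(run.eub338_count, run.sytobc_count)
    return LoadResult(
        microbial_load=load,
        viable_load=viable_load(load, rate),
        living_rate=rate,
        selected_dilution=run.dilution_factor,
        qc_flags=frozenset(flags),
    )
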