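"""Flow-cytometry gating for CytFISH wells.

A stained well contains a known aliquot of counting beads plus fixed,
FISH-hybridised bacterial cells stained with the membrane-permeant nucleic-acid
dye SytoBC. Gating proceeds in three steps:

1. beads are identified by a rectangular gate in (forward scatter, SytoBC)
   space — beads are large, uniformly bright particles well separated from the
   bacterial cloud;
2. total intact cells (live or dead) are the non-bead events above a SytoBC
   threshold and above a forward-scatter debris floor;
3. viable cells are the SytoBC+ events whose Cy5 (Eub338 probe) intensity
   exceeds a threshold derived from a matched control well hybridised with the
   complementary non-Eub338 probe: the threshold is the (1 - control_fpr)
   empirical quantile of the control's SytoBC+ Cy5 values, so the gate admits
   at most a fixed, small false-positive fraction of probe-negative cells.

The living bacterial rate is the Eub338+ fraction of SytoBC+ events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("fsc", "ssc", "sytobc", "cy5")


@dataclass(frozen=True)
class EventTable:
    """Per-event channel intensities for one acquisition.

    ``events`` holds one row per event with columns ``fsc``, ``ssc``,
    ``sytobc``, ``cy5`` (all finite, >= 0) and, for synthetic data, an optional
    ``truth_label`` column in {bead, live_cell, dead_cell, debris}.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"missing channel {missing[0]}")
        values = self.events[list(EVENT_COLUMNS)].to_numpy(dtype=float)
        if values.size and (not np.all(np.isfinite(values)) or values.min() < 0):
            raise ValueError("channel intensities must be finite and >= 0")
        if "truth_label" in self.events.columns and self.events["truth_label"].isna().any():
            raise ValueError("truth_label must be present for every event or absent")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def has_truth(self) -> bool:
        return "truth_label" in self.events.columns


@dataclass(frozen=True)
class GateConfig:
    """Gate geometry and thresholds.

    ``bead_gate`` is ((fsc_lo, fsc_hi), (sytobc_lo, sytobc_hi)). ``control_fpr``
    is the false-positive budget used to derive the Eub338 threshold from the
    non-Eub338 control; it must be a small fraction in (0, 0.05).
    """

    bead_gate: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0e5, 1.0e7),
        (5.0e3, 1.0e5),
    )
    sytobc_threshold: float = 200.0
    control_fpr: float = 0.005
    debris_floor: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.control_fpr < 0.05:
            raise ValueError("control_fpr must be in (0, 0.05)")
        (f_lo, f_hi), (s_lo, s_hi) = self.bead_gate
        if not (f_lo < f_hi and s_lo < s_hi):
            raise ValueError("bead_gate bounds must be ordered")


@dataclass(frozen=True)
class StainRunResult:
    """Gated counts for one stained well at one dilution."""

    bead_count: int
    sytobc_count: int
    eub338_count: int
    dilution_factor: float
    run_id: str = ""

    def __post_init__(self) -> None:
        if min(self.bead_count, self.sytobc_count, self.eub338_count) < 0:
            raise ValueError("counts must be >= 0")
        if self.eub338_count > self.sytobc_count:
            raise ValueError("eub338_count cannot exceed sytobc_count")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


def _require_events(events: EventTable) -> pd.DataFrame:
    if len(events) == 0:
        raise ValueError("no events")
    return events.events


def _bead_mask(df: pd.DataFrame, config: GateConfig) -> np.ndarray:
    (f_lo, f_hi), (s_lo, s_hi) = config.bead_gate
    fsc = df["fsc"].to_numpy(dtype=float)
    syt = df["sytobc"].to_numpy(dtype=float)
    return (fsc >= f_lo) & (fsc <= f_hi) & (syt >= s_lo) & (syt <= s_hi)


def _sytobc_mask(df: pd.DataFrame, config: GateConfig) -> np.ndarray:
    if config.sytobc_threshold is None:
        raise ValueError("sytobc_threshold not set")
    fsc = df["fsc"].to_numpy(dtype=float)
    syt = df["sytobc"].to_numpy(dtype=float)
    return (
        ~_bead_mask(df, config)
        & (syt >= config.sytobc_threshold)
        & (fsc >= config.debris_floor)
    )


def gate_beads(events: EventTable, config: GateConfig) -> int:
    """Count events inside the rectangular bead gate."""
    df = _require_events(events)
    return int(_bead_mask(df, config).sum())


def gate_sytobc(events: EventTable, config: GateConfig) -> int:
    """Count intact cells: non-bead events with SytoBC above threshold and
    forward scatter above the debris floor. Live and dead cells both count."""
    df = _require_events(events)
    return int(_sytobc_mask(df, config).sum())


def derive_eub338_threshold(control: EventTable, config: GateConfig) -> float:
    """Derive the Eub338 positivity threshold from a non-Eub338 control run.

    Returns the (1 - control_fpr) inclusive empirical quantile (linear
    interpolation) of Cy5 among the control's SytoBC+ events. Positivity uses
    strict ``cy5 > threshold``, so re-applying the threshold to the control
    yields a positive fraction <= control_fpr up to sampling error.
    """
    df = _require_events(control)
    cy5 = df.loc[_sytobc_mask(df, config), "cy5"].to_numpy(dtype=float)
    if cy5.size < 1000:
        raise ValueError("control underpowered: need >= 1000 SytoBC+ control events")
    return float(np.quantile(cy5, 1.0 - config.control_fpr))


def gate_eub338(events: EventTable, threshold: float, config: GateConfig) -> int:
    """Count viable cells: SytoBC+ events with Cy5 strictly above threshold."""
    df = _require_events(events)
    mask = _sytobc_mask(df, config) & (df["cy5"].to_numpy(dtype=float) > threshold)
    return int(mask.sum())


def living_rate(eub338_count: int, sytobc_count: int) -> float:
    """Living bacterial rate: Eub338+ fraction of SytoBC+ events, in [0, 1]."""
    if sytobc_count == 0:
        raise ValueError("no cells gated")
    if not 0 <= eub338_count <= sytobc_count:
        raise ValueError("eub338_count must be in [0, sytobc_count]")
    return eub338_count / sytobc_count


def gate_run(
    events: EventTable,
    threshold: float,
    config: GateConfig,
    dilution_factor: float = 1.0,
    run_id: str = "",
) -> StainRunResult:
    """Gate one stained well into a :class:`StainRunResult`."""
    return StainRunResult(
        bead_count=gate_beads(events, config),
        sytobc_count=gate_sytobc(events, config),
        eub338_count=gate_eub338(events, threshold, config),
        dilution_factor=dilution_factor,
        run_id=run_id,
    )
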