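"""Eub338 enrichment index (EI) for sorted viable/non-viable fractions.

Fecal cells are sorted by Eub338 probe signal into a viable (Eub338+) and a
non-viable (Eub338-) fraction and each fraction is profiled for taxon relative
abundance. For a taxon with relative abundance p in the positive fraction and
n in the negative fraction, and a sample whose living bacterial rate is r, the
frequency-weighted abundances are

    E338P_TA = p * r          (share of all cells that are viable taxon cells)
    E338N_TA = n * (1 - r)

and the enrichment index is the log-ratio statistic

    EI = -[log(E338P_TA) - log(E338N_TA)] / [log(E338P_TA) + log(E338N_TA)].

Both weighted abundances lie in (0, 1), so both logs are negative, |EI| < 1,
EI is positive when the taxon is enriched among viable cells, negative when
enriched among dead cells, and the value does not depend on the log base
(base 10 is used internally). Before the index is computed, taxa detected in
fewer than 50% of samples (in either fraction) are dropped, and zeros are
replaced by half the taxon's minimum nonzero abundance observed across all
samples and both fractions (an optional table-wide global mode is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SortedFractionTable:
    """Taxon x sample relative abundances for one sorted fraction.

    ``abundance`` rows are taxa, columns samples, values in [0, 1] summing to
    1 per sample (before zero replacement). ``fraction_frequency`` gives, per
    sample, the fraction of all cells falling in this sorted gate: the living
    bacterial rate for the Eub338+ fraction, 1 - rate for the Eub338- one.
    """

    abundance: pd.DataFrame
    fraction_label: str
    fraction_frequency: pd.Series
    check_sums: bool = True

    def __post_init__(self) -> None:
        if self.fraction_label not in ("eub_pos", "eub_neg"):
            raise ValueError("fraction_label must be 'eub_pos' or 'eub_neg'")
        a = self.abundance.to_numpy(dtype=float)
        if a.size and ((a < 0).any() | (a > 1).any()):
            raise ValueError("abundances must lie in [0, 1]")
        if self.check_sums and a.size:
            sums = a.sum(axis=0)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("each sample's abundances must sum to 1")
        freq = self.fraction_frequency.to_numpy(dtype=float)
        if ((freq < 0) | (freq > 1)).any():
            raise ValueError("fraction_frequency must lie in [0, 1]")
        if not self.fraction_frequency.index.equals(pd.Index(self.abundance.columns)):
            raise ValueError("fraction_frequency index must match sample columns")

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)


@dataclass(frozen=True)
class EITable:
    """Per-taxon, per-sample EI values plus filter/replacement provenance."""

    ei: pd.DataFrame
    included_taxa: tuple[str, ...]
    replaced_zero_value: pd.Series


def prevalence_filter(
    pos: SortedFractionTable,
    neg: SortedFractionTable,
    min_prevalence: float = 0.5,
) -> list[str]:
    """Taxa detected (nonzero in either fraction) in >= min_prevalence of
    samples; the boundary is inclusive."""
    detected = (pos.abundance > 0) | (neg.abundance > 0)
    prevalence = detected.mean(axis=1)
    return list(prevalence.index[prevalence >= min_prevalence])


def _half_min_nonzero(pos: pd.DataFrame, neg: pd.DataFrame, mode: str) -> pd.Series:
    stacked = pd.concat([pos, neg], axis=1).to_numpy(dtype=float)
    masked = np.where(stacked > 0, stacked, np.inf)
    if mode == "per_taxon":
        mins = masked.min(axis=1)
        if np.isinf(mins).any():
            raise ValueError("taxon with no nonzero abundance: replacement undefined")
        return pd.Series(0.5 * mins, index=pos.index)
    if mode == "global":
        lowest = masked.min()
        if np.isinf(lowest):
            raise ValueError("no nonzero abundance in table")
        return pd.Series(0.5 * lowest, index=pos.index)
    raise ValueError(f"unknown zero-replacement mode {mode!r}")


def replace_zeros(
    pos: SortedFractionTable,
    neg: SortedFractionTable,
    mode: str = "per_taxon",
) -> tuple[SortedFractionTable, SortedFractionTable, pd.Series]:
    """Replace zero abundances with half the minimum nonzero abundance.

    The minimum is taken across all samples and both fractions; by default per
    taxon (mode="per_taxon"), optionally one table-wide value (mode="global").
    Returns the two adjusted tables plus the per-taxon replacement values.
    """
    half_min = _half_min_nonzero(pos.abundance, neg.abundance, mode)

    def _apply(t: SortedFractionTable) -> SortedFractionTable:
        filled = t.abundance.mask(t.abundance == 0, half_min, axis=0)
        return replace(t, abundance=filled, check_sums=False)

    return _apply(pos), _apply(neg), half_min


def weighted_abundance(rel_abundance: float, fraction_frequency: float):
    """Frequency-weighted abundance: relative abundance x sorted-gate
    frequency. Zero abundances must have been replaced first."""
    rel = np.asarray(rel_abundance, dtype=float)
    freq = np.asarray(fraction_frequency, dtype=float)
    if (rel <= 0).any() or (rel > 1).any() or (freq <= 0).any() or (freq > 1).any():
        raise ValueError("inputs must lie in (0, 1]; run replace_zeros first")
    out = rel * freq
    return float(out) if out.ndim == 0 else out


def eub338_index(p_ta, n_ta):
    """EI = -(log p_ta - log n_ta) / (log p_ta + log n_ta), both in (0, 1)."""
    p = np.asarray(p_ta, dtype=float)
    n = np.asarray(n_ta, dtype=float)
    if (p >= 1).any() or (n >= 1).any() or (p <= 0).any() or (n <= 0).any():
        raise ValueError("degenerate abundance: weighted values must be in (0, 1)")
    lp, ln = np.log10(p), np.log10(n)
    out = -(lp - ln) / (lp + ln)
    return float(out) if out.ndim == 0 else out


def ei_table(
    pos: SortedFractionTable,
    neg: SortedFractionTable,
    min_prevalence: float = 0.5,
    zero_mode: str = "per_taxon",
) -> EITable:
    """Full EI computation: prevalence filter, zero replacement, frequency
    weighting, and the per-taxon x per-sample index."""
    if list(pos.abundance.columns) != list(neg.abundance.columns):
        raise ValueError("sample mismatch between sorted fractions")
    if list(pos.abundance.index) != list(neg.abundance.index):
        raise ValueError("taxon mismatch between sorted fractions")
    if pos.fraction_label == neg.fraction_label:
        raise ValueError("fractions must carry distinct labels")
    freq_sum = pos.fraction_frequency + neg.fraction_frequency
    if np.abs(freq_sum.to_numpy(dtype=float) - 1.0).max() > 1e-9:
        raise ValueError("pos and neg fraction frequencies must sum to 1")

    keep = prevalence_filter(pos, neg, min_prevalence)
    if not keep:
        raise ValueError("no taxa pass the prevalence filter")
    pos_f = replace(pos, abundance=pos.abundance.loc[keep], check_sums=False)
    neg_f = replace(neg, abundance=neg.abundance.loc[keep], check_sums=False)
    pos_r, neg_r, half_min = replace_zeros(pos_f, neg_f, zero_mode)

    if (pos_r.abundance.to_numpy() >= 1).any() or (neg_r.abundance.to_numpy() >= 1).any():
        raise ValueError("degenerate abundance: relative abundance of 1 leaves "
                         "no counterpart for the log-ratio")

    p_ta = pos_r.abundance.mul(pos.fraction_frequency, axis=1)
    n_ta = neg_r.abundance.mul(neg.fraction_frequency, axis=1)
    ei = pd.DataFrame(
        eub338_index(p_ta.to_numpy(), n_ta.to_numpy()),
        index=p_ta.index,
        columns=p_ta.columns,
    )
    return EITable(ei=ei, included_taxa=tuple(keep), replaced_zero_value=half_min)
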