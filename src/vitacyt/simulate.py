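"""Synthetic data with known ground truth for every pipeline stage.

Four generators:

* **Starvation kinetics** — a two-compartment first-order model of a washed
  culture held in buffer: viable cells die at ``death_rate`` (losing rRNA and
  hence probe signal while remaining intact), dead intact cells lyse at
  ``lysis_rate`` (leaving the countable population and releasing ATP into the
  supernatant). Closed-form trajectories; mass is conserved
  (viable + dead + lysed = initial total at all times). The default
  Escherichia coli scenario is calibrated so that over 168 h the total intact
  count falls from 10^9.3 to 10^8.9 cells/mL while the viable count falls from
  10^9.3 to 10^7.9 cells/mL; the two rate constants are solved from those
  endpoints at construction time. CFU trajectories apply a constant plating
  efficiency (default 10^-0.3, i.e. CFU from 10^9.0 to 10^7.6 cells/mL).

* **Stained wells** — event tables mixing counting beads with live and dead
  cells. Event numbers are Poisson with means set by the well composition and
  an acquisition fraction; channel intensities are log-normal, with dead-cell
  Cy5 drawn from the same distribution as the non-probe control so the
  control-derived gate is exercised honestly. Dilution series derive per-run
  acquisition fractions from a fixed total-event budget (default 100,000
  events), which reproduces the bead-window behaviour used for dilution
  selection: the more concentrated the cells, the fewer beads among the
  acquired events.

* **Plating** — Poisson colony counts per plate; plates with 30-300 colonies
  are flagged countable.

* **Cohorts** — per-subject living rates from a truncated normal (healthy
  defaults: mean 67.4%, SD 8.7%), log-normal microbial loads, and inflammation
  /bowel-habit markers tied to the living rate through a Gaussian copula that
  targets Spearman rank correlations directly. Sorted-fraction taxon tables
  are generated from per-taxon viabilities: each subject's bulk composition is
  Dirichlet, the positive fraction reweights taxa by viability and the
  negative fraction by (1 - viability), with multinomial sequencing noise.
  Per-subject viabilities are logit-shifted so the composition-implied living
  rate equals the subject's drawn rate exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from vitacyt.gating import EventTable
from vitacyt.quantify import BeadSpec, DilutionSeries
from vitacyt.ei import SortedFractionTable

# ---------------------------------------------------------------------------
# Starvation kinetics
# ---------------------------------------------------------------------------

DEFAULT_TIMEPOINTS = (0.0, 10.0, 24.0, 30.0, 72.0, 168.0)


@dataclass(frozen=True)
class StarvationScenario:
    """Two-compartment starvation decay (viable -> dead -> lysed).

    Rates are first-order per hour; ``atp_yield`` is the ATP released per
    lysed cell (amol/cell); ``plating_efficiency`` maps viable cells to CFU.
    """

    initial_total: float = 10 ** 9.3
    initial_viable_fraction: float = 1.0
    death_rate: float = 0.02
    lysis_rate: float = 0.02
    atp_yield: float = 1.0
    plating_efficiency: float = 1.0
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if self.death_rate < 0 or self.lysis_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 < self.initial_viable_fraction <= 1:
            raise ValueError("initial_viable_fraction must be in (0, 1]")
        if min(self.timepoints) < 0:
            raise ValueError("negative timepoint")
        if 0.0 not in self.timepoints:
            raise ValueError("timepoints must include 0")


def _dead(t: np.ndarray, v0: float, d0: float, kd: float, kl: float) -> np.ndarray:
    """Intact dead cells at time t under viable->dead->lysed kinetics."""
    if kd == 0.0:
        return d0 * np.exp(-kl * t)
    if math.isclose(kd, kl, rel_tol=1e-12):
        return (d0 + kd * v0 * t) * np.exp(-kd * t)
    return (
        kd * v0 / (kl - kd) * (np.exp(-kd * t) - np.exp(-kl * t))
        + d0 * np.exp(-kl * t)
    )


def simulate_starvation(s: StarvationScenario) -> pd.DataFrame:
    """Closed-form trajectory table: time_h, total, viable, dead, lysed
    (cells/mL), cfu (CFU/mL), atp (amol/mL)."""
    t = np.asarray(sorted(s.timepoints), dtype=float)
    if t.min() < 0:
        raise ValueError("negative timepoint")
    v0 = s.initial_total * s.initial_viable_fraction
    d0 = s.initial_total - v0
    viable = v0 * np.exp(-s.death_rate * t)
    dead = _dead(t, v0, d0, s.death_rate, s.lysis_rate)
    total = viable + dead
    lysed = s.initial_total - total
    return pd.DataFrame({
        "time_h": t,
        "total": total,
        "viable": viable,
        "dead": dead,
        "lysed": lysed,
        "cfu": s.plating_efficiency * viable,
        "atp": s.atp_yield * lysed,
    })


def calibrated_ecoli_scenario(
    log10_total_0: float = 9.3,
    log10_total_end: float = 8.9,
    log10_viable_end: float = 7.9,
    log10_cfu_0: float = 9.0,
    t_end: float = 168.0,
    atp_yield: float = 1.0,
) -> StarvationScenario:
    """Default E. coli starvation scenario with rates solved from endpoints.

    The death rate follows in closed form from the viable-count endpoints; the
    lysis rate is solved numerically so the total intact count matches its
    endpoint. Plating efficiency is the constant CFU/viable offset.
    """
    n0 = 10.0 ** log10_total_0
    total_end = 10.0 ** log10_total_end
    viable_end = 10.0 ** log10_viable_end
    kd = math.log(n0 / viable_end) / t_end

    def total_mismatch(kl: float) -> float:
        dead_end = _dead(np.asarray([t_end]), n0, 0.0, kd, kl)[0]
        return viable_end + dead_end - total_end

    # kl=0: nothing lyses, total stays at n0 (> total_end); large kl: total -> viable.
    kl = brentq(total_mismatch, 1e-9, 10.0, xtol=1e-15)
    return StarvationScenario(
        initial_total=n0,
        initial_viable_fraction=1.0,
        death_rate=kd,
        lysis_rate=float(kl),
        atp_yield=atp_yield,
        plating_efficiency=10.0 ** (log10_cfu_0 - log10_total_0),
    )


# ---------------------------------------------------------------------------
# Stained wells and dilution series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelNoise:
    """Log-normal channel intensity model (medians and log-SDs, a.u.).

    Dead-cell Cy5 follows the non-probe control distribution; live-cell Cy5
    sits well above it. ``dead_cy5_shift`` raises dead-cell Cy5 relative to
    the control to model residual rRNA in intact dead cells (1.0 = none).
    """

    bead_fsc: float = 5.0e5
    bead_fsc_sigma: float = 0.05
    bead_sytobc: float = 2.0e4
    bead_sytobc_sigma: float = 0.05
    cell_fsc: float = 5.0e3
    cell_fsc_sigma: float = 0.5
    cell_sytobc: float = 1.0e3
    cell_sytobc_sigma: float = 0.4
    live_cy5: float = 5.0e3
    live_cy5_sigma: float = 0.5
    control_cy5: float = 50.0
    control_cy5_sigma: float = 0.6
    dead_cy5_shift: float = 1.0
    bead_cy5: float = 20.0
    bead_cy5_sigma: float = 0.3
    ssc_over_fsc: float = 0.5
    debris_fsc: float = 100.0
    debris_fraction: float = 0.0


DEFAULT_NOISE = ChannelNoise()

MAX_EXPECTED_EVENTS = 5e6


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, size=n))


def _make_events(
    rng: np.random.Generator,
    n_beads: int,
    n_live: int,
    n_dead: int,
    n_debris: int,
    noise: ChannelNoise,
    control_probe: bool = False,
) -> EventTable:
    """Assemble an event table; with the control (nonsense) probe, live cells'
    Cy5 also follows the control background distribution."""
    parts = []
    if n_beads:
        parts.append(pd.DataFrame({
            "fsc": _lognormal(rng, noise.bead_fsc, noise.bead_fsc_sigma, n_beads),
            "sytobc": _lognormal(rng, noise.bead_sytobc, noise.bead_sytobc_sigma, n_beads),
            "cy5": _lognormal(rng, noise.bead_cy5, noise.bead_cy5_sigma, n_beads),
            "truth_label": "bead",
        }))
    live_cy5_median = noise.control_cy5 if control_probe else noise.live_cy5
    live_cy5_sigma = noise.control_cy5_sigma if control_probe else noise.live_cy5_sigma
    if n_live:
        parts.append(pd.DataFrame({
            "fsc": _lognormal(rng, noise.cell_fsc, noise.cell_fsc_sigma, n_live),
            "sytobc": _lognormal(rng, noise.cell_sytobc, noise.cell_sytobc_sigma, n_live),
            "cy5": _lognormal(rng, live_cy5_median, live_cy5_sigma, n_live),
            "truth_label": "live_cell",
        }))
    if n_dead:
        parts.append(pd.DataFrame({
            "fsc": _lognormal(rng, noise.cell_fsc, noise.cell_fsc_sigma, n_dead),
            "sytobc": _lognormal(rng, noise.cell_sytobc, noise.cell_sytobc_sigma, n_dead),
            "cy5": noise.dead_cy5_shift
                   * _lognormal(rng, noise.control_cy5, noise.control_cy5_sigma, n_dead),
            "truth_label": "dead_cell",
        }))
    if n_debris:
        parts.append(pd.DataFrame({
            "fsc": _lognormal(rng, noise.debris_fsc, 0.5, n_debris),
            "sytobc": _lognormal(rng, noise.cell_sytobc, noise.cell_sytobc_sigma, n_debris),
            "cy5": _lognormal(rng, noise.control_cy5, noise.control_cy5_sigma, n_debris),
            "truth_label": "debris",
        }))
    if not parts:
        df = pd.DataFrame({c: pd.Series(dtype=float)
                           for c in ("fsc", "sytobc", "cy5")})
        df["truth_label"] = pd.Series(dtype=object)
    else:
        df = pd.concat(parts, ignore_index=True)
        df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    df.insert(1, "ssc", df["fsc"] * noise.ssc_over_fsc)
    return EventTable(events=df)


def simulate_stained_well(
    true_concentration: float,
    viable_fraction: float,
    dilution: float,
    beads: BeadSpec = BeadSpec(),
    acquisition_fraction: float = 0.08,
    noise: ChannelNoise = DEFAULT_NOISE,
    seed: int | np.random.Generator = 0,
    control_probe: bool = False,
) -> EventTable:
    """One stained well: Poisson numbers of beads, live and dead cells.

    ``true_concentration`` is the undiluted cell concentration (cells/mL);
    the well receives ``beads.sample_volume`` of the ``dilution``-fold diluted
    suspension plus ``beads.bead_volume`` of bead stock, and the cytometer
    acquires ``acquisition_fraction`` of the well.
    """
    if not 0 < viable_fraction <= 1:
        raise ValueError("viable_fraction must be in (0, 1]")
    if not 0 <= acquisition_fraction <= 1:
        raise ValueError("acquisition_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells_in_well = true_concentration / dilution * beads.sample_volume
    mean_beads = beads.beads_per_well * acquisition_fraction
    mean_cells = cells_in_well * acquisition_fraction
    if mean_beads + mean_cells > MAX_EXPECTED_EVENTS:
        raise ValueError("acquisition too large")
    n_beads = int(rng.poisson(mean_beads))
    n_live = int(rng.poisson(mean_cells * viable_fraction))
    n_dead = int(rng.poisson(mean_cells * (1.0 - viable_fraction)))
    n_debris = int(rng.poisson(mean_cells * noise.debris_fraction))
    return _make_events(rng, n_beads, n_live, n_dead, n_debris, noise,
                        control_probe=control_probe)


def simulate_dilution_series(
    true_concentration: float,
    dilutions: tuple[float, ...] = (400.0, 2000.0, 10000.0),
    beads: BeadSpec = BeadSpec(),
    seed: int | np.random.Generator = 0,
    viable_fraction: float = 1.0,
    total_events: float = 1.0e5,
    noise: ChannelNoise = DEFAULT_NOISE,
) -> list[tuple[float, EventTable]]:
    """Stained wells across a dilution series under a fixed acquisition budget.

    Acquisition stops at ~``total_events`` events per run, so the acquisition
    fraction — and hence the expected bead count — scales inversely with the
    well's cell concentration. Returns (dilution, EventTable) pairs in
    ascending dilution order.
    """
    if len(dilutions) == 0:
        raise ValueError("need >= 1 dilution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for d in sorted(dilutions):
        expected_in_well = (beads.beads_per_well
                            + true_concentration / d * beads.sample_volume)
        frac = min(1.0, total_events / expected_in_well)
        out.append((d, simulate_stained_well(
            true_concentration, viable_fraction, d, beads, frac, noise, rng)))
    return out


def simulate_plating(
    viable_concentration: float,
    plated_volume: float = 0.050,
    dilutions: tuple[float, ...] = (1.0,),
    replicates: int = 1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Poisson colony counts per plate across dilutions and replicates.

    Columns: dilution, replicate, colonies, countable (30-300 colonies).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if viable_concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for d in dilutions:
        mean = viable_concentration * plated_volume / d
        counts = rng.poisson(mean, size=replicates)
        for i, c in enumerate(counts):
            rows.append((d, i, int(c), 30 <= c <= 300))
    return pd.DataFrame(rows, columns=["dilution", "replicate", "colonies", "countable"])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

DEFAULT_TAXA = {
    # family: (Dirichlet weight, viability)
    "Lachnospiraceae": (30.0, 0.80),
    "Bacteroidaceae": (20.0, 0.65),
    "Oscillospiraceae": (12.0, 0.72),
    "Ruminococcaceae": (10.0, 0.55),
    "Prevotellaceae": (8.0, 0.60),
    "Bifidobacteriaceae": (6.0, 0.85),
    "Butyricicoccaceae": (3.0, 0.75),
    "Selenomonadaceae": (2.0, 0.45),
    "Enterobacteriaceae": (1.5, 0.30),
    "Erysipelotrichaceae": (1.0, 0.40),
}

DEFAULT_MARKERS = {
    # marker: (target Spearman rho with living rate, log10 median, log10 sd)
    "calprotectin": (-0.5, 1.7, 0.5),   # ug/g
    "atp": (-0.4, 0.5, 0.4),            # nmol/g
    "igg": (-0.3, 1.0, 0.4),            # ug/g
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a subject cohort.

    Living rates (percent) are truncated-normal on (0, 100); the healthy-adult
    defaults are mean 67.4 and SD 8.7. Loads are log-normal in log10 cells/g.
    ``marker_spec`` maps marker name -> (target Spearman rho with the living
    rate, log10 median, log10 SD); dependence is induced by a Gaussian copula.
    ``taxa`` maps taxon -> (Dirichlet weight, viability in (0, 1)).
    """

    n_subjects: int = 90
    rate_mean: float = 67.4
    rate_sd: float = 8.7
    load_log10_mean: float = 10.9
    load_log10_sd: float = 0.4
    marker_spec: dict = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    taxa: dict = field(default_factory=lambda: dict(DEFAULT_TAXA))
    sequencing_depth: int = 10_000
    dirichlet_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rate_mean < 100:
            raise ValueError("rate_mean must be in (0, 100)")
        if self.rate_sd <= 0:
            raise ValueError("rate_sd must be > 0")
        for name, (rho, *_rest) in self.marker_spec.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"marker {name}: correlation outside [-1, 1]")
        for name, (w, v) in self.taxa.items():
            if w <= 0:
                raise ValueError(f"taxon {name}: Dirichlet weight must be > 0")
            if not 0 < v < 1:
                raise ValueError(f"taxon {name}: viability must be in (0, 1)")


@dataclass(frozen=True)
class CohortResult:
    """Cohort table plus sorted-fraction tables and generator ground truth."""

    cohort: pd.DataFrame
    pos_fraction: SortedFractionTable
    neg_fraction: SortedFractionTable
    truth: dict


def _copula_correlation(spearman: np.ndarray) -> np.ndarray:
    """Pearson correlation of the latent Gaussian achieving given Spearman."""
    return 2.0 * np.sin(np.pi * spearman / 6.0)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _solve_viability_shift(a: np.ndarray, v: np.ndarray, target: float) -> np.ndarray:
    """Logit-shift per-taxon viabilities so sum(a * v_shifted) == target."""
    base = _logit(v)

    def implied(delta: float) -> float:
        return float(a @ (1.0 / (1.0 + np.exp(-(base + delta))))) - target

    lo, hi = -30.0, 30.0
    return 1.0 / (1.0 + np.exp(-(base + brentq(implied, lo, hi, xtol=1e-14))))


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    """Generate a cohort with rates, loads, markers, and sorted fractions.

    Marker columns achieve their target Spearman correlation with the living
    rate via a Gaussian copula (markers are conditionally independent given
    the rate's latent score). Sorted-fraction compositions are reweighted by
    per-taxon viabilities whose subject-level mixture reproduces the drawn
    living rate exactly, then observed through multinomial sequencing noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    markers = list(spec.marker_spec)
    rhos = np.array([spec.marker_spec[m][0] for m in markers])

    k = 1 + len(markers)
    corr = np.eye(k)
    corr[0, 1:] = corr[1:, 0] = _copula_correlation(rhos)
    # markers conditionally independent given the rate latent
    for i in range(1, k):
        for j in range(1, k):
            if i != j:
                corr[i, j] = corr[0, i] * corr[0, j]
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 0:
        raise ValueError("infeasible correlation matrix (non-positive-definite)")
    z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    u = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)

    a_trunc = (0.0 - spec.rate_mean) / spec.rate_sd
    b_trunc = (100.0 - spec.rate_mean) / spec.rate_sd
    rate_pct = truncnorm.ppf(u[:, 0], a_trunc, b_trunc,
                             loc=spec.rate_mean, scale=spec.rate_sd)

    load = 10.0 ** rng.normal(spec.load_log10_mean, spec.load_log10_sd, size=n)
    subjects = [f"S{i:04d}" for i in range(n)]
    cohort = pd.DataFrame({"subject": subjects}).set_index("subject")
    cohort["microbial_load"] = load

    for j, m in enumerate(markers, start=1):
        _, log10_med, log10_sd = spec.marker_spec[m]
        cohort[m] = 10.0 ** norm.ppf(u[:, j], loc=log10_med, scale=log10_sd)

    # bulk composition and viability-tied sorted fractions
    taxa = list(spec.taxa)
    weights = np.array([spec.taxa[t][0] for t in taxa], dtype=float)
    viab = np.array([spec.taxa[t][1] for t in taxa], dtype=float)
    alpha = weights / weights.sum() * spec.dirichlet_concentration
    bulk = rng.dirichlet(alpha, size=n)  # subjects x taxa

    rate_frac = rate_pct / 100.0
    pos_counts = np.zeros((len(taxa), n), dtype=int)
    neg_counts = np.zeros((len(taxa), n), dtype=int)
    v_subject = np.zeros((n, len(taxa)))
    for i in range(n):
        v_i = _solve_viability_shift(bulk[i], viab, rate_frac[i])
        v_subject[i] = v_i
        pos_comp = bulk[i] * v_i
        pos_comp /= pos_comp.sum()
        neg_comp = bulk[i] * (1.0 - v_i)
        neg_comp /= neg_comp.sum()
        pos_counts[:, i] = rng.multinomial(spec.sequencing_depth, pos_comp)
        neg_counts[:, i] = rng.multinomial(spec.sequencing_depth, neg_comp)

    pos_abund = pd.DataFrame(pos_counts / spec.sequencing_depth,
                             index=taxa, columns=subjects)
    neg_abund = pd.DataFrame(neg_counts / spec.sequencing_depth,
                             index=taxa, columns=subjects)
    freq_pos = pd.Series(rate_frac, index=subjects)
    pos_tab = SortedFractionTable(abundance=pos_abund, fraction_label="eub_pos",
                                  fraction_frequency=freq_pos)
    neg_tab = SortedFractionTable(abundance=neg_abund, fraction_label="eub_neg",
                                  fraction_frequency=1.0 - freq_pos)

    cohort["living_rate"] = rate_pct
    cohort["viable_load"] = cohort["microbial_load"] * rate_frac
    cohort["shannon"] = -np.sum(
        np.where(bulk > 0, bulk * np.log2(np.where(bulk > 0, bulk, 1.0)), 0.0),
        axis=1,
    )

    truth = {
        "taxa": taxa,
        "taxon_viability": dict(zip(taxa, viab)),
        "per_subject_viability": pd.DataFrame(v_subject, index=subjects, columns=taxa),
        "bulk_composition": pd.DataFrame(bulk, index=subjects, columns=taxa),
        "target_marker_rho": dict(zip(markers, rhos)),
        "rate_percent": pd.Series(rate_pct, index=subjects),
    }
    return CohortResult(cohort=cohort, pos_fraction=pos_tab,
                        neg_fraction=neg_tab, truth=truth)
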