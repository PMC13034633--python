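# vitacyt

Quantitative viability profiling of gut bacteria from FISH-based flow
cytometry (CytFISH), for microbiome researchers who want absolute, viability-
aware metrics rather than relative abundances alone.

Bulk 16S profiling cannot tell a living community from a dying one: dead,
intact cells still carry DNA. CytFISH combines a membrane-permeant nucleic-acid
stain (SytoBC, marking all intact cells) with a Cy5-labelled universal 16S
rRNA probe (Eub338, whose signal requires intact ribosomal RNA and therefore
marks metabolically viable cells). This package implements the full analysis
chain around that readout:

- **Gating** (`vitacyt.gating`) — bead, SytoBC⁺ and Eub338⁺ counts from
  event-level data; the Eub338 gate is the (1 − f) empirical quantile of the
  Cy5 signal in a matched non-Eub338 (nonsense-probe) control, with a fixed
  false-positive budget f (default 0.5%).
- **Quantification** (`vitacyt.quantify`) — absolute microbial load against
  counting beads,

  load (cells/g) = dilution × (SytoBC⁺ count / bead count) × 1.03 × 10⁶,

  with dilution selected by the bead window (200 ≤ beads ≤ 1500, closest to
  850); living bacterial rate = Eub338⁺/SytoBC⁺; viable load = load × rate;
  CFU/mL from plating counts.
- **Eub338 index** (`vitacyt.ei`) — per-taxon enrichment between sorted
  Eub338⁺/Eub338⁻ fractions. With frequency-weighted abundances
  P = p·r and N = n·(1 − r) (r = living rate),

  EI = −[log P − log N] / [log P + log N] ∈ (−1, 1),

  positive when a taxon is enriched among viable cells; taxa in <50% of
  samples are dropped and zeros replaced by half the taxon's minimum nonzero
  abundance.
- **Cohort statistics** (`vitacyt.stats`) — Spearman correlations with BH-FDR,
  correlation networks, median stratification, Mann–Whitney (exact at small
  n), Shannon diversity, partial-Mayo activity classification (active ≥ 3;
  inactive < 2 with no subscore > 1).
- **Synthetic data** (`vitacyt.simulate`) — ground-truthed generators for
  starvation-culture decay, stained wells with beads, CFU plating, and
  cohorts with copula-linked inflammation markers and sorted-fraction tables.
- **I/O and pipeline** (`vitacyt.io`) — CSV/FCS 3.0 event tables, TSV
  abundance tables, and a config-driven gate → quantify → EI → stats runner
  with a reproducibility manifest.

## Worked example

The starvation experiment in one script — calibrate the default E. coli
scenario from its printed endpoints, then recover the trajectory through the
full simulated flow-cytometry path:

```sh
python analysis/01_starvation_kinetics.py
python analysis/02_fcm_load_recovery.py
```

```
calibrated rates: death 0.01919/h, lysis 0.00852/h, plating efficiency 0.501
168 h: total 8.90, viable 7.90, CFU 7.60 log10 cells/mL; living rate 0.100
```

Over 168 h of starvation the total intact count barely moves (9.3 → 8.9 log₁₀
cells/mL) while the viable count collapses (9.3 → 7.9) — the living rate falls
to 10%, and CFU tracks the viable count at a constant plating efficiency. The
second script pushes every timepoint through stained-well simulation, control-
derived gating and bead-window dilution selection:

```
time_h  log10_load_true  log10_load_est  rate_true  rate_est
  0.0       9.3000          9.2989        1.0000     1.0000
168.0       8.9000          8.9079        0.1000     0.1054
worst |log10 load error| 0.0246
```

`analysis/03_healthy_cohort.py` and `analysis/04_ei_analysis.py` run the
cohort layer: a 90-subject synthetic healthy cohort (living rate mean 67.8%,
median 67.5% under the default model), whose correlation network recovers the
built-in negative rate–calprotectin coupling (ρ = −0.47, q < 10⁻⁴), and a
sorted-fraction EI table whose per-taxon medians rank the generator's true
viabilities with Spearman ρ = 0.96. All tables land in `results/`.

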