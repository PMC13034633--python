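# Methods

## Gating model

Events are points in (fsc, ssc, sytobc, cy5) intensity space. Counting beads
are identified by a rectangular gate in (fsc, sytobc) — default
fsc ∈ [10⁵, 10⁷], sytobc ∈ [5×10³, 10⁵] — because beads are large, uniformly
bright particles; real instruments draw free-hand polygons, but a rectangle is
the simplest region that can be stated numerically and tested. Intact cells
are the non-bead events with sytobc ≥ 200 and fsc ≥ 500 (a single
forward-scatter floor stands in for debris exclusion). The Eub338⁺ gate is
*derived, not fixed*: the threshold is the inclusive type-7 empirical quantile
at (1 − control_fpr) of the Cy5 values among SytoBC⁺ events in a matched
nonsense-probe control, and positivity is strict (`cy5 > threshold`, ties
negative). The default false-positive budget control_fpr = 0.5% makes the
gate reproducible: re-applied to its own control it passes at most ~0.5% of
probe-negative cells. Controls with fewer than 1000 SytoBC⁺ events are
rejected as underpowered.

## Quantification

Microbial load = dilution × (SytoBC⁺/beads) × bead stock concentration
(1.03×10⁶ particles/mL) × (bead volume / sample volume), divided by the fecal
density (default 1 g/mL, so cells/mL of suspension-equivalent reads as
cells/g of feces). The volume ratio is 1 for the standard equal 10 µL
aliquots. `dilution_factor` means the *total* fold-dilution from raw sample to
the stained aliquot; the generator uses the same bookkeeping, so round-trip
tests close exactly. Among replicate dilutions, the run with total bead count
in [200, 1500] closest to 850 is adopted; ties break toward the lower
dilution factor because more acquired cells mean lower counting noise.
Viable load = load × living rate, so viable/total ≡ rate to floating point by
construction. CFU/mL = colonies / plated volume × dilution; the plating
simulator flags 30–300 colonies as countable.

## Eub338 index

For taxon t in sample s with relative abundances p (positive fraction) and
n (negative fraction) and living rate r: P = p·r, N = n·(1 − r),
EI = −(log P − log N)/(log P + log N). Both logs are negative for arguments in
(0, 1), hence |EI| < 1 and the sign convention: EI > 0 ⇔ P > N ⇔ enriched
among viable cells. The value is invariant to the log base (a ratio of log
differences); base 10 is used and base invariance is asserted to 1e-12 in the
tests. Procedure per table pair: (1) prevalence filter — keep taxa nonzero in
either fraction in ≥ 50% of samples, boundary inclusive; (2) zero replacement
— half the taxon's minimum nonzero abundance across all samples *and both
fractions*, per taxon by default (a table-wide global half-minimum is
available behind `zero_mode="global"`); per-taxon keeps the pseudo-abundance
on each taxon's own scale. (3) weight by fraction frequency and apply the
formula. A relative abundance of exactly 1 is rejected as degenerate (its log
is 0 and the complementary fraction is empty). Group contrasts summarise EI
per subject and compare by Mann–Whitney.

## Synthetic data

*Starvation.* Two-compartment first-order kinetics: viable cells die at rate
k_d (losing rRNA but staying intact and countable), dead intact cells lyse at
rate k_l (leaving the countable population, releasing ATP at a fixed yield
per cell). Closed forms: viable(t) = V₀e^(−k_d t); dead(t) solves the linear
cascade; total = viable + dead; lysed = initial − total. This is the simplest
model producing the observed pattern — near-stable totals, collapsing viable
counts, rising supernatant ATP. The default E. coli scenario is *calibrated*,
not hard-coded: k_d follows in closed form from the viable endpoints
(10^9.3 → 10^7.9 cells/mL over 168 h, giving 0.0192/h) and k_l is solved by
root-finding so total matches 10^9.3 → 10^8.9 (0.0085/h). CFU applies a
constant plating efficiency 10^−0.3 ≈ 0.50 (the constant offset between the
viable-count and CFU endpoints). Intermediate-timepoint shape is a model
convention; only the endpoints are calibrated.

*Stained wells.* Event counts are Poisson with means = well content ×
acquisition fraction; channel intensities are log-normal. Dead-cell Cy5 is
drawn from the same distribution as the nonsense-probe control (shiftable via
`dead_cy5_shift` to model residual rRNA in intact dead cells), so the
control-derived gate is exercised honestly rather than against a separated
dummy distribution. Dilution series model a fixed total-event acquisition
budget (default 10⁵ events per run): the acquisition fraction per run is
budget / expected well content, which makes the expected bead count scale
inversely with cell concentration — exactly the behaviour the bead-window
rule exploits to select a well-measured dilution. For a typical fecal load
(~10^10.9 cells/g) the standard 400/2000/10000 series puts the 400-fold run
in window; for starvation cultures (~10^8.9 cells/mL) the analysis uses a
2/10/50 series chosen by the same window arithmetic.

*Cohorts.* Living rates are truncated-normal on (0, 100)% — healthy defaults
mean 67.4, SD 8.7. Loads are log-normal (default log₁₀ mean 10.9, SD 0.4).
Markers (defaults: calprotectin ρ = −0.5, ATP −0.4, IgG −0.3 with the rate;
log-normal marginals) are coupled through a Gaussian copula with latent
Pearson correlation 2·sin(πρ_s/6), targeting Spearman correlation directly —
the natural choice since the downstream statistics are rank-based; markers
are conditionally independent given the rate's latent score. Bulk taxon
compositions are Dirichlet over ten gut families with literature-plausible
weights; per-taxon viabilities span 0.30 (Enterobacteriaceae) to 0.85
(Bifidobacteriaceae). The sorted fractions reweight the bulk composition by
v_t (positive) and 1 − v_t (negative); per subject the viabilities are
logit-shifted so Σ_t a_t·v_t equals the subject's drawn rate exactly, tying
the fraction frequencies to cohort truth without clipping. Sequencing noise
is multinomial at depth 10⁴.

What the generator does *not* emulate: probe-affinity differences between
taxa, viable-but-nonculturable states, compositional correlations between
taxa beyond the Dirichlet, batch effects, doublets, spectral spillover, or
real 16S read processing. Passing recovery tests therefore shows the
*analysis chain* is correct and well-calibrated under its stated model, not
that the biological assay is unbiased.

## Statistics

Spearman ρ is the Pearson correlation of mid-ranks with the t-approximation
p-value (scipy), pairwise-complete over missing data. BH-FDR is the standard
step-up (statsmodels), applied as one family per correlation matrix. The
correlation network keeps edges with q < α (default 0.05). Median splits
assign the boundary value to the high group. Mann–Whitney returns the exact
enumerated two-sided p (tie-safe, criterion |U − mn/2| ≥ observed) for
m + n ≤ 12 and the tie-corrected normal approximation with continuity
correction otherwise; enumeration at m = n = 6 shows the approximation is
good to ~0.016 worst-case, which is why small samples get the exact branch.
Shannon diversity is in bits (log₂). Partial-Mayo activity: ≥ 3 active; < 2
with no subscore > 1 inactive; the undefined score-2 region is labelled
`intermediate` rather than guessed. Kruskal–Wallis and the pairwise post-hoc
screen are delegated to scipy.

## Numerical and design notes

- All generators take integer seeds (or a shared `numpy` Generator) and are
  bitwise deterministic given the seed.
- log₁₀ transforms of loads floor at 1 cell to avoid −∞ on zero counts.
- Starvation conservation (viable + dead + lysed = initial) holds to 1e-9
  relative; the k_d = k_l and k_d = 0 degeneracies use their analytic limits.
- Problem sizes in the analyses: 90-subject cohorts, 10⁵-event acquisitions,
  100-plate CFU recovery, 200-replicate null-network calibration — sizes at
  which the binomial/Poisson error budgets (±0.05 log₁₀ on loads, ±2 points
  on rates) are comfortably resolvable on a laptop.
- Known limitations: the bead gate assumes beads and cells are separable in
  (fsc, sytobc); strongly autofluorescent samples would violate it. The EI is
  undefined for taxa absent from both fractions everywhere, and unstable when
  a weighted abundance approaches 1 (single-taxon communities). The copula
  targets rank correlation only — marker marginals carry no mechanistic
  meaning.
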