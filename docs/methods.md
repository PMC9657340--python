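# Methods

## The discrete washout model

The simulator is modelled as a chain of perfectly stirred vessels with fixed
working volumes, fed and drained in discrete cycles. One cycle moves the
transfer volume `u` into each vessel: fresh medium (tracked-organism
concentration usually 0) into the first, each vessel's discharge into the
next, and the last vessel's discharge to waste. Mixing follows the
volume-weighted average `r = (M1 r1 + M2 r2)/(M1 + M2)`, and discharging `u`
of the mixture restores the working volume, so a single organism-free-fed
vessel retains the fraction `V/(V+u)` per cycle.

Two transit orderings are implemented:

* **simultaneous** (default): every vessel's discharge concentration is
  computed from the *pre-cycle* state (`d_i = mix(u, c_{i-1}, V_i, c_i)`),
  then all mass fluxes are applied at once
  (`V_i c_i' = V_i c_i + u d_{i-1} - u d_i`, feed entering at the feed
  concentration, waste receiving `u d_k`). The update telescopes, so mass is
  conserved exactly, and it reduces to the `V/(V+u)` retention for a single
  vessel. This is the only discretisation we found that satisfies both
  properties while using only pre-cycle information, which is why it is the
  default.
* **sequential**: vessels update upstream-first, each receiving its
  upstream neighbour's *already-mixed* discharge. Also exactly conserving;
  identical for a single vessel, very slightly faster downstream transport
  for chains.

The two orderings differ below 10% in downstream concentrations for the
default geometry; both are exposed via `transit_ordering` because the
physical hardware pumps all vessels within minutes of each other and neither
idealisation is obviously right.

Assumptions: no volume change between cycles, perfect mixing, the mucosal
(mucin-carrier) phase is excluded from the mass balance (its volume and
cell load are small); mucosal qPCR series are handled descriptively only.
Concentrations below 1e-30 cells/mL are clamped to zero to avoid denormal
drift; clamped mass is tracked on the trajectory so conservation checks
remain exact.

Defaults (configuration values, not measured constants): AC/TC/DC working
volumes 500/800/600 mL, transfer 140 mL/cycle, 3 cycles/day, 31-cycle
horizon, dose 2.5e9 cells into the AC at cycle 0 (5e6 cells/mL). Note that
with this geometry the slowest washout mode is the TC (`800/940 = 0.851`
per cycle), so the chain retains a few percent of the initial dosed
concentration in the downstream vessels at cycle 30 — washout is
substantial but not complete on that horizon.

### Growth extension

A per-compartment net multiplier `g_i >= 0` scales resident cells at the
start of each cycle, before transit. `g = 1` reproduces the no-growth model
bit-for-bit (the multiplication is skipped entirely in that code path);
`g = (V+u)/V` exactly cancels dilution in a single vessel. `g` lumps birth
and death into one net factor — the model cannot separate replication from
mortality, only net balance.

## qPCR quantification

DNA mass converts to genome copies with
`copies = ng * 6.0221e23 / (3,010,111 * 660 * 1e9)` (~3.031e5 copies/ng,
equivalently a 3.30 fg genome). One chromosomal target copy is counted as
one cell; `copies_per_cell` is exposed for multi-copy assays. Amplification
curves and standard-curve fitting are out of scope — inputs are mass,
copies or cells.

The endogenous baseline is the arithmetic mean (optionally median) of
pre-dose measurements; it is subtracted from post-dose values, clamping at
zero with a reported clamp count since abundances cannot be negative.

## Engraftment inference

* **Fold change**: final post-dose concentration over baseline. A zero
  baseline yields a flagged "from zero" result carrying the final value.
* **Classification**: geometric mean R of measured/predicted over the last
  6 eligible cycles; R > 2 is `ABOVE_EXPECTED`, R < 1/2 `BELOW_EXPECTED`,
  else `TRACKING`. Both window and factor are configurable; the two-fold
  default corresponds to ~0.3 log10, a deviation comfortably larger than
  the ~0.1 log10 measurement noise. Measured zeros are replaced by half the
  series' smallest positive value before taking logs. Cycles where the
  prediction has fallen below the endogenous baseline are excluded
  (`min_predicted`): once the expected signal is under the baseline, the
  baseline-subtracted measurement is dominated by subtraction noise and
  comparing the two only injects variance. The pipeline passes the
  estimated baseline; standalone calls default to no floor.
* **Growth fit**: 1-D least squares of log measured concentration against
  the log of the chain simulation as a function of the compartment's `g`,
  fitted in chain order with upstream compartments frozen at their own
  estimates (downstream state cannot influence upstream vessels). Only
  post-dose cycles with positive measurements above `min_level` enter;
  cycles where the model is structurally zero (no mass can have arrived
  yet) are dropped — structural zero-ness does not depend on `g`, so this
  does not bias the profile. Optimisation is bounded Brent on
  `g ∈ [1e-3, 5]` with `xatol = 1e-9`; noise-free data is recovered to
  better than 1e-6. Intervals come from a residual bootstrap (resample
  log-residuals, refit; 199 resamples, percentile method, fixed default
  seed) — appropriate because the lognormal noise model makes log-residuals
  approximately exchangeable.

Note the classification and the fit answer different questions: a vessel
downstream of a growing compartment can sit far above the *whole-chain*
no-growth prediction while its own fitted multiplier is below 1, because
upstream growth feeds it more cells than pure washout would.

## Community metrics

* Probiotic ASVs are removed before diversity (they would trivially inflate
  post-dose values); removal matches explicit ids or a genus-level lineage
  match (Lactobacillus/Lacticaseibacillus). Removed read totals are
  reported per sample.
* Shannon uses natural log by default (switchable); richness counts
  positive taxa; Faith's PD (root-inclusive, via scikit-bio) sums the
  branch lengths connecting observed tips to the root. No rarefaction is
  applied; per-sample depth is reported alongside the metrics so users can
  judge comparability.
* Group testing: one-way ANOVA (scipy) with Tukey–Kramer adjusted pairwise
  p-values (statsmodels). Groups with fewer than two samples are excluded
  with a warning.
* Taxonomic aggregation parses Greengenes-style prefixed lineages
  (`k__; p__; ...`), tolerating empty or missing ranks, pools unassigned
  taxa as "unclassified", and normalises each sample to proportions.
  The F/B ratio is the Firmicutes over Bacteroidetes proportion (depth
  invariant); zero-Bacteroidetes samples flag as infinite.
* SCFA statistics: Pearson r with two-sided t-distribution p (n−2 df) and
  0.05/0.01/0.001 stars; pre/post comparisons use Welch's unequal-variance
  t-test per (bioreplicate × region × acid) stratum with no multiplicity
  correction, reporting the raw count of significant strata — the
  convention for raw significant-pair tallies. Understaffed strata are
  skipped and reported.

## Synthetic data

The generators emulate the study conditions the analysis targets: three
bioreplicates, AC/TC/DC chain, single AC dose of 2.5e9 cells, 31 cycles,
endogenous baselines log-uniform in [1.3e3, 8e4] cells/mL, net growth 1.2
in the AC and 0.9 downstream, multiplicative lognormal qPCR noise
(sd 0.1 on the log scale — qPCR error is multiplicative). Mucosal series
scale the luminal signal by 0.03 (1–2 log lower). Feature tables are
Dirichlet-multinomial (the minimal overdispersed count model) with a
bioreplicate-specific base composition, a smaller Dirichlet concentration
in the AC (0.1 vs 1.0) so AC communities are less even and hence less
diverse, Firmicutes+Bacteroidetes-dominated lineages, and a probiotic ASV
spiked at 5% of reads into post-dose AC samples. SCFA tables multiply
per-acid base means by region factors 1.0/1.4/1.8 (AC<TC<DC) with lognormal
noise (sd 0.15, plus 0.1 extra spread early post-dose). Trees are random
binary joins with exponential branch lengths (mean 0.1).

What the generators do *not* emulate: compositional correlation between
taxa, read-level sequencing error and chimeras, time-autocorrelated qPCR
drift, pH/nutrient feedback on growth, and any coupling between the
community tables and the dosed organism's trajectory beyond the spiked ASV.
Passing tests therefore demonstrate correctness of the estimators under the
stated noise models, not robustness to every artefact of real sequencing
data.

All generators are deterministic for a fixed seed, each drawing from its
own fixed substream so outputs do not depend on call order.

## Numerical and reporting choices

JSON reports and numeric TSV/CSV outputs serialise floats at 12 significant
digits, making repeat runs byte-identical while round-tripping within
1e-11 relative error. Cycles are integers with the dose at cycle 0 and
pre-dose cycles negative. ANOVA refuses all-constant data; Shannon refuses
all-zero vectors; degenerate mixtures (`M1 + M2 = 0`) and negative inputs
raise domain errors rather than propagating NaNs.

## Problem sizes

Default analyses use 60-taxon tables at depth 2e4 (54 samples), 31-cycle
trajectories, 20-seed recovery grids, 50–100-seed classification
Monte-Carlo runs, and 1000-replicate null calibrations; these sizes give
stable rates (binomial se under 0.7 percentage points at 1000 reps) while
keeping a full test run to a few minutes.

## Known limitations

* The growth multiplier is net; mortality versus upstream retention in
  downstream vessels is not identifiable from luminal qPCR alone, and the
  package does not attempt it.
* The classification threshold (2-fold over a 6-cycle window) is a
  judgement calibrated to the generator's noise level; heavier-tailed noise
  would warrant a wider factor.
* Faith's PD requires every observed ASV to be a tree tip; trees with
  missing tips are rejected rather than pruned.
* The baseline is assumed constant over the experiment; drifting endogenous
  levels would bias fold changes and late-cycle classifications.
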