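# Methods

This note documents the models, conventions and numerical choices behind
`sipcoculture`, in the spirit of a model-description appendix: what is
computed, under which assumptions, and what the synthetic data do and do not
emulate.

## Isotope quantification

**Ratio → atom fraction.** The cyanide pair carries one nitrogen atom, so
the heavy fraction is q = R/(1+R). The carbon dimer carries two carbon
atoms; assuming random pairing of atoms with heavy fraction p, the expected
species abundances are (1−p)² : 2p(1−p) : p² for ¹²C₂ : ¹²C¹³C : ¹³C₂, hence
R = ¹²C¹³C/¹²C₂ = 2p/(1−p) and p = R/(2+R). This "pairing" model reduces the
printed natural standard ratio 0.02247 to p = 0.01111, the natural ¹³C
abundance — which is the consistency check that motivated the choice. A
"linear" convention (p = R/(1+R) applied to the dimer ratio) is available
via `IsotopeStandards(dimer_model="linear")` for comparability with
simpler treatments; APE is always computed on atom fractions, so under the
default model APE is exactly zero at the standard ratio for both species.

**Net assimilation.** X_net = (F_cell − F_unlabeled)/(F_substrate −
F_unlabeled). F_unlabeled derives from the standard ratios above. For
nitrogen, F_substrate = 0.5 × 0.99 + 0.5 × 0.003657 ≈ 0.4968 (half the
ammonium replaced by 99 atom% ¹⁵N stock, the rest natural). For carbon the
gas-delivered source cannot be mass-balanced in an open system, so the
arithmetic mean of algal F¹³C over all algal cells and timepoints of the
experiment stands in for the source. X_net values outside [0, 1] are
retained and flagged, never clipped. Medians are reported for X_net
(robust to the long-tailed cell-to-cell spread), means for APE.

**ROI summarization.** Counts are summed per labeled region with
`scipy.ndimage.sum_labels`; a naive per-pixel loop serves as the test
oracle. ROIs under 5 pixels (default) are excluded and reported, not
silently dropped.

**Background threshold.** When unlabeled / killed-control fields are
supplied, the maximum |APE| among control cells is reported per isotope as
the enrichment detection threshold for the experiment.

## Growth models

Doublings d = log₂(N_t/N₀), computed from raw CFU fold-changes and never
rounded to integers (the interesting regime is fractional d). Expected
new-biomass fraction after balanced growth: 1 − 2⁻ᵈ. Reductive division is
flagged at a timepoint when measured X_net < 0.5 × expected while d has
increased since the previous assessed timepoint; the 0.5 threshold is
configurable (`flag_ratio`) and sits midway between balanced growth and
the ~0.2–0.45 measured-to-expected ratios typical of starved cocultures.
N₀ defaults to the first observation of each replicate.

Significance testing uses the classical Student's t (pooled variance
unpaired; difference-based paired), two-tailed, α = 0.05, because that is
the convention of the comparisons this pipeline reproduces; Welch's
correction is available behind a flag. Zero-variance comparisons with
identical means return p = 1 by convention and are logged.

## Lysis budget

yield = (CFU_lysate − CFU_baseline)/lysed-cell density; required lysed
density = observed proliferation / yield; required fraction = 100 ×
required/algal density. The baseline defaults to 0 when no matched
carbon-free monoculture is supplied, and both baseline conventions are
computed. A one-significant-figure "headline" yield is reported alongside
full precision, and the headline value drives the headline budget
(100 CFU/cell → 1.1 × 10⁵ cells/ml → 1.8%); replicate scatter propagates
into the required fraction by the first-order delta method (the fraction
scales as 1/yield, so relative sds are equal). The consistency verdict
compares the required fraction against the measured lysis range widened by
that propagated sd: `consistent`, `insufficient_lysis` (requirement above
the range) or `excess_lysis` (below it).

## Assays

The B₁₂ bioassay signal is ΔOD = OD(ΔmetE) − OD(ΔmetEΔmetH), floored at 0
with a QC flag (a negative B₁₂ signal is biologically meaningless). The
standard curve is a four-parameter logistic in log₁₀ concentration when at
least 6 distinct standards are available, otherwise a monotone
piecewise-linear interpolant in log space; a standard series that decreases
by more than the noise tolerance between consecutive concentrations is
refused with a diagnostic. Quantification inverts the fitted curve; the
limit of detection is the ΔOD of the lowest standard, and any reading
outside the calibrated range is censored at the nearest bound with a
`<LOD`/`>ULOQ` flag — no numeric concentration is ever extrapolated.

Cytotoxicity: 100 × (sample − blank)/(killed − blank); affine-invariant in
the fluorescence scale; values > 100% flagged, not clipped. NPOC:
measured × dilution factor.

## Synthetic-data generator

The generator emulates the study conditions of a dual-label coculture
experiment: duplicate cultures, half the ammonium at 99 atom% ¹⁵N from
inoculation, ¹³CO₂ bubbling from 13 h post-inoculation, sampling at 14, 24,
36 and 48 h with ≥ 5 algal and ≥ 8 bacterial measurable cells per culture
per timepoint, continuous versus 12 h/12 h diurnal light, ~1–2% of the
algal population lysing per day, and bacterial reductive division (mean
length 2.3 → 1.4–1.5 µm).

**Population layer (deterministic).** Algae grow logistically under
continuous light (doubling time 8 h, carrying capacity 4 × 10⁶ cells/ml) or
hold density through the light phase and double just after nightfall under
diurnal light, capped at the same carrying capacity. Each hour a constant
fraction (1%/day) of the algal population lyses, releasing 20 pg C per
cell, and each cell exudes NPOC at a regime-specific rate. Bacteria take up
a single dissolved-organic-carbon pool with Monod kinetics (Ks = 0.3 µg/ml,
per-CFU Vmax capping growth at ~0.2 h⁻¹) and convert it to CFUs at the
yield implied by 100 CFU per lysed algal cell; a biomass-retention cap
(30% of assimilated carbon, at most `reductive_division_max` extra
doublings beyond what biomass allows) bounds the CFU count. Only half the
exuded NPOC is bioavailable by default; the wild-type-strain scenario sets
that fraction to 0, so its bacterial growth is fed by lysate alone and the
necromass budget closes exactly against the simulated lysis fraction.
Cumulative assimilation never exceeds cumulative release (carbon
conservation), and identical scenario + seed gives bit-identical outputs.

The regime-specific exudation rates (0.10 and 0.028 µg NPOC per 10⁶ cells
per hour) were calibrated once so the packaged scenario pair reproduces the
observed experiment endpoints — a ~3-fold continuous/diurnal ratio of
maximum bacterial density and ~15 µg/ml cumulative NPOC under continuous
light — and are not free parameters of the analysis.

**Single-cell enrichment layer (phenomenological).** Per-cell isotope truth
follows saturating trajectories anchored to observed endpoint enrichments
rather than being derived from the population mass balance: algal ¹³C rises
toward an asymptotic source fraction (0.35) after label start; bacterial
¹³C approaches a fixed fraction of the time-averaged algal composition
(0.17 continuous, 0.09 diurnal at 48 h); bacterial ¹⁵N-read new-biomass
fraction saturates toward 0.34, except in monocultures where it tracks
balanced CFU growth until the carbon pool is exhausted. Per-cell lognormal
jitter (sd 0.15 in log space, median-preserving) supplies cell-to-cell
spread. This split is deliberate: per-cell enrichments, CFU yields and cell
lengths measured in such experiments are not mutually closable as a single
mass balance (small cells, carbon recycling and respiration decouple CFU
counts from biomass carbon), so the generator reproduces each observable's
endpoint statistics and keeps strict conservation on the population carbon
ledger, where it is well defined. Consequently, pipeline tests against this
generator demonstrate recovery of known per-cell enrichments from Poisson
count images and correct propagation through X_net — not the biological
coupling between density dynamics and single-cell enrichment, which is
imposed, not emergent.

**Rendering.** Fields are 256 × 256 px at 0.1 µm/px (rods of 1.4–2.3 µm
span ≥ 14 px). Algae are disks (Ø 5–7 µm), bacteria are capsules (width
0.5 µm, length from truth, random orientation), placed by rejection
sampling with an explicit-position override that errors on overlap, naming
the colliding cells. Each cell's expected total carbon-dimer counts
(6 × 10⁵ alga, 1 × 10⁵ bacterium) are spread uniformly over its footprint
and partitioned (1−p)² : 2p(1−p) between ¹²C₂ and ¹²C¹³C — the p² share is
the uncollected ¹³C₂ species — and the nitrogen budget (0.6 × carbon)
partitioned (1−q) : q; every pixel of every channel is an independent
Poisson draw over a near-zero background (0.01 counts/px). At these budgets
the binomial sampling error on a recovered atom fraction is ≲ 10⁻³, so
quantification error is dominated by the intended cell-to-cell spread.

**What the generator does not emulate:** instrument effects (deadtime,
quasi-simultaneous arrival, beam drift), segmentation error (masks are
exact), within-cell enrichment heterogeneity, algal cell-cycle size
distributions, and any mechanistic link between light regime and exudate
composition. Passing tests therefore validate the quantification chain and
the budget arithmetic, not instrument correction or segmentation.

## Numerical choices and sizes

Euler integration at dt = 0.1 h (dynamics are smooth and slow; halving dt
changes endpoints by < 0.5%). Observation noise: multiplicative lognormal,
CV 5%, on density observations every 2 h. All randomness flows from one
root seed through `numpy` `SeedSequence` spawning, one child per stage.
The packaged analyses render 16 fields per run (2 regimes × 4 timepoints ×
2 replicate cultures) with 11 cells each, which keeps a full pipeline run
under ~5 s on one CPU while leaving ≥ 10 bacterial cells per pooled group,
matching the pooling convention of the quantification (n ≥ 10). The
acceptance script's density-fold target uses the same packaged scenarios at
the caller's seed.

## Known limitations

- The coculture enrichment truth is imposed (see above); the generator
  cannot be used to test hypotheses about the coupling of growth and
  enrichment.
- The 4PL fit needs ≥ 6 informative standards; with the classic 4-point
  decade series the piecewise-linear fallback introduces up to ~10%
  interpolation bias between standards, within the assay's replicate noise.
- `quantify_experiment` estimates the carbon source from the supplied algal
  cells only; experiments with very few algal ROIs inherit that sampling
  error in every bacterial C_net.
- Lengths enter the truth table directly; the rendered rod footprint is the
  length rounded to pixels, so length statistics should be read from the
  truth/annotation tables, not re-measured from masks.
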