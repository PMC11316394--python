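# sipcoculture

Quantitative single-cell stable-isotope-probing (SIP) analysis of a
phototroph–heterotroph coculture: a green alga (*Chlamydomonas reinhardtii*)
fixing CO₂ in the light, and a vitamin-B₁₂-producing bacterium
(*Mesorhizobium japonicum*) living off the carbon the alga releases.

The package is for microbial ecologists who want to quantify how much carbon
and nitrogen actually moves between partners in such a coculture, using
nanoSIMS-style ion-count images of labeled cells, CFU/cell-density time
series, and plate assays — or to prototype that analysis on synthetic data
with known ground truth before spending instrument time.

## What it computes

**Per-cell isotope enrichment.** From co-registered ion-count images
(¹²C₂⁻, ¹²C¹³C⁻, ¹²C¹⁴N⁻, ¹²C¹⁵N⁻, ³²S⁻) and a cell label mask, counts are
summed per region of interest and converted to heavy-isotope atom fractions:
for the cyanide pair p = R/(1+R); for the carbon dimer, random pairing of
atoms gives p = R/(2+R). Enrichment is reported as atom percent enrichment,
APE = 100 (F_cell − F_natural), using natural-abundance standard ratios
0.02247 (C) and 0.00367 (N), and as net assimilation,

    X_net = (F_cell − F_unlabeled) / (F_substrate − F_unlabeled),

the fraction of a cell's biomass newly synthesized from the labeled source.
For ¹⁵N the substrate composition is known from the medium recipe (half the
ammonium at 99 atom% ¹⁵N); for ¹³C, delivered as gas in an open system, the
mean algal biomass composition of the experiment serves as the source
estimate.

**Reductive-division diagnosis.** After d balanced doublings, the expected
new-biomass fraction is 1 − 2⁻ᵈ. When the tracer-measured X_net falls far
below this expectation while CFUs keep doubling, the bacteria are dividing
without commensurate biomass synthesis — reductive division, the starvation
response that also shows up as shrinking cell length.

**Lysis budget.** From the CFU yield supported by lysate of a known algal
cell density, the model computes the per-lysed-cell yield, the lysed-cell
density required to explain observed bacterial proliferation, that
requirement as a percentage of the algal population, and whether it is
consistent with the lysis fraction measured by a membrane-integrity assay.

**Assay calibrations.** Two-strain B₁₂ bioassay (ΔmetE minus ΔmetEΔmetH
differential growth against a monotone standard curve, with limit-of-
detection censoring), cytotoxicity relative to a killed control, and NPOC
dilution correction.

**Synthetic data.** A seeded generator produces everything above with known
ground truth: logistic (continuous light) or nightfall-synchronized
(diurnal 12 h/12 h) algal growth, exudation and lysis feeding a dissolved
carbon pool, Monod bacterial uptake, per-cell enrichment and cell-length
truth tables, Poisson-rendered ion images, and assay plates.

## Worked example

```
sip-coculture report --seed 1 --out-dir out/
```

prints (abridged):

```
Median bacterial C_net at 48 h: 0.171 (continuous) vs 0.090 (diurnal); t = 9.38, p = 2e-10 *
Max bacterial density fold (continuous/diurnal): 3.03
Algal plateau (cells/ml): continuous 4.04e+06, diurnal_12_12 4.12e+06

Lysis budget (worked example): yield 106.2 CFU/cell (headline 100 ± 42),
required 1.1e+05 cells/ml = 1.8% of the population -> consistent
  t= 24.0 h  d=1.97  expected=0.745  measured=0.183  REDUCTIVE DIVISION
  t= 48.0 h  d=4.26  expected=0.948  measured=0.270  REDUCTIVE DIVISION
```

Reading this: under continuous light about 17% of bacterial cell carbon at
48 h is algal-derived, versus 9% under a diurnal light cycle — continuous
light supports roughly 3-fold more bacteria, so night-time algal
fermentation does not boost the heterotroph. The bacteria double ~2–4 times
while synthesizing only ~20–30% new biomass (reductive division). A
per-lysed-algal-cell yield of ~100 CFU means ~1.1 × 10⁵ lysed cells/ml —
1.8% of the algal population, inside the 1–3% lysis measured independently —
fully accounts for the bacterial growth: necromass, not exudate, feeds the
heterotroph.

The same stages are available piecewise (`simulate`, `quantify`, `growth`,
`lysis-budget`, `bioassay`, `cytotox`, `validate`) and as library functions;
see `sip-coculture --help`.

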