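# Lysis-budget worked example: measured quantities for the default coculture.
#
# Triplicate lysate cultures reached 1.7e8 CFU/ml on average after 48 h in
# soluble lysate prepared from 1.6e6 algal cells/ml.  The individual
# replicate values are a synthetic stand-in constructed to reproduce that
# mean and the ~40% relative sd of the per-cell yield.
cfu_in_lysate_per_ml: [1.02e8, 1.70e8, 2.38e8]
cfu_baseline_per_ml: 0.0
lysed_algal_density_per_ml: 1.6e6
# CFU/ml increase observed in the matched cocultures.
observed_proliferation_cfu_per_ml: 1.1e7
# Algal population density in those cocultures (cells/ml).
algal_density_per_ml: 6.1e6
# Membrane-integrity assay range for the same cultures (percent).
measured_lysis_range_pct: [1.0, 3.0]
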