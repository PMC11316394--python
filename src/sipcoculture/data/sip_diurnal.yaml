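light_regime: diurnal_12_12
duration_h: 72.0
algal_inoculum: 500000.0
algal_K: 4000000.0
algal_doubling_h: 8.0
exudation_rate: 0.028
exudate_usable_fraction: 0.5
lysis_fraction_per_day: 0.01
carbon_per_algal_cell_ug: 2.0e-05
bacterial_inoculum_cfu: 1000000.0
bacterial_yield_per_lysed_cell: 100.0
vmax_ug_per_cfu_h: 4.0e-08
Ks_ug_per_ml: 0.3
biomass_retention: 0.3
carbon_per_cfu_ug: 4.0e-08
reductive_division_max: 2.0
initial_doc_ug_per_ml: 0.0
label_start_h: 13.0
f15N_substrate: null
f13C_source_max: 0.35
algal_label_tau_h: 12.0
cnet_48h: 0.09
cnet_tau_h: 20.0
nnet_max: 0.34
nnet_tau_h: 30.0
b12_onset_h: 24.0
cell_length_start_um: 2.3
cell_length_min_um: 1.4
cell_length_tau_h: 8.0
cell_length_sd_um: 0.15
alga_diameter_um:
- 5.0
- 7.0
sampling_timepoints_h:
- 14.0
- 24.0
- 36.0
- 48.0
n_replicates: 2
n_algae_per_sample: 3
n_bacteria_per_sample: 8
enrichment_jitter: 0.15
obs_noise_cv: 0.05
obs_every_h: 2.0
dt_h: 0.1
seed: 0
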