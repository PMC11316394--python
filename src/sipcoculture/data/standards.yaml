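# Natural-abundance instrument standards and labeling-design constants.
R_std_C: 0.02247      # 12C13C- / 12C2- ratio of unlabeled biomass
R_std_N: 0.00367      # 12C15N- / 12C14N- ratio of unlabeled biomass
p_label_15N: 0.99     # atom fraction 15N of the labeled ammonium stock
substrate_mix_fraction: 0.5  # fraction of medium ammonium from the labeled stock
dimer_model: pairing
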