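{
  "version": "1.0",
  "comment": "Length-mass power laws (ln mg fresh weight from ln mm) and metabolic-rate regression coefficients (J/h from mg, eV) per taxon group; all overridable. Metabolic defaults use the overall phylogenetically corrected invertebrate regression.",
  "mass_regressions": {
    "Lumbricidae": {"intercept": -3.71, "length_exp": 2.3},
    "Diplopoda": {"intercept": -3.88, "length_exp": 2.6},
    "Isopoda": {"intercept": -2.0, "length_exp": 2.6},
    "Chilopoda": {"intercept": -3.71, "length_exp": 2.3},
    "Collembola": {"intercept": -5.3, "length_exp": 2.7},
    "Oribatida": {"intercept": -4.2, "length_exp": 2.9},
    "Mesostigmata": {"intercept": -4.4, "length_exp": 2.8}
  },
  "metabolic_params": {
    "Lumbricidae": {"ln_i0": 23.055, "mass_exp": 0.695, "activation_e": 0.686},
    "Diplopoda": {"ln_i0": 23.055, "mass_exp": 0.695, "activation_e": 0.686},
    "Isopoda": {"ln_i0": 23.055, "mass_exp": 0.695, "activation_e": 0.686},
    "Chilopoda": {"ln_i0": 23.055, "mass_exp": 0.695, "activation_e": 0.686},
    "Collembola": {"ln_i0": 23.055, "mass_exp": 0.695, "activation_e": 0.686},
    "Oribatida": {"ln_i0": 23.055, "mass_exp": 0.695, "activation_e": 0.686},
    "Mesostigmata": {"ln_i0": 23.055, "mass_exp": 0.695, "activation_e": 0.686}
  },
  "temperatures": {"northern": 10.3, "central": 9.3, "southern": 8.6},
  "efficiency": {
    "slope": 0.471,
    "intercept": -2.097,
    "source_n": {"bacteria": 7.07, "fungi": 3.14, "plants": 1.30},
    "reference_temperature": 9.4,
    "activation_e": 0.164,
    "arrhenius_ref_temperature": 20.0,
    "carnivore_ea": 0.91
  }
}
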