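tier2_parameters:
  cfi_maintenance:
    value: 0.322
    provenance: IPCC 2006 default
  ca_housing:
    value: 0.0
    provenance: IPCC 2006 default
  ca_pasture:
    value: 0.17
    provenance: IPCC 2006 default
  c_growth_steer:
    value: 1.0
    provenance: IPCC 2006 default
  c_growth_heifer:
    value: 0.8
    provenance: IPCC 2006 default
  mature_weight_steer:
    value: 620.0
    provenance: assumed
  mature_weight_heifer:
    value: 555.0
    provenance: assumed
  ym_pasture:
    value: 6.5
    provenance: assumed
  ym_housing:
    value: 6.5
    provenance: assumed
  energy_per_kg_ch4:
    value: 55.65
    provenance: IPCC 2006 default
  ge_per_kg_dm:
    value: 18.45
    provenance: IPCC 2006 default
  urinary_energy_frac:
    value: 0.04
    provenance: IPCC 2006 default
  ash_frac:
    value: 0.08
    provenance: IPCC 2006 default
  b0:
    value: 0.18
    provenance: IPCC 2006 default
  ch4_density:
    value: 0.67
    provenance: IPCC 2006 default
  mcf_deep_bedding:
    value: 20.0
    provenance: paper
  mcf_pasture:
    value: 1.0
    provenance: IPCC 2006 default
  annual_temp:
    value: 12.0
    provenance: paper
  storage_months:
    value: 6
    provenance: paper
  n_retention_intercept:
    value: 268.0
    provenance: IPCC 2006 default
  n_retention_slope:
    value: 7.03
    provenance: IPCC 2006 default
  ef1_soil:
    value: 0.01
    provenance: IPCC 2006 default
  ef3_deep_bedding:
    value: 0.01
    provenance: IPCC 2006 default
  ef3_prp_cattle:
    value: 0.02
    provenance: IPCC 2006 default
  ef3_prp_sheep:
    value: 0.01
    provenance: IPCC 2006 default
  ef4_volatilisation:
    value: 0.01
    provenance: IPCC 2006 default
  ef5_leaching:
    value: 0.0075
    provenance: IPCC 2006 default
  frac_gas_ms:
    value: 0.3
    provenance: IPCC 2006 default
  frac_leach:
    value: 0.3
    provenance: IPCC 2006 default
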