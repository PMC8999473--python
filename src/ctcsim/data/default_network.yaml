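# Calibrated default CTC + ARAS network parameters.
populations:
  SG_E:
    polarity: excitatory
    Smax: 100.0
    theta: 6.0
    steepness: 0.25
    resting_offset: -6.3559
  SG_I:
    polarity: inhibitory
    Smax: 100.0
    theta: 6.0
    steepness: 0.25
    resting_offset: -8.0092
  GIG_E:
    polarity: excitatory
    Smax: 100.0
    theta: 5.0
    steepness: 0.1095
    resting_offset: 7.5323
  GIG_I:
    polarity: inhibitory
    Smax: 100.0
    theta: 5.0
    steepness: 0.1095
    resting_offset: 0.7317
  RELAY_E:
    polarity: excitatory
    Smax: 100.0
    theta: 0.0
    steepness: 0.12
    resting_offset: -36.6135
  RETIC_I:
    polarity: inhibitory
    Smax: 100.0
    theta: 24.3601
    steepness: 0.1627
    resting_offset: -52.0578
synapses:
  SG_E->SG_I:
    efficacy: 0.4248
    rise_rate: 280.0
    delay: 0.0
    region_tag: SG
  SG_I->SG_E:
    efficacy: -0.3161
    rise_rate: 230.0
    delay: 0.0
    region_tag: SG
  RELAY_E->SG_E:
    efficacy: 0.0822
    rise_rate: 100.0
    delay: 0.015
    region_tag: SG
  GIG_E->GIG_I:
    efficacy: 0.1449
    rise_rate: 150.0
    delay: 0.0
    region_tag: cortico_thalamic_loop
  GIG_I->GIG_E:
    efficacy: -0.2856
    rise_rate: 150.0
    delay: 0.0
    region_tag: cortico_thalamic_loop
  GIG_E->RELAY_E:
    efficacy: 0.7673
    rise_rate: 80.0
    delay: 0.015
    region_tag: cortico_thalamic_loop
  RELAY_E->GIG_E:
    efficacy: 0.3782
    rise_rate: 80.0
    delay: 0.015
    region_tag: cortico_thalamic_loop
  GIG_E->RETIC_I:
    efficacy: 0.6
    rise_rate: 15.042
    delay: 0.015
    region_tag: cortico_thalamic_loop
  RELAY_E->RETIC_I:
    efficacy: 0.6411
    rise_rate: 83.6072
    delay: 0.0
    region_tag: cortico_thalamic_loop
  RETIC_I->RELAY_E:
    efficacy: -0.3114
    rise_rate: 83.6072
    delay: 0.0
    region_tag: cortico_thalamic_loop
  ARAS->SG_E:
    efficacy: 1.0
    rise_rate: 100.0
    delay: 0.0
    region_tag: ARAS_afferent
aras:
  mean_input: 13.0278
  noise_intensity: 0.0705
  efficacy_gain: 1.0
  disinhibition_gain: 1.0
relay_noise_sigma: 0.005
relay_noise_rise_rate: 60.0
population_noise:
  GIG_E: 0.089
population_noise_rise_rate: 60.0
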