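# Scenario configuration; hidden values are pre-calibration placeholders
# (analyses apply the shipped fitted_params.yaml).
region:
  live_births: 34806654
  setting_shares:
    home: 0.5
    clinic: 0.35
    hospital: 0.15
  pph_rate:
    home: 0.12
    clinic: 0.1
    hospital: 0.08
  atonic_fraction: 0.9
  year_label: '2018'
uterotonic_coverage:
  home: 0.0
  clinic: 0.6
  hospital: 0.8
ubt:
  name: low-cost UBT
  penetration:
    home: 0.0
    clinic: 0.6
    hospital: 0.8
  utilization:
    home: 0.0
    clinic: 0.85
    hospital: 0.85
  efficacy_nonsevere: 0.85
  efficacy_severe: 0.7
hidden:
  uterotonic_efficacy: 0.85
  presevere_fraction: 0.15
  progression_prob: 0.3
  rebleed_prob: 0.1
  surgery_access:
    home: 0.05
    clinic: 0.3
    hospital: 0.8
  cfr_severe_no_surgery: 0.2
  cfr_severe_surgery: 0.05
  cfr_nonsevere_resolved: 0.001
  nonatonic_death_load: 6000.0
constants:
  severe_threshold_ml: 1000.0
  anemia_fraction: 0.12
scenario:
  name: nonsevere_eff95
  population_filter: all
  efficacy_overrides:
    efficacy_nonsevere: 0.95
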