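# Reference calibrated hidden parameters.
# Produced by analysis/02_calibrate.py (multi-start bounded least squares
# against the published output targets in targets.yaml); all analyses and
# acceptance runs start from this file. These are *a* compatible parameter
# set, not a unique solution: the inverse problem is under-determined and
# several directions are non-identifiable (see docs/methods.md).
hidden:
  uterotonic_efficacy: 0.5018139128897274
  presevere_fraction: 0.01188156338546388
  progression_prob: 0.07520205900153203
  rebleed_prob: 0.06362680313077017
  surgery_access:
    home: 0.0
    clinic: 0.017836542042579718
    hospital: 0.044385072284964175
  cfr_severe_no_surgery: 0.22250158958286156
  cfr_severe_surgery: 0.05
  cfr_nonsevere_resolved: 0.001
  nonatonic_death_load: 1712.3073287787022
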