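# Disease-stage multipliers applied on top of the sampled healthy
# physiology (literature-typical pathophysiology; the declared calibration
# surface for the drug-disease predictions).  Keys: volume:<organ>,
# flow:<organ>, enzyme:<CYP>, albumin, hematocrit, gfr (multiplier),
# gfr_absolute (mL/min), gut_cyp3a4 (enterocyte abundance).
hi_cp_a:
  volume:liver: 0.94
  enzyme:CYP3A4: 0.88
  enzyme:CYP3A5: 0.94
  enzyme:CYP2D6: 0.94
  gut_cyp3a4: 0.90
  albumin: 0.95
  hematocrit: 0.96
  flow:gut: 0.90
  gfr: 0.95
hi_cp_b:
  volume:liver: 0.82
  enzyme:CYP3A4: 0.42
  enzyme:CYP3A5: 0.60
  enzyme:CYP2D6: 0.60
  gut_cyp3a4: 0.55
  albumin: 0.85
  hematocrit: 0.92
  flow:gut: 0.80
  gfr: 0.90
hi_cp_c:
  volume:liver: 0.70
  enzyme:CYP3A4: 0.28
  enzyme:CYP3A5: 0.45
  enzyme:CYP2D6: 0.45
  gut_cyp3a4: 0.40
  albumin: 0.75
  hematocrit: 0.88
  flow:gut: 0.70
  gfr: 0.85
ri_moderate:
  gfr_absolute: 45.0
  enzyme:CYP3A4: 0.93
  albumin: 0.95
  hematocrit: 0.92
ri_severe:
  gfr_absolute: 20.0
  enzyme:CYP3A4: 0.85
  albumin: 0.88
  hematocrit: 0.88
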