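# Mean physiology of a healthy Chinese adult (literature-typical values).
# Volumes in L, cardiac output in L/h, flow fractions of cardiac output
# (liver entry = hepatic artery; gut/spleen/pancreas drain to the portal
# vein), GFR in mL/min, MPPGL in mg microsomal protein per g liver.
body_weight: 61.0
cardiac_output: 330.0
organ_volumes:
  adipose: 10.0
  bone: 7.0
  brain: 1.40
  gut: 1.10
  heart: 0.33
  kidney: 0.27
  liver: 1.70
  lung: 0.50
  muscle: 25.0
  skin: 2.30
  spleen: 0.17
  pancreas: 0.12
  blood: 4.70
flow_fractions:
  adipose: 0.050
  bone: 0.050
  brain: 0.120
  gut: 0.150
  heart: 0.040
  kidney: 0.190
  liver: 0.065      # hepatic artery
  muscle: 0.247
  skin: 0.058
  spleen: 0.020
  pancreas: 0.010
mppgl: 45.0
hematocrit: 0.43
gfr: 110.0
albumin_scalar: 1.0
enzyme_abundance_scalar:
  CYP3A4: 1.0
  CYP3A5: 1.0
  CYP2D6: 1.0
enterocyte_cyp3a4_scalar: 1.0
qgut: 18.0             # L/h, enterocyte hybrid flow
gut_cyp3a4_clint: 6.0  # L/h, baseline enterocyte CYP3A4 intrinsic clearance
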