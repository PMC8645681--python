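# Victim-drug input file for apatinib (free base MW; dose as labelled).
# intrinsic_solubility, solubility_cap and dissolution_coefficient describe
# the mesylate tablet and are calibrated against the observed sub-proportional
# 250 -> 750 mg exposure (see docs/methods.md).
name: apatinib
molecular_weight: 397.48    # g/mol
log_p: 3.14
compound_class: diprotic_base
pka1: 6.60
pka2: 5.31
fu_plasma: 0.076
blood_to_plasma: 0.995
papp_caco2: 6.81e-6         # cm/s
peff_human: 0.80            # 1e-4 cm/s
kp_scalar: 0.7
vss_predicted: 2.684        # L/kg
intrinsic_solubility: 0.050  # mg/mL free base, calibrated
solubility_cap: 2.0         # mg/mL, mesylate in gastric fluid
dissolution_coefficient: 0.15  # 1/h, calibrated
salt_factor: 1.0
enzymes:
  CYP3A4: {vmax: 39.1, km: 2.18}   # pmol/min/mg protein; uM
  CYP3A5: {vmax: 3.28, km: 1.93}
  CYP2D6: {vmax: 9.82, km: 1.41}
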