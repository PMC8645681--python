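# Nine-segment gut: fasted-state fluid volumes (dosed with water), pH, mean
# residence times, effective absorptive radii and relative mucosal
# permeability (stomach does not absorb; caecum/colon strongly scaled
# down for this low-permeability base). Total small-intestinal transit ~3.1 h.
segments:
  - {name: stomach,  volume_ml: 250.0, ph: 1.8, transit_h: 0.20, radius_cm: 5.0,  absorption_scale: 0.0}
  - {name: duodenum, volume_ml: 80.0,  ph: 6.0, transit_h: 0.25, radius_cm: 0.80, absorption_scale: 1.0}
  - {name: jejunum1, volume_ml: 120.0, ph: 6.2, transit_h: 0.60, radius_cm: 0.74, absorption_scale: 1.0}
  - {name: jejunum2, volume_ml: 120.0, ph: 6.4, transit_h: 0.60, radius_cm: 0.68, absorption_scale: 1.0}
  - {name: ileum1,   volume_ml: 100.0, ph: 6.8, transit_h: 0.55, radius_cm: 0.62, absorption_scale: 1.0}
  - {name: ileum2,   volume_ml: 100.0, ph: 7.0, transit_h: 0.55, radius_cm: 0.56, absorption_scale: 1.0}
  - {name: ileum3,   volume_ml: 100.0, ph: 7.2, transit_h: 0.55, radius_cm: 0.50, absorption_scale: 1.0}
  - {name: caecum,   volume_ml: 30.0,  ph: 6.2, transit_h: 4.0,  radius_cm: 3.5,  absorption_scale: 0.05}
  - {name: colon,    volume_ml: 15.0,  ph: 6.8, transit_h: 12.0, radius_cm: 2.5,  absorption_scale: 0.02}
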