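# Moderate CYP3A4 inhibitor: mechanism-based inactivation.
name: erythromycin
molecular_weight: 733.9
dosing: {dose_mg: 250, interval_h: 6, days: 6}
pk: {ka: 1.0, v_f: 300.0, cl_f: 30.0, fu: 0.28}
interactions:
  CYP3A4:
    mbi: {kinact: 6.0, ki_app: 5.0}
  CYP3A5:
    mbi: {kinact: 3.0, ki_app: 8.0}
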