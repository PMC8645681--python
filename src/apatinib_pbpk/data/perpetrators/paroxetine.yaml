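# Strong CYP2D6 inhibitor: mechanism-based inactivation.
name: paroxetine
molecular_weight: 329.4
dosing: {dose_mg: 30, interval_h: 24, days: 6}
pk: {ka: 1.0, v_f: 500.0, cl_f: 30.0, fu: 0.05}
interactions:
  CYP2D6:
    mbi: {kinact: 6.0, ki_app: 0.30}
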