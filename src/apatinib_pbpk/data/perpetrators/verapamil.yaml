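# Weak-to-moderate CYP3A4 inhibitor: mechanism-based inactivation.
name: verapamil
molecular_weight: 454.6
dosing: {dose_mg: 120, interval_h: 8, days: 6}
pk: {ka: 1.5, v_f: 350.0, cl_f: 50.0, fu: 0.10}
interactions:
  CYP3A4:
    mbi: {kinact: 1.4, ki_app: 2.0}
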