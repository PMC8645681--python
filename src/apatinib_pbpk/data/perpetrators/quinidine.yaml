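# CYP2D6 competitive inhibitor.
name: quinidine
molecular_weight: 324.4
dosing: {dose_mg: 200, interval_h: 24, days: 6}
pk: {ka: 1.0, v_f: 200.0, cl_f: 20.0, fu: 0.13}
interactions:
  CYP2D6:
    competitive: {ki: 0.15}
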