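# CYP3A4 inducer.
name: efavirenz
molecular_weight: 315.7
dosing: {dose_mg: 600, interval_h: 24, days: 10}
pk: {ka: 0.5, v_f: 250.0, cl_f: 9.0, fu: 0.01}
interactions:
  CYP3A4:
    induction: {ind_max: 2.5, ind_c50: 0.06}
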