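# CYP3A4 inducer.
name: phenytoin
molecular_weight: 252.3
dosing: {dose_mg: 300, interval_h: 24, days: 10}
pk: {ka: 0.5, v_f: 45.0, cl_f: 2.0, fu: 0.10}
interactions:
  CYP3A4:
    induction: {ind_max: 4.8, ind_c50: 4.0}
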