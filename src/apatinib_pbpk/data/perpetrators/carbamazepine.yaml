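# CYP3A4 inducer.
name: carbamazepine
molecular_weight: 236.3
dosing: {dose_mg: 400, interval_h: 12, days: 10}
pk: {ka: 0.5, v_f: 90.0, cl_f: 4.0, fu: 0.25}
interactions:
  CYP3A4:
    induction: {ind_max: 4.2, ind_c50: 10.0}
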