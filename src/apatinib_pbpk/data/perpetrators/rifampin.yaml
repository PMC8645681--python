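# Strong CYP3A4 inducer (weakly competitive as well).
name: rifampin
molecular_weight: 822.9
dosing: {dose_mg: 600, interval_h: 24, days: 10}
pk: {ka: 1.0, v_f: 50.0, cl_f: 12.0, fu: 0.15}
interactions:
  CYP3A4:
    induction: {ind_max: 6.0, ind_c50: 0.32}
    competitive: {ki: 20.0}
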