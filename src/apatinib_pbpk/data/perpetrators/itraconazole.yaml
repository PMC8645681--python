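# Strong competitive CYP3A inhibitor; one-compartment oral PK
# (literature-typical) and unbound interaction constants in uM.
name: itraconazole
molecular_weight: 705.6
dosing: {dose_mg: 100, interval_h: 24, days: 6}
pk: {ka: 0.4, v_f: 700.0, cl_f: 30.0, fu: 0.036}
interactions:
  CYP3A4:
    competitive: {ki: 0.0015}
  CYP3A5:
    competitive: {ki: 0.0015}
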