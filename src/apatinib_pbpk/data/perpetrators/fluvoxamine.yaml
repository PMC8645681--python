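# Weak CYP2D6 (competitive) inhibitor at therapeutic exposure.
name: fluvoxamine
molecular_weight: 318.3
dosing: {dose_mg: 50, interval_h: 24, days: 6}
pk: {ka: 1.0, v_f: 1400.0, cl_f: 100.0, fu: 0.23}
interactions:
  CYP2D6:
    competitive: {ki: 8.0}
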