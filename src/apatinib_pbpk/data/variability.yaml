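# Between-subject coefficients of variation for the mean-preserving
# log-normal sampler: 30% for clearance-related parameters, 20% for
# volumes/flows (defaults; override per study).
body_weight: 0.15
cardiac_output: 0.15
volumes: 0.20
flows: 0.20
mppgl: 0.30
enzyme_abundance: 0.30
enterocyte_cyp3a4: 0.30
gfr: 0.20
hematocrit: 0.05
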