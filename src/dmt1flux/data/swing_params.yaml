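# Swinging-mechanism model, jackknife point estimates
# (k12, k45 in 1/(min*uM); other rates in 1/min; DMT1_E in uM)
k12: 1.68e-7
k23: 1.6608
k34: 1.3221
k41: 0.7064
k14: 30.7036
k45: 0.2887
k56: 3.2082
k64: 2.9639
DMT1_E: 46156.25
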