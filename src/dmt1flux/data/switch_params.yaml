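# Binary switching-mechanism model, jackknife point estimates
# (k12, k45 in 1/(min*uM); other rates in 1/min; DMT1_E in uM)
k12: 5.31e-6
k23: 0.9104
k34: 2.2193
k41: 0.3731
k14: 11.2703
k45: 0.0630
k54: 0.6492
DMT1_E: 566.10
alpha_E: 0.9890
alpha_M: 0.9780
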