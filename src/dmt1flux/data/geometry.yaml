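# Caco-2 insert culture geometry (lengths in um, volumes in uL)
h_c: 29.6
d_c: 6.2
R_V: 0.04
V_a: 200.0
V_cb: 1000.0
V_m: 1.67
release_fraction: 0.01
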