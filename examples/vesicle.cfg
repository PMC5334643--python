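# Budding phase diagram over (K_m/K_s, eps_LJ/K_s) at reduced membrane size.
[grid]
km_over_ks = 0.3, 0.7, 1.5, 4.0, 10.0
eps_over_ks = 0.03, 0.15, 0.7, 1.7, 3.0
N_m = 100
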