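# Small end-to-end run of all three stages (minutes on one CPU).
[pipeline]
stages = aggregate, vesicle, spots

[lattice]
Lx = 16
Ly = 16
Lz = 8

[rates]
k_in = 1.0

[sweep]
kout_values = 0.1, 1.0, 10.0, 100.0, 1000.0
replicates = 4
t_obs = 5.0
min_size = 10

[grid]
km_over_ks = 0.3, 1.5, 10.0
eps_over_ks = 0.03, 0.7, 3.0
N_m = 100

[spots]
n_images = 2
n_nuclei = 8
spots_per_cell = 4.0
snr = 8.0
image_size = 256
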