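n_bonds = 60
fene_k = 20.0
l0 = 0.7
l_min = 0.4
l_max = 1.0
r0 = 0.30000000000000004
morse_alpha = 24.0
morse_rmin = 0.8
morse_eps = 1.0
morse_cutoff = 1.0
kappa = 10.0
eps_vp = 2.0
lj_rm = 0.8
lj_cutoff = 2.0
kBT = 1.0
max_disp = 0.25
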