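# Single flyback echo train: ghost-free reference acquisition (water-oil phantom).
fov_read: 80.0
fov_phase: 80.0
n_read: 256
n_phase: 192
n_trains: 1
echoes_per_train: 96
delta_te_eff: 1.55   # ms; sBW 5.03 ppm at 128.33 MHz
te1: 3.0
tr: 200.0
flip_deg: 35.0
rbw: 434028.0        # Hz; G_r 127.42 mT/m at FOV 80 mm
ramp: 0.15
rewind_min: 0.6
larmor: 128.33
gamma_bar: 42.5774
slice_thickness: 1.5
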