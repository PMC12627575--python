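# Two interleaved flyback echo trains, 48 echoes each; sBW 9.74 ppm.
fov_read: 80.0
fov_phase: 80.0
n_read: 256
n_phase: 192
n_trains: 2
echoes_per_train: 48
delta_te_eff: 0.8
te1: 3.0
tr: 200.0
flip_deg: 45.0
rbw: 434028.0
ramp: 0.15
rewind_min: 0.6
larmor: 128.33
gamma_bar: 42.5774
slice_thickness: 1.5
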