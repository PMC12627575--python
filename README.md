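# epsighost

Simulation and correction of **Nyquist ghost spectral lines** in
high-resolution echo-planar spectroscopic imaging (EPSI) with interleaved
flyback readout.

EPSI encodes one spatial axis and the spectroscopic time axis with a single
gradient-echo train. A flyback train alone has a narrow spectral bandwidth
(sBW = 1/ΔTE), so high-resolution water–fat protocols interleave N trains,
each offset by ΔTE, to multiply the bandwidth by N. The price is a new
artifact: any amplitude, phase, or timing inconsistency *between* the
interleaved trains is periodic with period N on the merged spectroscopic
grid, so every true spectral line at frequency f throws aliases — ghost
lines — at

    f + j·sBW/N,   j = 1 … N−1,

stealing intensity from the true peak and cluttering the spectrum. The
package quantifies a line's ghosting by the **ghost-to-true ratio**
GTR = mean |ghost| / |true|, and removes it with an iterative **zero-order
phase correction**: a grid search over the constant phase e^{iΦ0} applied to
whole echo trains that minimizes GTR (a single Φ0 on train 2 for N = 2; a
two-stage search over a common Φ0 and an arithmetic per-train step ΔΦ for
N = 4). For a pure phase inconsistency Φ between two interleaves the theory
is closed-form — GTR = |tan(Φ/2)| — and the package ships these closed
forms as independent oracles alongside the full simulation pipeline.

Intended users: MR physicists prototyping interleaved EPSI protocols or
ghost-correction strategies who want a fully synthetic, exactly invertible
testbed (forward model ↔ reconstruction form an exact DFT pair) before
touching scanner data.

## What's inside

| module         | role |
| -------------- | ---- |
| `seqconfig`    | acquisition parameters, validation, derived quantities (dwell, G_r, sBW, resolutions); bundled `paper_single/two/four` protocols |
| `phantom`      | synthetic objects: water/oil cylinder section, point and slab objects, ΔB0 maps |
| `acquisition`  | forward simulation of interleaved flyback echo trains; train merge |
| `corruption`   | interleave reorganization + per-train temporal-shift / magnitude / zero-order-phase injection |
| `recon`        | zero-fill → spectral FFT → chemical-shift (skew) correction → spatial FFT → ΔB0 correction → line images and VOI spectra |
| `ghostlab`     | ghost detection, GTR, two- and four-train phase corrections, parameter sweeps |
| `oracle`       | closed-form GTR laws, dark-strip null positions, brute-force O(n²) DFT reference |
| `archive`/`cli`| HDF5/NIfTI/CSV I/O, experiment specs, `epsighost` command-line drivers |

## Worked example

Inject a −42.5° zero-order phase inconsistency into the second of two
interleaves and recover it:

```python
import numpy as np
import epsighost as eg

cfg = eg.SequenceConfig(n_read=64, n_phase=64, n_trains=1,
                        echoes_per_train=48, delta_te_eff=0.8)
print(cfg.summary())

phantom = eg.make_water_oil_phantom(cfg, oil_density=0.0, t2_water=np.inf)
ets = eg.simulate(phantom, cfg)                      # ghost-free single train

bad = eg.apply_phase0(eg.split_trains(ets, 2), 1, -42.5)
voi = eg.disc_voi((cfg.n_phase, cfg.n_read), (1.25, 1.25), radius_mm=10.0)
res = eg.correct_two_trains(bad, voi)
print(f"recovered phi0 = {res.phi0_per_train[1]:.1f} deg")
print(f"GTR before = {res.gtr_before:.4f}, after = {res.gtr_after:.2e}")
```

prints

```
{'dwell_us': 2.3, 'readout_gradient_mT_m': 127.42, 'resolution_read_mm': 1.25,
 'resolution_phase_mm': 1.25, 'sbw_hz': 1250.0, 'sbw_ppm': 9.74,
 'intra_train_spacing_ms': 0.8}
recovered phi0 = 42.5 deg
GTR before = 0.3889, after = 9.91e-17
```

Reading it: at rBW 434 028 Hz the dwell time is 2.3 µs and the readout
gradient 127.42 mT/m; two interleaves at ΔTE 0.8 ms give a 1250 Hz
(9.74 ppm) spectral band. The injected inconsistency splits the water line,
raising a ghost at the band-edge alias with GTR = tan(21.25°) ≈ 0.389; the
0.5°-step search lands exactly on the compensating +42.5° and the ghost
collapses to numerical zero.

The same flow is available from the shell:

```bash
epsighost simulate --protocol paper_single --out raw.h5
epsighost corrupt raw.h5 --split 2 --train 1 --phase0-deg 40 --out bad.h5
epsighost recon bad.h5 --outdir out/
epsighost correct bad.h5 --mode 2 --outdir out/
epsighost oracle --protocol paper_single --tau-us 5.76
```

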