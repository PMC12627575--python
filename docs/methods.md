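# Methods

## Scope and model

`epsighost` is a desk-scale simulator and correction toolkit for the spectral
Nyquist ghosts of echo-planar spectroscopic imaging (EPSI) with interleaved
flyback readout. One flyback gradient-echo train encodes the readout axis
(within each echo) and the spectroscopic time axis (across echoes); N trains,
offset from each other by the effective echo spacing ΔTE, merge into a
uniform spectroscopic grid `t_m = TE1 + m·ΔTE` and multiply the spectral
bandwidth sBW = 1/ΔTE by N. Any periodic inconsistency among the interleaves
— a per-train amplitude, phase, or timing error — multiplies the merged time
series by a period-N sequence and therefore splits every spectral line into
its true component plus N−1 aliases at `f + j·sBW/N`. The ghost-to-true
ratio (GTR) is the mean magnitude of a line's aliases divided by the true
line's magnitude.

The forward model (`acquisition.simulate`) is a discrete sum over grid
voxels and chemical species:

    data[k, m, p, n] = Σ ρ · e^{−t/T2} · e^{i2π(f_cs + ΔB0)t}
                         · e^{+i2π(k_x(n)·x + k_y(p)·y)},
    t = TE1 + k·ΔTE + m·N·ΔTE + (n − n_read/2)·dwell.

Sampling is restricted to the gradient flat-top; ramps and rewinds are dead
time (ramp sampling is not modelled — only timing bookkeeping). The phantom
grid equals the acquisition matrix, which makes the model an exact DFT pair
with the reconstruction: an uncorrupted single-train acquisition reconstructs
with an off-line spectral floor at numerical zero (~1e−16 of the peak), so
ghost-level assertions at 1e−10 are meaningful rather than drowned in
modelling error.

## Processing chain

`recon.reconstruct` merges the trains, zero-fills (k_read, k_phase, k_t) to a
target matrix (default 256³; spatial axes padded symmetrically about the
k-space centre, k_t end-padded because the signal is FID-like), FFTs along
k_t, removes the intra-echo acquisition-time skew (the readout
chemical-shift artifact) by the first-order spectral phase
`exp(−i2π f (n − n_read/2) dwell)`, applies the centred 2-D spatial FFT, and
optionally corrects per-voxel spectral shifts from static-field (ΔB0)
offsets. Conventions that were genuinely open and are now fixed:

* **FFT signs.** The forward model encodes space with the positive exponent;
  reconstruction inverts with the negative-exponent centred DFT. The
  spectral FFT uses the negative exponent so `exp(+i2πft)` lands at +f.
* **Skew-correction pivot.** The first-order phase is pivoted on the echo
  centre `n_read/2`, so the correction vanishes at the k-space centre. It is
  deliberately not idempotent; the pipeline applies it exactly once.
* **ΔB0 correction.** Two modes are provided and neither is claimed
  canonical: `known_map` (shift by the simulation's ground-truth map) and
  `self_reference` (align each object voxel's dominant peak to the modal
  dominant-peak bin). Integer-bin circular shifts by default; a Fourier
  sub-bin mode exists but introduces ringing on sharp lines.
* **Spectral windows.** Water line image defaults to ±0.5 ppm around the
  reference; the fat window is centred on the configured oil shift.
* **VOI spectra** take per-voxel magnitude *before* summation, which makes
  them exactly additive over disjoint VOIs and insensitive to inter-voxel
  phase.

## Corruption operators

Ghost simulations start from a single-train acquisition (ghost-free by
construction), reorganized into N interleaves; with 1-based echo numbering
train j receives the echoes ≡ j (mod N), so "train 2 holds the even echoes".
This parity convention is load-bearing: a 0-based convention silently swaps
the trains. Three per-train operators are provided:

* **Temporal shift** — every echo of the train resampled along the readout
  at `n − shift` by natural cubic splines (real and imaginary parts; the
  spline is linear, so this equals complex interpolation), zero-filled
  outside the original support.
* **Magnitude scale** — multiplication by a real constant a > 0.
* **Zero-order phase** — multiplication by `exp(iΦ0)`.

The operators commute pairwise on a given train and act on raw echoes before
any zero-filling. First-order (frequency-dependent) phase errors are out of
scope; they are exactly the residual the zero-order correction cannot
remove.

## Closed-form oracles

Derivations are in `docs/THEORY.md`. For two interleaves: a phase offset Φ
gives GTR = |tan(Φ/2)|; a scale a gives GTR = |1−a|/(1+a) (symmetric under
a → 1/a); an inter-train temporal offset τ under readout gradient G_r gives
the per-voxel phase φ(x) = 2π·γ̄·G_r·τ·x, hence GTR(x) = |tan(π γ̄ G_r τ x)|,
independent of the phase-encode coordinate, with true-line nulls (the dark
strips) at x = (2k+1)/(2 γ̄ G_r τ). An independent O(n²) DFT (no FFT
library) backs these closed forms in the test suite.

## Phase correction

`correct_two_trains` grid-searches the zero-order phase applied to train 2
(default 0.5° steps over the full circle — matching the half-degree
granularity of correction constants usually reported — starting at the
identity candidate, so the correction can never raise GTR).
`correct_four_trains` runs two stages: a common Φ applied to trains 2–4,
then the arithmetic step ΔΦ of a per-train progression. The progression is
pivoted on the *middle* train (corrections Φc−ΔΦ, Φc, Φc+ΔΦ): the stage-1
optimum of a common phase against an arithmetic phase progression lands on
the progression's central value, so pivoting stage 2 on train 2 would leave
the train-2 residual frozen and the truth unreachable; the centred pivot
recovers an injected progression exactly. The reported Φ0 is the train-2
correction Φc−ΔΦ, so the final constants read (Φ0, Φ0+ΔΦ, Φ0+2ΔΦ).

Because every pipeline step is linear in the raw data, the corrected cube is
`Σ_k e^{iφ_k} C_k` with `C_k` the cube of train k alone; the search
reconstructs each train once and sweeps phases algebraically. This is exact
(verified against naive re-reconstruction in the tests) — not a speed
approximation. Self-referencing ΔB0 correction is data-dependent and is
rejected inside the search; use a known map or none.

GTR during correction is evaluated on a VOI-summed magnitude spectrum (a
per-voxel mode is available); peak windows are ±3 spectral bins around the
predicted frequencies with ties broken toward the window centre.

## Synthetic objects and what the tests do(n't) show

The default object mirrors the physical phantom: a 26 mm cylinder section
split into a water half-disc (T2 30 ms, the 0-ppm reference) and a
vegetable-oil half-disc (T2 70 ms, (-CH2-)n at −3.4 ppm — the standard
water–methylene separation; the geometric arrangement inside the cylinder is
a package choice). ΔB0 maps are user-specified fields (uniform, linear,
Gaussian bump); no susceptibility physics is computed. Flip angle and TR are
recorded as metadata only — no steady-state amplitude modelling.

Oracle-equivalence and recovery tests use decay-free (T2 = ∞), on-resonance
objects without k_t zero-filling, so spectral lines are exact DFT deltas.
With realistic T2 the Lorentzian tail of the true line at the alias
frequency biases small GTRs by several percent, and end-padding a truncated
FID adds sinc sidelobes at the 1e−3 level; both are lineshape/truncation
effects, not interleaving physics, and would mask the quantities under test.
Consequently the passing tests validate the ghost mechanism and the
correction machinery — they do not certify GTR accuracy on broad, decaying,
noisy lines, where window-limited peak picking inherits lineshape bias.

Two further known limitations of the spline shift operator: (i) GTR(τ) vs
GTR(−τ) symmetry, exact for the ideal shift, holds only to ~0.3–1% because
even-length echoes put the spline domain midpoint half a sample off the echo
centre; (ii) near the readout Nyquist edge the spline's amplitude response
droops, so the tan-law is asserted only for objects bounded well inside the
FOV and away from the nulls (within 5%).

## Problem sizes

The bundled protocols carry the full acquisition parameters (80×80 mm FOV,
256 echo points, 192 phase encodings, rBW 434 028 Hz, ΔTE 1.55/0.8 ms,
96/48/24 echoes per 1/2/4 trains, TE1 3 ms, TR 200 ms). Tests and the
acceptance script run the same bandwidths and FOV on reduced matrices
(32–64 readout points, 8–64 phase rows, 48 spectral samples): every reported
quantity — gradients, temporal offsets, per-voxel phase laws, ghost
amplitudes, recovered corrections — is independent of matrix size, which
only sets spatial resolution. The full 256×192×96 protocol runs through the
same code paths unchanged.
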