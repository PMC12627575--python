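# Ghost-amplitude derivations

These are the closed forms implemented in `epsighost.oracle` and used as
independent ground truth by the test suite. Throughout, the merged
spectroscopic samples of one voxel are

    s_m = A · e^{i 2π f t_m} · e^{−t_m/T2},   t_m = TE1 + m·ΔTE,

and an inter-train inconsistency multiplies s_m by a period-N sequence c_{m mod N}
(train k of the interleave receives merged indices m ≡ k−1 mod N).

## Alias positions

Expand the periodic modulation in its discrete Fourier components:

    c_n = Σ_{j=0}^{N−1} C_j e^{i 2π j n / N},
    C_j = (1/N) Σ_{n=0}^{N−1} c_n e^{−i 2π j n / N}.

Each component turns s_m into a tone at `f + j/(N·ΔTE) = f + j·sBW/N`
(wrapped into [−sBW/2, sBW/2)), with complex amplitude C_j relative to the
unmodulated line. Hence the line splits into the true component C_0 at f and
N−1 ghosts C_1..C_{N−1} at the alias frequencies, all sharing the same
lineshape (the modulation is multiplicative, so each component is convolved
with the identical envelope transform). Peak-height ratios therefore equal
amplitude ratios |C_j|/|C_0| regardless of T2.

## Two interleaves

With c = (1, e^{iΦ}) (zero-order phase Φ on train 2):

    C_0 = (1 + e^{iΦ})/2 = e^{iΦ/2} cos(Φ/2),
    C_1 = (1 − e^{iΦ})/2 = −i e^{iΦ/2} sin(Φ/2),

    GTR(Φ) = |C_1| / |C_0| = |tan(Φ/2)|.

With c = (1, a), a real scale on train 2:

    C_0 = (1 + a)/2,  C_1 = (1 − a)/2,
    GTR(a) = |1 − a| / (1 + a),

which is invariant under a → 1/a (scaling train 2 by a or train 1 by 1/a
differ only by an overall factor).

## Temporal shift

Shifting the echoes of train 2 by δ readout points (τ = δ·dwell seconds)
advances the k-space trajectory of that train by Δk = γ̄·G_r·τ cycles/m
(equivalently δ/FOV, since γ̄·G_r·dwell = 1/FOV by the definition of the
readout gradient). By the Fourier shift theorem the train-2 *image* acquires
the linear phase

    φ(x) = 2π · γ̄ · G_r · τ · x,

so each voxel sees a two-interleave phase modulation with Φ = φ(x):

    GTR(x) = |tan(π · γ̄ · G_r · τ · x)|,

growing with |x| along the readout direction and independent of the
phase-encode coordinate. The true line of a voxel vanishes where
cos(φ/2) = 0:

    x_null = (2k+1) / (2 · γ̄ · G_r · τ),  k = 0, 1, …

— the dark strips perpendicular to the readout direction, spaced
1/(γ̄·G_r·τ). For the full protocol (G_r = 127.42 mT/m) and τ = 5.76 µs
(2.5 echo points) the first null sits at |x| = 16.0 mm; GTR(τ) = GTR(−τ)
because |tan| is even in φ.

The spline implementation realises this shift only approximately: its
amplitude response is < 1 near the readout Nyquist frequency and its
boundary handling is asymmetric about the echo centre for even-length
echoes. Tolerance tiers used in the tests: closed forms vs pipeline, 2%
(phase/magnitude) and 5% away from nulls (shift); brute-force DFT vs the
FFT path, 1e−10 relative.

## Four interleaves and the two-stage correction

For phase errors (0, ψ2, ψ3, ψ4) on the four trains and corrections
(0, χ2, χ3, χ4), the residuals r_k = χ_k − ψ_k give

    C_j = (1/4) Σ_k e^{i r_k} e^{−i 2π j k / 4},
    GTR = (|C_1| + |C_2| + |C_3|) / (3 |C_0|) · 3/3,

with GTR defined as the mean ghost magnitude over the true magnitude. For an
arithmetic progression ψ_k = Φ* + (k−2)·ΔΦ*, a *common* correction χ ≡ χ2 =
χ3 = χ4 gives residuals (0, χ−Φ*−jΔΦ*): writing δ = χ − ψ3, every |C_{j>0}|
is of the form |1 − β_j e^{iδ}|/4 with β_j > 0, and |C_0| = |1 + β_0 e^{iδ}|/4
— all ghosts are minimised and the true line maximised at δ = 0. The stage-1
optimum is therefore the *middle* train's error ψ3, which is why stage 2
searches the progression step with the pivot at train 3
(χ = Φc−ΔΦ, Φc, Φc+ΔΦ) and reaches the exact truth at ΔΦ = ΔΦ*.
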