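"""Independent ground truth for ghost amplitudes.

Closed forms (derivations in docs/THEORY.md):

* zero-order phase Φ on one of two interleaves splits a unit line into a true
  component cos(Φ/2) and an alias sin(Φ/2):  GTR(Φ) = |tan(Φ/2)|;
* magnitude scale a on one of two interleaves:  GTR(a) = |1−a|/(1+a),
  symmetric under a → 1/a;
* an inter-train temporal offset τ under readout gradient G_r imprints the
  voxel-position-dependent phase φ(x) = 2π·γ̄·G_r·τ·x on the shifted train,
  so per-voxel GTR(x) = |tan(π γ̄ G_r τ x)| and the true line nulls at
  x = (2k+1) / (2 γ̄ G_r τ) — the dark strips.

:func:`brute_force_spectrum` is a direct O(n²) DFT written without any FFT
library; it is the reference against which both the closed forms and the
reconstruction pipeline's FFT path are checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqconfig import SequenceConfig

__all__ = [
    "ModulatedFid",
    "gtr_phase",
    "gtr_magnitude",
    "timeshift_phase_at",
    "null_positions",
    "brute_force_spectrum",
]


@dataclass(frozen=True)
class ModulatedFid:
    """A complex time series multiplied by a period-N per-residue factor.

    ``samples[m] = base[m] * modulation[m % period]`` — the idealization of an
    inter-train inconsistency on the merged spectroscopic grid.
    """

    samples: np.ndarray
    period: int
    modulation: np.ndarray

    @classmethod
    def pure_tone(
        cls,
        n: int,
        f_hz: float,
        dt_ms: float,
        modulation: np.ndarray,
        t2_ms: float = np.inf,
    ) -> "ModulatedFid":
        m = np.asarray(modulation, dtype=complex)
        t = np.arange(n) * dt_ms * 1e-3
        base = np.exp((2j * np.pi * f_hz - 1.0 / (t2_ms * 1e-3)) * t)
        return cls(base * m[np.arange(n) % len(m)], len(m), m)


def gtr_phase(phi_deg: float) -> float:
    """GTR caused by a zero-order phase Φ on the second of two interleaves."""
    return abs(np.tan(np.deg2rad(phi_deg) / 2.0))


def gtr_magnitude(a: float) -> float:
    """GTR caused by scaling the second of two interleaves by a > 0."""
    if not a > 0:
        raise ValueError("magnitude scale must be positive")
    return abs(1.0 - a) / (1.0 + a)


def timeshift_phase_at(x_mm: float, tau_us: float, cfg: SequenceConfig) -> float:
    """Phase error in degrees at readout position x for inter-train offset τ.

    φ(x) = 360° · γ̄ · G_r · τ · x  (γ̄ in Hz/T, G_r in T/m, τ in s, x in m).
    """
    gr_t_per_m = cfg.readout_gradient() * 1e-3
    gamma_hz = cfg.gamma_bar * 1e6
    return 360.0 * gamma_hz * gr_t_per_m * (tau_us * 1e-6) * (x_mm * 1e-3)


def null_positions(tau_us: float, cfg: SequenceConfig, x_max_mm: float) -> np.ndarray:
    """True-line null (dark strip) positions |x| ≤ x_max, in mm, sorted.

    Nulls where φ(x) is an odd half cycle: x = (2k+1)/(2 γ̄ G_r τ).
    """
    if tau_us == 0:
        return np.array([])
    gr_t_per_m = cfg.readout_gradient() * 1e-3
    rate_per_mm = cfg.gamma_bar * 1e6 * gr_t_per_m * abs(tau_us) * 1e-6 * 1e-3  # cycles/mm
    first = 1.0 / (2.0 * rate_per_mm)
    spacing = 1.0 / rate_per_mm
    pos = np.arange(first, x_max_mm + 1e-12, spacing)
    return np.sort(np.concatenate([-pos[::-1], pos]))


def brute_force_spectrum(fid: ModulatedFid | np.ndarray) -> np.ndarray:
    """Magnitude spectrum by direct O(n²) DFT (no FFT), fftshifted bin order.

    Bin q (after shift, q ∈ [−n/2, n/2)) holds |Σ_m s_m exp(−2πi q m / n)|.
    Chunked over output bins to bound memory.
    """
    s = fid.samples if isinstance(fid, ModulatedFid) else np.asarray(fid, dtype=complex)
    n = len(s)
    q_axis = np.arange(-(n // 2), n - n // 2)
    out = np.empty(n)
    m = np.arange(n)
    for start in range(0, n, 256):
        q = q_axis[start : start + 256]
        kernel = np.exp(-2j * np.pi * np.outer(q, m) / n)
        out[start : start + 256] = np.abs(kernel @ s)
    return out
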