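"""Inter-train inconsistency injection.

The ghost-line simulation protocol starts from a single flyback echo train
(which is ghost-free), reorganizes it into N interleaves, and perturbs chosen
trains with the three mechanisms that break inter-train consistency:

* temporal shift of echoes along the readout axis (fractional echo points,
  resampled by natural cubic splines — the real/imaginary parts are
  interpolated, which for a linear operator equals interpolating the complex
  signal);
* a constant magnitude scale per train;
* a zero-order phase offset Φ0 per train.

Echo parity is **1-based** to match the usual "second train holds the even
echoes" wording: with ``n_out = 2``, train 2 receives echoes 2, 4, 6, …
(0-based odd indices). A 0-based parity convention would silently swap the
trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .acquisition import EchoTrainSet

__all__ = [
    "TrainCorruption",
    "CorruptionSpec",
    "split_trains",
    "apply_time_shift",
    "apply_magnitude_scale",
    "apply_phase0",
    "apply_corruption",
]


@dataclass(frozen=True)
class TrainCorruption:
    """Identity by default: no shift, unit scale, zero phase."""

    time_shift_points: float = 0.0
    magnitude_scale: float = 1.0
    phase0_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.magnitude_scale > 0:
            raise ValueError("magnitude_scale must be positive")

    def is_identity(self) -> bool:
        return (
            self.time_shift_points == 0.0
            and self.magnitude_scale == 1.0
            and self.phase0_deg == 0.0
        )


@dataclass(frozen=True)
class CorruptionSpec:
    """Per-train corruption entries keyed by 0-based train index."""

    trains: dict[int, TrainCorruption] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "CorruptionSpec":
        return cls({int(k): TrainCorruption(**v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {
            str(k): {
                "time_shift_points": v.time_shift_points,
                "magnitude_scale": v.magnitude_scale,
                "phase0_deg": v.phase0_deg,
            }
            for k, v in self.trains.items()
        }


def split_trains(ets: EchoTrainSet, n_out: int) -> EchoTrainSet:
    """Reorganize a single-train acquisition into ``n_out`` interleaves.

    With 1-based echo numbering, train j (1-based) receives the echoes
    congruent to j modulo ``n_out``; timing metadata is updated so that
    :func:`epsighost.acquisition.merge_trains` inverts the operation exactly.
    """
    if ets.cfg.n_trains != 1:
        raise ValueError("split_trains expects a single-train set")
    n_echo = ets.cfg.echoes_per_train
    if n_echo % n_out:
        raise ValueError(f"{n_echo} echoes not divisible into {n_out} trains")
    if n_out == 1:
        return ets
    _, _, ny, nx = ets.data.shape
    # 0-based echo m goes to train (m mod n_out) at position m // n_out;
    # train index k (0-based) = j−1 holds 1-based echoes j, j+n_out, ...
    out = np.transpose(
        ets.data[0].reshape(n_echo // n_out, n_out, ny, nx), (1, 0, 2, 3)
    ).copy()
    cfg = ets.cfg.replace_unchecked(n_trains=n_out, echoes_per_train=n_echo // n_out)
    return EchoTrainSet(out, cfg, provenance="reorganized")


def _check_train(ets: EchoTrainSet, train: int) -> None:
    if not 0 <= train < ets.cfg.n_trains:
        raise IndexError(f"train {train} out of range for {ets.cfg.n_trains} trains")


def apply_time_shift(ets: EchoTrainSet, train: int, shift_points: float) -> EchoTrainSet:
    """Resample every echo of ``train`` at readout positions ``n − shift_points``.

    Natural cubic splines, zero fill outside the original support. The sanity
    bound |shift| < n_read/4 rejects shifts large enough to slide the echo
    center out of the sampled window.
    """
    _check_train(ets, train)
    nx = ets.cfg.n_read
    if abs(shift_points) >= nx / 4:
        raise ValueError(f"|shift_points| must be < n_read/4 = {nx / 4}")
    if shift_points == 0.0:
        return ets
    grid = np.arange(nx, dtype=float)
    pos = grid - shift_points
    block = ets.data[train]  # (echoes, phase, read)
    spline_re = CubicSpline(grid, block.real, axis=-1, bc_type="natural")
    spline_im = CubicSpline(grid, block.imag, axis=-1, bc_type="natural")
    shifted = spline_re(pos) + 1j * spline_im(pos)
    shifted[..., (pos < 0) | (pos > nx - 1)] = 0.0
    out = ets.data.copy()
    out[train] = shifted
    return ets.with_data(out, provenance="corrupted")


def apply_magnitude_scale(ets: EchoTrainSet, train: int, a: float) -> EchoTrainSet:
    """Multiply all echoes of ``train`` by a real constant a > 0."""
    _check_train(ets, train)
    if not a > 0:
        raise ValueError("magnitude scale must be positive")
    if a == 1.0:
        return ets
    out = ets.data.copy()
    out[train] *= a
    return ets.with_data(out, provenance="corrupted")


def apply_phase0(ets: EchoTrainSet, train: int, phi_deg: float) -> EchoTrainSet:
    """Zero-order phase: multiply all echo points of ``train`` by exp(i Φ0)."""
    _check_train(ets, train)
    if phi_deg == 0.0:
        return ets
    out = ets.data.copy()
    out[train] *= np.exp(1j * np.deg2rad(phi_deg))
    return ets.with_data(out, provenance="corrupted")


def apply_corruption(ets: EchoTrainSet, spec: CorruptionSpec) -> EchoTrainSet:
    """Apply a full per-train corruption spec (shift, then scale, then phase).

    The three operators commute on a given train, so the order is only a
    convention. Corruption acts on raw echoes, before any zero-filling.
    """
    out = ets
    for train, c in sorted(spec.trains.items()):
        if c.time_shift_points:
            out = apply_time_shift(out, train, c.time_shift_points)
        if c.magnitude_scale != 1.0:
            out = apply_magnitude_scale(out, train, c.magnitude_scale)
        if c.phase0_deg:
            out = apply_phase0(out, train, c.phase0_deg)
    return out
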