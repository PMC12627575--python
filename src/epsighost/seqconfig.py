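"""Acquisition parameters for interleaved flyback EPSI and derived sequence quantities.

Unit conventions, used package-wide:

* sequence-level timing (echo spacing, TE, TR, ramps) in **ms**;
* sample-level timing (dwell time, temporal echo offsets) in **µs**;
* frequencies in **Hz** (Larmor frequency in MHz, so Hz/MHz gives ppm directly);
* lengths in **mm**, gradients in **mT/m**;
* the reduced gyromagnetic ratio ``gamma_bar`` (γ̄ = γ/2π) in **MHz/T**.

All internal arithmetic is carried at full precision; rounding to the two
decimals conventionally quoted for scan parameters happens only in
presentation helpers (:meth:`SequenceConfig.summary`).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SequenceConfig",
    "load_config",
    "paper_protocol",
    "PROTOCOL_NAMES",
]

#: CODATA proton value; reproduces the printed readout gradient exactly.
GAMMA_BAR_PROTON_MHZ_PER_T = 42.5774


class SequenceConfig(BaseModel):
    """Complete description of one interleaved flyback EPSI protocol.

    ``n_trains`` interleaved gradient-echo trains, each train offset by the
    effective echo spacing ``delta_te_eff`` relative to its predecessor, are
    merged into a single uniform spectroscopic time grid

        ``t_m = te1 + m * delta_te_eff``,  ``m = 0 .. n_trains*echoes_per_train - 1``

    so the intra-train (physical) echo spacing is ``n_trains * delta_te_eff``.
    """

    model_config = {"frozen": True}

    fov_read: float = Field(80.0, gt=0, description="readout field of view [mm]")
    fov_phase: float = Field(80.0, gt=0, description="phase-encode field of view [mm]")
    n_read: int = Field(256, gt=0, description="echo (readout) points per echo")
    n_phase: int = Field(192, gt=0, description="phase-encoding steps")
    n_trains: int = Field(1, description="number of interleaved echo trains N")
    echoes_per_train: int = Field(96, gt=0, description="echoes in each train")
    delta_te_eff: float = Field(1.55, gt=0, description="effective echo spacing ΔTE after interleaving [ms]")
    te1: float = Field(3.0, ge=0, description="time of the first echo TE1 [ms]")
    tr: float = Field(200.0, gt=0, description="repetition time [ms] (metadata)")
    flip_deg: float = Field(35.0, description="excitation flip angle [deg] (metadata)")
    rbw: float = Field(434028.0, gt=0, description="readout sampling bandwidth [Hz]")
    ramp: float = Field(0.15, ge=0, description="gradient ramp duration [ms] (metadata)")
    rewind_min: float = Field(0.6, ge=0, description="minimum rewind gradient duration incl. ramps [ms]")
    larmor: float = Field(128.33, gt=0, description="Larmor frequency [MHz]")
    gamma_bar: float = Field(GAMMA_BAR_PROTON_MHZ_PER_T, gt=0, description="γ/2π [MHz/T]")
    slice_thickness: float = Field(1.5, gt=0, description="slice thickness [mm] (metadata)")

    @model_validator(mode="after")
    def _check_consistency(self) -> "SequenceConfig":
        if self.n_trains not in (1, 2, 4):
            raise ValueError(f"n_trains must be 1, 2 or 4, got {self.n_trains}")
        # Hardware feasibility: every train must fit one full readout plus the
        # rewind into its physical echo spacing.
        spacing = self.intra_train_spacing()
        needed = self.readout_duration() + self.rewind_min
        if spacing + 1e-12 < needed:
            raise ValueError(
                "infeasible timing: intra-train echo spacing "
                f"{spacing:.4f} ms < readout {self.readout_duration():.4f} ms "
                f"+ rewind {self.rewind_min:.4f} ms"
            )
        return self

    # ------------------------------------------------------------------ timing
    def dwell_time(self) -> float:
        """Readout dwell time 1/rBW in µs."""
        return 1e6 / self.rbw

    def points_to_time(self, n_points: float) -> float:
        """Temporal offset in µs of a (possibly fractional, signed) echo-point shift."""
        if not math.isfinite(n_points):
            raise ValueError("n_points must be finite")
        return n_points * self.dwell_time()

    def readout_duration(self) -> float:
        """Flat-top duration of one readout, n_read · dwell, in ms."""
        return self.n_read * self.dwell_time() * 1e-3

    def intra_train_spacing(self) -> float:
        """Physical echo spacing within one train, N·ΔTE, in ms."""
        return self.n_trains * self.delta_te_eff

    def interleave_offsets(self) -> list[float]:
        """Start offset of each train relative to the first, in ms: (k−1)·ΔTE."""
        return [k * self.delta_te_eff for k in range(self.n_trains)]

    def effective_time_grid(self) -> np.ndarray:
        """Merged uniform spectroscopic time axis te1 + m·ΔTE [ms]."""
        m = np.arange(self.n_trains * self.echoes_per_train)
        return self.te1 + m * self.delta_te_eff

    # ---------------------------------------------------------------- derived
    def readout_gradient(self) -> float:
        """Readout gradient amplitude G_r = rBW / (γ̄ · FOV_read) in mT/m."""
        return self.rbw / (self.gamma_bar * self.fov_read)

    def nominal_resolution(self) -> tuple[float, float]:
        """Nominal in-plane resolution (Δx read, Δy phase) in mm."""
        return self.fov_read / self.n_read, self.fov_phase / self.n_phase

    def spectral_bandwidth(self) -> tuple[float, float]:
        """Spectral bandwidth of the merged train as (Hz, ppm)."""
        hz = 1000.0 / self.delta_te_eff
        return hz, hz / self.larmor

    def n_spectral_samples(self) -> int:
        """Total effective spectral samples N · echoes_per_train."""
        return self.n_trains * self.echoes_per_train

    # ------------------------------------------------------------------- I/O
    def summary(self) -> dict[str, float]:
        """Derived quantities rounded the way scan protocols print them."""
        sbw_hz, sbw_ppm = self.spectral_bandwidth()
        dx, dy = self.nominal_resolution()
        return {
            "dwell_us": round(self.dwell_time(), 2),
            "readout_gradient_mT_m": round(self.readout_gradient(), 2),
            "resolution_read_mm": round(dx, 2),
            "resolution_phase_mm": round(dy, 2),
            "sbw_hz": round(sbw_hz, 2),
            "sbw_ppm": round(sbw_ppm, 2),
            "intra_train_spacing_ms": round(self.intra_train_spacing(), 4),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def replace_unchecked(self, **updates: Any) -> "SequenceConfig":
        """Copy with updated fields, skipping validation.

        Needed for *virtual* configurations produced by processing (e.g. the
        merged single-train view of an interleaved acquisition), which may
        violate the hardware feasibility constraint on purpose.
        """
        return self.model_copy(update=updates)


def load_config(path: str | Path) -> SequenceConfig:
    """Load a :class:`SequenceConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return SequenceConfig(**data)


PROTOCOL_NAMES = ("paper_single", "paper_two", "paper_four")


def paper_protocol(name: str) -> SequenceConfig:
    """One of the three bundled acquisition protocols.

    ``paper_single``: 1 train × 96 echoes, ΔTE 1.55 ms (sBW 5.03 ppm), flip 35°;
    ``paper_two``:    2 trains × 48 echoes, ΔTE 0.8 ms (sBW 9.74 ppm), flip 45°;
    ``paper_four``:   4 trains × 24 echoes, ΔTE 0.8 ms, flip 45°.
    """
    if name not in PROTOCOL_NAMES:
        raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
    from importlib.resources import files

    text = files("epsighost.configs").joinpath(f"{name}.yaml").read_text()
    return SequenceConfig(**yaml.safe_load(text))
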