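"""Forward simulation of interleaved flyback EPSI acquisitions.

Signal model: the phantom lives on the acquisition grid, so the acquired
sample of train ``k``, echo ``m``, phase step ``p``, readout point ``n`` is
the exact discrete sum

    data[k,m,p,n] = Σ_voxels Σ_species ρ · exp(−t/T2) · exp(i2π (f_cs + ΔB0) t)
                    · exp(+i2π (k_x(n)·x + k_y(p)·y))

with ``t = time_of(k, m, n)``, ``k_x(n) = (n − n_read/2)/FOV_read`` and
``k_y(p) = (p − n_phase/2)/FOV_phase``. Sampling happens on the gradient
flat-top only; ramps and rewinds are dead time. Spatial encoding uses the
positive exponent; image reconstruction (recon module) applies the matching
negative-exponent centered DFT.

Acquisition-time bookkeeping (0-based indices)::

    time_of(k, m, n) = te1 + k·ΔTE + m·N·ΔTE + (n − n_read/2)·dwell

so merging the N trains in offset order yields the uniform effective grid
``te1 + m_eff·ΔTE`` with ``m_eff = m·N + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantom import Phantom
from .seqconfig import SequenceConfig

__all__ = ["EchoTrainSet", "simulate", "merge_trains"]


@dataclass(frozen=True)
class EchoTrainSet:
    """Complex raw data indexed ``[train][echo][phase][read]`` plus timing metadata."""

    data: np.ndarray
    cfg: SequenceConfig
    provenance: str = "simulated"  # simulated | reorganized | corrupted | loaded

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=complex)
        expected = (
            self.cfg.n_trains,
            self.cfg.echoes_per_train,
            self.cfg.n_phase,
            self.cfg.n_read,
        )
        if d.shape != expected:
            raise ValueError(f"data shape {d.shape} != cfg shape {expected}")
        if not np.all(np.isfinite(d)):
            raise ValueError("raw data must be finite")
        object.__setattr__(self, "data", d)

    def time_of(self, train: int, echo: int, sample: int | np.ndarray) -> float | np.ndarray:
        """Acquisition time from excitation in ms (0-based indices, echo center at n_read/2)."""
        cfg = self.cfg
        return (
            cfg.te1
            + train * cfg.delta_te_eff
            + echo * cfg.n_trains * cfg.delta_te_eff
            + (np.asarray(sample) - cfg.n_read // 2) * cfg.dwell_time() * 1e-3
        )

    def with_data(self, data: np.ndarray, provenance: str | None = None) -> "EchoTrainSet":
        return replace(self, data=data, provenance=provenance or self.provenance)


def _encode_matrices(cfg: SequenceConfig) -> tuple[np.ndarray, np.ndarray]:
    """Centered spatial-encoding DFT matrices Ey[p, iy], Ex[n, ix] (positive exponent)."""
    p = np.arange(cfg.n_phase) - cfg.n_phase // 2
    iy = np.arange(cfg.n_phase) - cfg.n_phase // 2
    n = np.arange(cfg.n_read) - cfg.n_read // 2
    ix = np.arange(cfg.n_read) - cfg.n_read // 2
    ey = np.exp(2j * np.pi * np.outer(p, iy) / cfg.n_phase)
    ex = np.exp(2j * np.pi * np.outer(n, ix) / cfg.n_read)
    return ey, ex


def simulate(
    phantom: Phantom,
    cfg: SequenceConfig,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> EchoTrainSet:
    """Simulate the full interleaved acquisition of ``phantom`` under ``cfg``.

    ``noise_sd`` adds complex Gaussian noise (that standard deviation per real
    channel); a ``seed`` is then mandatory so runs stay reproducible.
    """
    if not phantom.matches(cfg):
        raise ValueError(
            f"phantom grid {phantom.shape} does not match acquisition matrix "
            f"(n_phase={cfg.n_phase}, n_read={cfg.n_read})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0 and seed is None:
        raise ValueError("seed is required when noise is enabled")

    ey, ex = _encode_matrices(cfg)
    n_tr, ept = cfg.n_trains, cfg.echoes_per_train
    ny, nx = cfg.n_phase, cfg.n_read
    dwell_s = cfg.dwell_time() * 1e-6
    dte_s = cfg.delta_te_eff * 1e-3
    te1_s = cfg.te1 * 1e-3
    samp = np.arange(nx) - nx // 2

    data = np.zeros((n_tr, ept, ny, nx), dtype=complex)
    for sp in phantom.species:
        if not np.any(sp.density_map):
            continue
        freq = sp.chem_shift + phantom.b0_map  # Hz per voxel
        lam = 2j * np.pi * freq - 1.0 / (sp.t2 * 1e-3)  # 1/s
        # intra-echo evolution, shared by all echoes: (ny, nx, n_read)
        intra = np.exp(lam[:, :, None] * (samp * dwell_s)[None, None, :])
        rho_intra = sp.density_map[:, :, None] * intra
        for k in range(n_tr):
            for m in range(ept):
                t0 = te1_s + (k + m * n_tr) * dte_s  # echo-center time
                w0 = np.exp(lam * t0)
                weighted = (w0[:, :, None] * rho_intra).reshape(ny, nx * nx)
                tmp = (ey @ weighted).reshape(ny, nx, nx)  # Σ_iy
                # Σ_ix with the sample-dependent readout encoding
                data[k, m] += np.einsum("nx,pxn->pn", ex, tmp)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return EchoTrainSet(data, cfg, provenance="simulated")


def merge_trains(ets: EchoTrainSet) -> EchoTrainSet:
    """Interleave the N trains into one effective train ordered by acquisition time.

    Output echo index ``m_eff = m·N + k``; inverse of
    :func:`epsighost.corruption.split_trains`. The merged configuration is a
    processing construct (its virtual single train need not be hardware-
    feasible), so it is built without re-validation.
    """
    cfg = ets.cfg
    n_tr, ept, ny, nx = ets.data.shape
    merged = np.transpose(ets.data, (1, 0, 2, 3)).reshape(1, n_tr * ept, ny, nx)
    mcfg = cfg.replace_unchecked(n_trains=1, echoes_per_train=n_tr * ept)
    return EchoTrainSet(merged, mcfg, provenance=ets.provenance)
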