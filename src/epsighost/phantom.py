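"""Synthetic spectroscopic-imaging objects.

A :class:`Phantom` is a set of chemical :class:`Species` (proton density map,
chemical-shift offset, T2) sharing one spatial grid, plus a static-field
offset map ΔB0 in Hz. The default object is a two-compartment cylinder —
a water half-disc (MnCl2-doped, T2 ≈ 30 ms, shift 0 as the reference) and a
vegetable-oil half-disc (T2 ≈ 70 ms, (-CH2-)n line 3.4 ppm below water).

Grid convention: arrays are indexed ``[iy][ix]`` with x the readout and y the
phase-encode direction; the magnet isocenter sits at index ``(n_y//2, n_x//2)``
consistent with FFT centering. By default the grid equals the acquisition
matrix (n_phase × n_read), which makes the forward model an exact discrete
Fourier pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqconfig import SequenceConfig

__all__ = [
    "Species",
    "Phantom",
    "make_water_oil_phantom",
    "point_phantom",
    "uniform_slab_phantom",
    "make_b0_map",
]

#: water vs (-CH2-)n methylene separation in ppm (water is the 0-ppm reference)
DEFAULT_OIL_SHIFT_PPM = -3.4


@dataclass(frozen=True)
class Species:
    """One chemical species on the shared grid.

    ``t2`` may be ``numpy.inf`` for idealized decay-free objects used by the
    closed-form oracle tests.
    """

    name: str
    density_map: np.ndarray  # [n_y][n_x], arbitrary units, >= 0
    chem_shift: float  # Hz relative to the reference line
    t2: float  # ms, > 0

    def __post_init__(self) -> None:
        d = np.asarray(self.density_map, dtype=float)
        if d.ndim != 2:
            raise ValueError("density_map must be 2-D [n_y][n_x]")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("density_map must be finite and non-negative")
        if not self.t2 > 0:
            raise ValueError("t2 must be positive")
        object.__setattr__(self, "density_map", d)


@dataclass(frozen=True)
class Phantom:
    species: list[Species]
    b0_map: np.ndarray  # Hz offset per voxel
    grid_spacing: tuple[float, float]  # (dy, dx) mm
    origin: tuple[int, int] = field(default=None)  # isocenter index (iy, ix)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("phantom needs at least one species")
        shape = self.species[0].density_map.shape
        for s in self.species:
            if s.density_map.shape != shape:
                raise ValueError("all species maps must share one shape")
        b0 = np.asarray(self.b0_map, dtype=float)
        if b0.shape != shape:
            raise ValueError("b0_map shape must match species maps")
        if not np.all(np.isfinite(b0)):
            raise ValueError("b0_map must be finite")
        object.__setattr__(self, "b0_map", b0)
        if self.origin is None:
            object.__setattr__(self, "origin", (shape[0] // 2, shape[1] // 2))

    @property
    def shape(self) -> tuple[int, int]:
        return self.species[0].density_map.shape

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) coordinates of the grid nodes in mm, isocenter at 0."""
        ny, nx = self.shape
        dy, dx = self.grid_spacing
        y = (np.arange(ny) - self.origin[0]) * dy
        x = (np.arange(nx) - self.origin[1]) * dx
        return y, x

    def matches(self, cfg: SequenceConfig) -> bool:
        ny, nx = self.shape
        return nx == cfg.n_read and ny == cfg.n_phase


def _grid_for(cfg_or_shape, fov_mm: tuple[float, float] | None):
    """Resolve (shape, spacing) from a SequenceConfig or an explicit shape."""
    if isinstance(cfg_or_shape, SequenceConfig):
        cfg = cfg_or_shape
        return (cfg.n_phase, cfg.n_read), (cfg.fov_phase / cfg.n_phase, cfg.fov_read / cfg.n_read)
    shape = tuple(cfg_or_shape)
    if fov_mm is None:
        raise ValueError("fov_mm required when grid_shape is given explicitly")
    return shape, (fov_mm[0] / shape[0], fov_mm[1] / shape[1])


def make_b0_map(shape, spacing, spec="uniform") -> np.ndarray:
    """Build a ΔB0 map [Hz]: 'uniform', ('linear', gx, gy) in Hz/mm, or
    ('bump', amplitude_hz, sigma_mm) for a smooth Gaussian bump at isocenter."""
    ny, nx = shape
    dy, dx = spacing
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    if spec == "uniform" or spec is None:
        return np.zeros(shape)
    kind = spec[0]
    if kind == "linear":
        _, gx, gy = spec
        return gx * xx + gy * yy
    if kind == "bump":
        _, amp, sigma = spec
        return amp * np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    raise ValueError(f"unknown b0 spec {spec!r}")


def make_water_oil_phantom(
    cfg_or_shape,
    *,
    fov_mm: tuple[float, float] | None = None,
    diameter_mm: float = 26.0,
    center_mm: tuple[float, float] = (0.0, 0.0),
    t2_water: float = 30.0,
    t2_oil: float = 70.0,
    oil_shift_hz: float | None = None,
    larmor_mhz: float = 128.33,
    water_density: float = 1.0,
    oil_density: float = 1.0,
    b0: object = "uniform",
) -> Phantom:
    """Two-compartment cylinder section: water lower half-disc, oil upper half-disc.

    The oil/water arrangement inside the physical cylinder is not prescribed;
    a half-disc split along the phase-encode axis is used and documented.
    ``oil_shift_hz`` defaults to −3.4 ppm × larmor ≈ −436 Hz. Set a density to
    0 to drop that compartment. Compartments are disjoint by construction.
    """
    shape, spacing = _grid_for(cfg_or_shape, fov_mm)
    ny, nx = shape
    dy, dx = spacing
    if diameter_mm > min(ny * dy, nx * dx):
        raise ValueError("phantom does not fit inside the field of view")
    if oil_shift_hz is None:
        oil_shift_hz = DEFAULT_OIL_SHIFT_PPM * larmor_mhz

    y = (np.arange(ny) - ny // 2) * dy - center_mm[0]
    x = (np.arange(nx) - nx // 2) * dx - center_mm[1]
    yy, xx = np.meshgrid(y, x, indexing="ij")
    disc = xx**2 + yy**2 <= (diameter_mm / 2.0) ** 2
    water_mask = disc & (yy < 0)
    oil_mask = disc & (yy >= 0)
    if np.any(water_mask & oil_mask):  # defensive; disjoint by construction
        raise ValueError("compartments overlap")

    species = [
        Species("water", water_density * water_mask.astype(float), 0.0, t2_water),
        Species("oil", oil_density * oil_mask.astype(float), oil_shift_hz, t2_oil),
    ]
    b0_map = b0 if isinstance(b0, np.ndarray) else make_b0_map(shape, spacing, b0)
    return Phantom(species, b0_map, spacing)


def point_phantom(
    cfg_or_shape,
    position_mm: tuple[float, float] = (0.0, 0.0),
    *,
    fov_mm: tuple[float, float] | None = None,
    name: str = "water",
    chem_shift: float = 0.0,
    t2: float = np.inf,
    amplitude: float = 1.0,
    b0: object = "uniform",
) -> Phantom:
    """Delta object: one nonzero voxel at the grid node nearest ``position_mm`` (y, x)."""
    shape, spacing = _grid_for(cfg_or_shape, fov_mm)
    ny, nx = shape
    dy, dx = spacing
    iy = ny // 2 + int(round(position_mm[0] / dy))
    ix = nx // 2 + int(round(position_mm[1] / dx))
    if not (0 <= iy < ny and 0 <= ix < nx):
        raise ValueError(f"position {position_mm} mm falls outside the field of view")
    density = np.zeros(shape)
    density[iy, ix] = amplitude
    b0_map = b0 if isinstance(b0, np.ndarray) else make_b0_map(shape, spacing, b0)
    return Phantom([Species(name, density, chem_shift, t2)], b0_map, spacing)


def uniform_slab_phantom(
    cfg_or_shape,
    *,
    fov_mm: tuple[float, float] | None = None,
    n_rows: int = 4,
    name: str = "water",
    chem_shift: float = 0.0,
    t2: float = np.inf,
    b0: object = "uniform",
) -> Phantom:
    """Slab spanning the full readout extent over ``n_rows`` central phase rows.

    Used to probe readout-position-dependent effects (dark strips, GTR vs x)
    across the whole field of view.
    """
    shape, spacing = _grid_for(cfg_or_shape, fov_mm)
    ny, nx = shape
    density = np.zeros(shape)
    lo = ny // 2 - n_rows // 2
    density[lo : lo + n_rows, :] = 1.0
    b0_map = b0 if isinstance(b0, np.ndarray) else make_b0_map(shape, spacing, b0)
    return Phantom([Species(name, density, chem_shift, t2)], b0_map, spacing)
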