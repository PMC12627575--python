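"""File formats and the serializable experiment description.

Complex arrays (raw echo trains, spectral cubes, phantoms) travel in an HDF5
archive with a fixed layout: complex data as paired float64 datasets
``data_re`` / ``data_im``; the sequence configuration embedded as a JSON
string attribute ``cfg_json``; provenance and axis conventions as attributes.
Real-valued images and VOI masks export to NIfTI (voxel size in the header);
spectra and search traces export to CSV with repr-round-trip float formatting,
so write→read is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .acquisition import EchoTrainSet
from .phantom import Phantom, Species
from .recon import VOI, LineImage, SpectralCube
from .seqconfig import SequenceConfig

__all__ = [
    "ExperimentSpec",
    "save_echo_trains",
    "load_echo_trains",
    "save_cube",
    "load_cube",
    "save_phantom",
    "load_phantom",
    "write_line_image_nifti",
    "write_voi_nifti",
    "spectrum_to_csv",
    "read_spectrum_csv",
    "trace_to_csv",
]

_FLOAT_FMT = "%.17g"  # repr-round-trip for float64


# ------------------------------------------------------------------- HDF5


def _write_complex(group: h5py.Group, name: str, arr: np.ndarray) -> None:
    group.create_dataset(f"{name}_re", data=np.ascontiguousarray(arr.real))
    group.create_dataset(f"{name}_im", data=np.ascontiguousarray(arr.imag))


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    return np.asarray(group[f"{name}_re"]) + 1j * np.asarray(group[f"{name}_im"])


def save_echo_trains(path: str | Path, ets: EchoTrainSet) -> None:
    """Archive layout: /data_re, /data_im [train][echo][phase][read];
    attrs: cfg_json, provenance, axis_order."""
    with h5py.File(path, "w") as f:
        _write_complex(f, "data", ets.data)
        f.attrs["cfg_json"] = ets.cfg.model_dump_json()
        f.attrs["provenance"] = ets.provenance
        f.attrs["axis_order"] = "train,echo,phase,read"


def load_echo_trains(path: str | Path) -> EchoTrainSet:
    with h5py.File(path, "r") as f:
        data = _read_complex(f, "data")
        cfg = SequenceConfig.model_construct(**json.loads(f.attrs["cfg_json"]))
        prov = str(f.attrs.get("provenance", "loaded"))
    return EchoTrainSet(data, cfg, provenance=prov)


def save_cube(path: str | Path, cube: SpectralCube) -> None:
    with h5py.File(path, "w") as f:
        _write_complex(f, "data", cube.values)
        f.create_dataset("freq_hz", data=cube.freq_hz)
        f.attrs["voxel_size_mm"] = list(cube.voxel_size)
        f.attrs["larmor_mhz"] = cube.larmor
        f.attrs["axis_order"] = "y,x,f"
        if cube.cfg is not None:
            f.attrs["cfg_json"] = cube.cfg.model_dump_json()


def load_cube(path: str | Path) -> SpectralCube:
    with h5py.File(path, "r") as f:
        vals = _read_complex(f, "data")
        freq = np.asarray(f["freq_hz"])
        voxel = tuple(f.attrs["voxel_size_mm"])
        larmor = float(f.attrs["larmor_mhz"])
        cfg = None
        if "cfg_json" in f.attrs:
            cfg = SequenceConfig.model_construct(**json.loads(f.attrs["cfg_json"]))
    return SpectralCube(vals, freq, voxel, larmor, cfg)


def save_phantom(path: str | Path, ph: Phantom) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("b0_map", data=ph.b0_map)
        f.attrs["grid_spacing_mm"] = list(ph.grid_spacing)
        f.attrs["origin"] = list(ph.origin)
        for i, sp in enumerate(ph.species):
            g = f.create_group(f"species_{i}")
            g.create_dataset("density_map", data=sp.density_map)
            g.attrs["name"] = sp.name
            g.attrs["chem_shift_hz"] = sp.chem_shift
            g.attrs["t2_ms"] = sp.t2


def load_phantom(path: str | Path) -> Phantom:
    with h5py.File(path, "r") as f:
        b0 = np.asarray(f["b0_map"])
        spacing = tuple(f.attrs["grid_spacing_mm"])
        origin = tuple(int(v) for v in f.attrs["origin"])
        species = []
        i = 0
        while f"species_{i}" in f:
            g = f[f"species_{i}"]
            species.append(
                Species(
                    str(g.attrs["name"]),
                    np.asarray(g["density_map"]),
                    float(g.attrs["chem_shift_hz"]),
                    float(g.attrs["t2_ms"]),
                )
            )
            i += 1
    return Phantom(species, b0, spacing, origin)


# ------------------------------------------------------------------ NIfTI


def _nifti(values: np.ndarray, voxel_size: tuple[float, float]) -> nib.Nifti1Image:
    affine = np.diag([voxel_size[1], voxel_size[0], 1.0, 1.0])  # (x, y) mm
    return nib.Nifti1Image(np.asarray(values, dtype=np.float64).T, affine)


def write_line_image_nifti(path: str | Path, img: LineImage) -> None:
    _nifti(img.values, img.voxel_size).to_filename(str(path))


def write_voi_nifti(path: str | Path, voi: VOI, voxel_size: tuple[float, float]) -> None:
    _nifti(voi.mask.astype(np.uint8), voxel_size).to_filename(str(path))


# -------------------------------------------------------------------- CSV


def spectrum_to_csv(
    path: str | Path, freq_hz: np.ndarray, magnitude: np.ndarray, larmor_mhz: float
) -> None:
    df = pd.DataFrame(
        {"freq_hz": freq_hz, "freq_ppm": np.asarray(freq_hz) / larmor_mhz, "magnitude": magnitude}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectrum_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def trace_to_csv(path: str | Path, trace: dict[str, list[tuple[float, float]]]) -> None:
    rows = [
        {"stage": stage, "phase_deg": p, "gtr": g}
        for stage, samples in trace.items()
        for p, g in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------- experiment spec


class PhantomSpec(BaseModel):
    """Declarative phantom description used by the CLI drivers."""

    kind: str = "water_oil"  # water_oil | point | slab
    params: dict[str, Any] = Field(default_factory=dict)

    def build(self, cfg: SequenceConfig) -> Phantom:
        from . import phantom as ph

        params = dict(self.params)
        if "b0" in params and isinstance(params["b0"], list):
            params["b0"] = tuple(params["b0"])
        if self.kind == "water_oil":
            params.setdefault("larmor_mhz", cfg.larmor)
            return ph.make_water_oil_phantom(cfg, **params)
        if self.kind == "point":
            pos = tuple(params.pop("position_mm", (0.0, 0.0)))
            return ph.point_phantom(cfg, pos, **params)
        if self.kind == "slab":
            return ph.uniform_slab_phantom(cfg, **params)
        raise ValueError(f"unknown phantom kind {self.kind!r}")


class ExperimentSpec(BaseModel):
    """Fully serializable experiment: re-running with a fixed seed reproduces
    all outputs bit-for-bit."""

    sequence: SequenceConfig = Field(default_factory=SequenceConfig)
    phantom: PhantomSpec = Field(default_factory=PhantomSpec)
    corruption: dict[str, dict[str, float]] = Field(default_factory=dict)
    split_into: int | None = None
    noise_sd: float = 0.0
    seed: int = 0
    zero_fill: list[int] | None = [256, 256, 256]
    chemshift_correction: bool = True
    b0_method: str | None = None
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def spec_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]
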