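"""Experiment configuration and file I/O.

Configs are YAML (or JSON) with geometry / optics / scene / noise /
solver blocks.  Volumes travel as NIfTI (voxel size recorded in the
header, cm stored as mm x 10 per NIfTI convention), measurements as CSV
(detector_id, source_id, value at 17 significant digits, bit-faithful
round-trip) with an optional HDF5 mirror for large runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .forward import (
    OpticalBackground,
    OptodeLayout,
    VoxelGrid,
    make_grid,
    make_layout,
    standard_grid,
)
from .phantoms import (
    DEFAULT_DELTA_MUA,
    Inclusion,
    MeasurementSet,
    PhantomScene,
    ReconVolume,
    scene_library,
)
from .pipeline import DroOptions
from .solvers import SolverConfig

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "write_nifti",
    "read_nifti",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_measurements_h5",
    "read_measurements_h5",
]


class ConfigError(ValueError):
    """Raised on malformed experiment configuration, with the field path."""


@dataclass
class ExperimentConfig:
    """Fully resolved experiment description (units cm and 1/cm)."""

    variant: str = "SD-I"
    pitch: float | None = None
    include_colocated: bool = False
    grid_origin: tuple | None = None
    grid_shape: tuple | None = None
    voxel_size: float = 0.2

    mua: float = 0.03
    musp: float = 10.0
    n_index: float = 1.33
    boundary_A: float = 2.0

    scene: str | None = "fig1_disk"
    inclusions: list = field(default_factory=list)
    delta_mua: float = DEFAULT_DELTA_MUA

    noise_level: float = 0.02
    seed: int = 0
    replicates: int = 1

    tau: float = 0.96
    depth_comp: bool = True
    p: float = 1.0
    lam: float | None = None
    alphas: list | None = None
    tol: float = 1e-5
    max_iter: int = 2000
    admm_mu: float = 1.0
    eps_support: float = 1e-3

    def layout(self) -> OptodeLayout:
        return make_layout(self.variant, self.pitch, self.include_colocated)

    def grid(self) -> VoxelGrid:
        if self.grid_origin is not None and self.grid_shape is not None:
            return make_grid(self.grid_origin, self.grid_shape, self.voxel_size)
        return standard_grid(self.variant, self.voxel_size)

    def background(self) -> OpticalBackground:
        return OpticalBackground(self.mua, self.musp, self.n_index, self.boundary_A)

    def phantom(self) -> PhantomScene:
        if self.inclusions:
            incs = tuple(
                Inclusion(
                    i["shape"],
                    tuple(i["center"]),
                    tuple(np.atleast_1d(i["dims"])),
                    float(i.get("delta_mua", self.delta_mua)),
                )
                for i in self.inclusions
            )
            return PhantomScene(incs, name="inline")
        if self.scene is None:
            raise ConfigError("config has neither 'scene' nor 'inclusions'")
        return scene_library(self.scene, self.delta_mua)

    def solver(self) -> SolverConfig:
        return SolverConfig(
            admm_mu=self.admm_mu, tol=self.tol, max_iter=self.max_iter
        )

    def dro_options(self) -> DroOptions:
        return DroOptions(
            tau=self.tau,
            depth_comp=self.depth_comp,
            p=self.p,
            lam=self.lam,
            alphas=np.asarray(self.alphas) if self.alphas else None,
            eps_support=self.eps_support,
            solver=self.solver(),
        )


_BLOCK_FIELDS = {
    "geometry": {
        "variant": "variant",
        "pitch_cm": "pitch",
        "include_colocated": "include_colocated",
        "origin_cm": "grid_origin",
        "shape": "grid_shape",
        "voxel_cm": "voxel_size",
    },
    "optics": {
        "mua": "mua",
        "musp": "musp",
        "n_index": "n_index",
        "A_bnd": "boundary_A",
    },
    "scene": {"name": "scene", "inclusions": "inclusions", "delta_mua": "delta_mua"},
    "noise": {"level": "noise_level", "seed": "seed", "replicates": "replicates"},
    "solver": {
        "tau": "tau",
        "depth_comp": "depth_comp",
        "p": "p",
        "lam": "lam",
        "alphas": "alphas",
        "tol": "tol",
        "max_iter": "max_iter",
        "admm_mu": "admm_mu",
        "eps_support": "eps_support",
    },
}


def load_config(path) -> ExperimentConfig:
    """Parse a YAML/JSON experiment config with field-path error messages."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # JSON is a YAML subset; one parser suffices
        raise ConfigError(f"{path}: not valid YAML/JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = ExperimentConfig()
    for block, mapping in _BLOCK_FIELDS.items():
        sub = raw.get(block, {})
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"{path}: '{block}' must be a mapping")
        for key, val in sub.items():
            if key not in mapping:
                raise ConfigError(f"{path}: unknown field '{block}.{key}'")
            setattr(cfg, mapping[key], val)
    unknown = set(raw) - set(_BLOCK_FIELDS)
    if unknown:
        raise ConfigError(f"{path}: unknown top-level block(s) {sorted(unknown)}")
    try:
        cfg.layout(), cfg.grid(), cfg.background()
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return cfg


# ---------------------------------------------------------------------------
# Volumes (NIfTI)


def write_nifti(vol: ReconVolume, path) -> None:
    """float32 NIfTI; affine encodes the voxel size (cm -> mm x 10)."""
    h_mm = vol.grid.voxel_size * 10.0
    affine = np.diag([h_mm, h_mm, h_mm, 1.0])
    affine[:3, 3] = np.asarray(vol.grid.origin) * 10.0
    img = nib.Nifti1Image(vol.as_volume().astype(np.float32), affine)
    img.header.set_zooms((h_mm, h_mm, h_mm))
    nib.save(img, str(path))


def read_nifti(path) -> ReconVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    h_cm = float(img.header.get_zooms()[0]) / 10.0
    origin = tuple(np.asarray(img.affine[:3, 3]) / 10.0)
    grid = make_grid(origin, data.shape, h_cm)
    return ReconVolume(grid.from_volume(data), grid)


# ---------------------------------------------------------------------------
# Measurements (CSV / HDF5)


def write_measurements_csv(ms: MeasurementSet, path) -> None:
    """detector_id, source_id, value rows; 17 significant digits so the
    vector round-trips bit-exactly.  sigma2/seed go to a JSON sidecar."""
    pairs = ms.layout.pair_list
    df = pd.DataFrame(
        {
            "detector_id": [d for d, _ in pairs],
            "source_id": [s for _, s in pairs],
            "value": ms.y,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    _sidecar(path).write_text(
        json.dumps({"sigma2": ms.sigma2, "seed": ms.seed}, indent=1)
    )


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def read_measurements_csv(path) -> tuple[np.ndarray, float | None, pd.DataFrame]:
    """Returns (y, sigma2 or None, full dataframe)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("detector_id", "source_id", "value"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column '{col}'")
    sigma2 = None
    meta = _sidecar(path)
    if meta.exists():
        sigma2 = json.loads(meta.read_text()).get("sigma2")
    return df["value"].to_numpy(dtype=float), sigma2, df


def write_measurements_h5(ms: MeasurementSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=ms.y)
        f.create_dataset("pairs", data=np.asarray(ms.layout.pair_list))
        f.attrs["sigma2"] = ms.sigma2
        if ms.seed is not None:
            f.attrs["seed"] = ms.seed


def read_measurements_h5(path) -> tuple[np.ndarray, float | None]:
    with h5py.File(path, "r") as f:
        y = f["y"][:]
        sigma2 = float(f.attrs["sigma2"]) if "sigma2" in f.attrs else None
    return y, sigma2
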