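"""Phantom scenes and synthetic measurement generation.

Voxelized absorption-perturbation phantoms (cylinders and spheres in an
intralipid-like homogeneous background) and the additive-Gaussian
measurement simulator.  These scenes are the synthetic stand-in for the
laboratory phantom experiments the reconstruction algorithm targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import SensingMatrix, VoxelGrid

__all__ = [
    "Inclusion",
    "PhantomScene",
    "ReconVolume",
    "MeasurementSet",
    "voxelize_scene",
    "simulate_measurements",
    "estimate_noise_variance",
    "scene_library",
    "SCENE_NAMES",
]

#: default absorption contrast (1/cm) for "black" high-contrast inclusions
DEFAULT_DELTA_MUA = 0.2


@dataclass(frozen=True)
class Inclusion:
    """A single absorbing inclusion.

    shape: ``cylinder_z`` (axis along depth; dims = (diameter, length)) or
    ``sphere`` (dims = (diameter,)).  center in cm, delta_mua in 1/cm.
    """

    shape: str
    center: tuple[float, float, float]
    dims: tuple[float, ...]
    delta_mua: float = DEFAULT_DELTA_MUA

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder_z", "sphere"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if not self.delta_mua > 0:
            raise ValueError("delta_mua must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Membership of (n, 3) points; cylinder depth extent half-open."""
        c = np.asarray(self.center)
        if self.shape == "sphere":
            r = self.dims[0] / 2.0
            return np.linalg.norm(pts - c, axis=1) <= r
        r, length = self.dims[0] / 2.0, self.dims[1]
        radial = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r
        axial = (pts[:, 2] >= c[2] - length / 2.0) & (pts[:, 2] < c[2] + length / 2.0)
        return radial & axial

    def analytic_volume(self) -> float:
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * (self.dims[0] / 2.0) ** 3
        return np.pi * (self.dims[0] / 2.0) ** 2 * self.dims[1]


@dataclass(frozen=True)
class PhantomScene:
    inclusions: tuple[Inclusion, ...]
    name: str = "custom"

    def __iter__(self):
        return iter(self.inclusions)


@dataclass
class ReconVolume:
    """Per-voxel absorption perturbation (1/cm) on a grid, flat order."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError(
                f"values length {self.values.shape} does not match grid "
                f"voxel count {self.grid.n_voxels}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    def as_volume(self) -> np.ndarray:
        return self.grid.to_volume(self.values)


@dataclass
class MeasurementSet:
    """Rytov measurement vector with its noise-variance record."""

    y: np.ndarray
    sigma2: float
    seed: int | None = None
    layout: object = None
    grid: VoxelGrid | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")


def voxelize_scene(scene: PhantomScene, grid: VoxelGrid) -> ReconVolume:
    """Rasterize a scene: voxel value = sum of delta_mua of inclusions
    whose shape contains the voxel center.

    Raises if any inclusion's center lies outside the grid volume.
    """
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.shape) * grid.voxel_size
    for inc in scene:
        c = np.asarray(inc.center)
        if np.any(c < lo) or np.any(c > hi):
            raise ValueError(f"inclusion center {inc.center} outside grid volume")
    pts = grid.centers()
    vals = np.zeros(grid.n_voxels)
    for inc in scene:
        vals[inc.contains(pts)] += inc.delta_mua
    return ReconVolume(vals, grid)


def simulate_measurements(
    A: SensingMatrix,
    x_true: ReconVolume,
    noise_level: float = 0.02,
    seed: int | None = None,
) -> MeasurementSet:
    """Forward-project a truth volume and add i.i.d. Gaussian noise.

    The noise standard deviation is ``noise_level`` times the RMS of the
    clean data A @ x, so noise_level is a fractional noise floor.  The
    realized sigma^2 is stored for the discrepancy-principle selector.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    if x_true.grid.n_voxels != A.shape[1]:
        raise ValueError("truth volume does not match sensing-matrix columns")
    clean = A.values @ x_true.values
    sigma = noise_level * float(np.sqrt(np.mean(clean**2)))
    rng = np.random.default_rng(seed)
    y = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean.copy()
    return MeasurementSet(y, sigma**2, seed=seed, layout=A.layout, grid=A.grid)


def estimate_noise_variance(replicates) -> float:
    """Pooled noise variance from repeated measurements.

    Per-channel sample variance (ddof=1) across >= 2 replicate
    acquisitions, averaged over channels — the practical estimate enabled
    by the high sampling rate of CW instruments.
    """
    reps = np.asarray(list(replicates), dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 2:
        raise ValueError("need at least two replicate measurement vectors")
    return float(np.mean(np.var(reps, axis=0, ddof=1)))


def _sd_center(depth: float) -> tuple[float, float, float]:
    # center of the 4x4 cm SD imaging volume
    return (2.0, 2.0, depth)


def _tr_center(dx: float, depth: float) -> tuple[float, float, float]:
    # transrectal volume spans x in [-1, 5], y in [-1, 3]; probe center x=2, y=1
    return (2.0 + dx, 1.0, depth)


SCENE_NAMES = ("fig1_disk", "fig7a_B", "fig7b_Cs", "fig7c_dualC1", "fig7d_C1C2")


def scene_library(name: str, delta_mua: float = DEFAULT_DELTA_MUA) -> PhantomScene:
    """Standard benchmark phantoms.

    ``fig1_disk``
        1.1 cm diameter x 0.4 cm thick disk centred in the SD volume at
        1.5 cm depth — the brain-imaging surrogate.
    ``fig7a_B`` … ``fig7d_C1C2``
        Transrectal-probe phantoms: a 0.9 cm sphere at 1.8 cm depth; a
        tiny 0.2 x 0.3 cm cylinder at 1.5 cm; two identical 0.85 x 0.62 cm
        cylinders 1.5 cm apart (centre to centre); and a 0.85/0.65 cm
        cylinder pair 1 cm apart, all at 1.5 cm depth.
    """
    d = delta_mua
    if name == "fig1_disk":
        incs = (Inclusion("cylinder_z", _sd_center(1.5), (1.1, 0.4), d),)
    elif name == "fig7a_B":
        incs = (Inclusion("sphere", _tr_center(0.0, 1.8), (0.9,), d),)
    elif name == "fig7b_Cs":
        incs = (Inclusion("cylinder_z", _tr_center(0.0, 1.5), (0.2, 0.3), d),)
    elif name == "fig7c_dualC1":
        incs = (
            Inclusion("cylinder_z", _tr_center(-0.75, 1.5), (0.85, 0.62), d),
            Inclusion("cylinder_z", _tr_center(+0.75, 1.5), (0.85, 0.62), d),
        )
    elif name == "fig7d_C1C2":
        incs = (
            Inclusion("cylinder_z", _tr_center(-0.5, 1.5), (0.85, 0.62), d),
            Inclusion("cylinder_z", _tr_center(+0.5, 1.5), (0.65, 0.45), d),
        )
    else:
        raise ValueError(f"unknown scene {name!r}; choose from {SCENE_NAMES}")
    return PhantomScene(incs, name=name)
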