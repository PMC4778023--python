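"""Forward model for continuous-wave diffuse optical tomography.

Voxel grids, optode layouts, and the linearized (Rytov) sensing matrix
for a semi-infinite homogeneous medium.  Photon transport is modelled with
the diffusion approximation; the half-space Green's function uses the
image-source construction about an extrapolated boundary.

Geometry conventions
--------------------
Coordinates are in cm.  The optode plane is z = 0 and depth increases with
z.  Voxels are indexed layer-major (all voxels of the shallowest layer
first), so the per-depth-layer blocks of the sensing matrix occupy
contiguous column ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "OptodeLayout",
    "OpticalBackground",
    "SensingMatrix",
    "make_grid",
    "make_layout",
    "standard_grid",
    "greens_fn",
    "build_sensing_matrix",
]

#: default extrapolated-boundary constant (refractive-index mismatch factor)
DEFAULT_BOUNDARY_A = 2.0


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid covering the imaging volume.

    Parameters
    ----------
    origin : tuple of float
        Coordinates (cm) of the corner of voxel (0, 0, 0).
    shape : tuple of int
        Voxel counts ``(nx, ny, nz)``.
    voxel_size : float
        Cubic voxel edge length h (cm).
    """

    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    voxel_size: float

    def __post_init__(self) -> None:
        if any(int(s) < 1 for s in self.shape):
            raise ValueError(f"voxel counts must be >= 1, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def n_layers(self) -> int:
        return self.shape[2]

    @property
    def voxels_per_layer(self) -> int:
        return self.shape[0] * self.shape[1]

    def centers(self) -> np.ndarray:
        """(n, 3) voxel-center coordinates in flat (layer-major) order."""
        nx, ny, nz = self.shape
        h = self.voxel_size
        ox, oy, oz = self.origin
        ix = ox + (np.arange(nx) + 0.5) * h
        iy = oy + (np.arange(ny) + 0.5) * h
        iz = oz + (np.arange(nz) + 0.5) * h
        zz, yy, xx = np.meshgrid(iz, iy, ix, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def flat_index(self, ix: int, iy: int, iz: int) -> int:
        nx, ny, _ = self.shape
        return iz * (nx * ny) + iy * nx + ix

    def unflatten(self, k: int) -> tuple[int, int, int]:
        nx, ny, _ = self.shape
        iz, rem = divmod(k, nx * ny)
        iy, ix = divmod(rem, nx)
        return ix, iy, iz

    def layer_of(self, k: int | np.ndarray) -> int | np.ndarray:
        """0-based depth-layer index of flat voxel index ``k``."""
        return np.asarray(k) // self.voxels_per_layer

    def layer_slice(self, iz: int) -> slice:
        npl = self.voxels_per_layer
        return slice(iz * npl, (iz + 1) * npl)

    def to_volume(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flat vector to an (nx, ny, nz) array."""
        nx, ny, nz = self.shape
        return np.asarray(flat).reshape(nz, ny, nx).transpose(2, 1, 0)

    def from_volume(self, vol: np.ndarray) -> np.ndarray:
        return np.asarray(vol).transpose(2, 1, 0).ravel()


@dataclass(frozen=True)
class OpticalBackground:
    """Homogeneous background optical properties.

    mua, musp in 1/cm; refractive_index dimensionless.  The diffusion
    coefficient is D = 1/(3(mua+musp)) and the effective attenuation
    mu_eff = sqrt(mua/D) = sqrt(3 mua (mua+musp)).
    """

    mua: float = 0.03
    musp: float = 10.0
    refractive_index: float = 1.33
    boundary_A: float = DEFAULT_BOUNDARY_A

    def __post_init__(self) -> None:
        if not (self.mua > 0 and self.musp > 0):
            raise ValueError("mua and musp must be positive")

    @property
    def D(self) -> float:
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mu_eff(self) -> float:
        return float(np.sqrt(self.mua / self.D))

    @property
    def z_b(self) -> float:
        """Extrapolated-boundary distance above the surface (cm)."""
        return 2.0 * self.boundary_A * self.D

    @property
    def z_0(self) -> float:
        """Effective isotropic source depth 1/(mua+musp) (cm)."""
        return 1.0 / (self.mua + self.musp)


@dataclass(frozen=True)
class OptodeLayout:
    """Source and detector positions on the z = 0 measurement plane.

    ``pair_list`` holds the ordered (detector index, source index)
    measurement rows.  When ``bifurcated`` every physical optode acts as
    both source and detector; co-located (d == s) pairs are excluded by
    default because their Rytov datum is degenerate.
    """

    sources: np.ndarray
    detectors: np.ndarray
    pair_list: tuple[tuple[int, int], ...]
    bifurcated: bool = False
    name: str = "custom"

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    @property
    def n_measurements(self) -> int:
        return len(self.pair_list)


def _all_pairs(n_det: int, n_src: int) -> tuple[tuple[int, int], ...]:
    return tuple((d, s) for d in range(n_det) for s in range(n_src))


def make_layout(
    variant: str,
    pitch: float | None = None,
    include_colocated: bool = False,
) -> OptodeLayout:
    """Build one of the standard optode geometries.

    Variants
    --------
    ``SD-I``
        5x5 grid of bifurcated optodes (default pitch 1 cm); every optode
        is both source and detector.
    ``SD-II``
        5x5 grid with sources and detectors alternating in a checkerboard
        (13 sources, 12 detectors).
    ``SD-III``
        SD-I minus one optode row (5x4), alternating roles.
    ``SD-IV``
        SD-I minus three rows (5x2), alternating roles.
    ``transrectal``
        Two rows 2 cm apart, nine sources and nine detectors alternating
        within each row; the closest optode separation (default 0.5 cm)
        is the within-row pitch.

    Parameters
    ----------
    pitch : float, optional
        Neighbour separation in cm.  Defaults: 1.0 for the SD grids,
        0.5 for the transrectal probe.
    include_colocated : bool
        For bifurcated layouts, keep the degenerate d == s pairs
        (25x25 = 625 rows for SD-I instead of 600).
    """
    variant = str(variant)
    if variant == "SD-I":
        p = 1.0 if pitch is None else float(pitch)
        if not p > 0:
            raise ValueError("pitch must be positive")
        pos = np.array([(i * p, j * p, 0.0) for j in range(5) for i in range(5)])
        pairs = tuple(
            (d, s)
            for d in range(25)
            for s in range(25)
            if include_colocated or d != s
        )
        return OptodeLayout(pos, pos, pairs, bifurcated=True, name=variant)

    if variant in ("SD-II", "SD-III", "SD-IV"):
        p = 1.0 if pitch is None else float(pitch)
        if not p > 0:
            raise ValueError("pitch must be positive")
        n_rows = {"SD-II": 5, "SD-III": 4, "SD-IV": 2}[variant]
        src, det = [], []
        for j in range(n_rows):
            for i in range(5):
                pt = (i * p, j * p, 0.0)
                (src if (i + j) % 2 == 0 else det).append(pt)
        src_a, det_a = np.array(src), np.array(det)
        return OptodeLayout(
            src_a, det_a, _all_pairs(len(det_a), len(src_a)), name=variant
        )

    if variant == "transrectal":
        p = 0.5 if pitch is None else float(pitch)
        if not p > 0:
            raise ValueError("pitch must be positive")
        row_sep = 2.0
        src, det = [], []
        for j, first in ((0, "s"), (1, "d")):
            for i in range(9):
                pt = (i * p, j * row_sep, 0.0)
                role = first if i % 2 == 0 else ("d" if first == "s" else "s")
                (src if role == "s" else det).append(pt)
        src_a, det_a = np.array(src), np.array(det)
        return OptodeLayout(
            src_a, det_a, _all_pairs(len(det_a), len(src_a)), name=variant
        )

    raise ValueError(f"unknown layout variant {variant!r}")


def standard_grid(variant: str, voxel_size: float = 0.2) -> VoxelGrid:
    """Conventional imaging volume for a layout variant.

    SD grids image a 4 x 4 x 2.5 cm volume directly under the 5x5
    footprint; the transrectal probe images 6 x 4 x 2.5 cm centred on
    the probe (origin shifted so the optodes sit in the middle).
    """
    h = float(voxel_size)
    nz = int(np.ceil(2.5 / h))
    if variant.startswith("SD"):
        n = int(round(4.0 / h))
        return make_grid((0.0, 0.0, 0.0), (n, n, nz), h)
    if variant == "transrectal":
        nx = int(round(6.0 / h))
        ny = int(round(4.0 / h))
        return make_grid((-1.0, -1.0, 0.0), (nx, ny, nz), h)
    raise ValueError(f"unknown layout variant {variant!r}")


def make_grid(
    origin: tuple[float, float, float],
    shape: tuple[int, int, int],
    voxel_size: float,
) -> VoxelGrid:
    """Create a :class:`VoxelGrid` (validation happens in the dataclass)."""
    return VoxelGrid(tuple(float(v) for v in origin), tuple(int(s) for s in shape), float(voxel_size))


# ---------------------------------------------------------------------------
# Green's functions


def _g_inf(r: np.ndarray, bg: OpticalBackground) -> np.ndarray:
    return np.exp(-bg.mu_eff * r) / (4.0 * np.pi * bg.D * r)


def _half_space_g(
    p1: np.ndarray, p2: np.ndarray, bg: OpticalBackground, min_dist: float = 0.0
) -> np.ndarray:
    """Vectorized semi-infinite-medium Green's function.

    p1: (..., 3), p2: (..., 3) broadcastable.  Image source mirrored
    across the extrapolated plane z = -z_b; distances below ``min_dist``
    are clamped (near-field regularization).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d_direct = np.linalg.norm(p1 - p2, axis=-1)
    mirror = p2.copy()
    mirror[..., 2] = -2.0 * bg.z_b - p2[..., 2]
    d_image = np.linalg.norm(p1 - mirror, axis=-1)
    if min_dist > 0:
        d_direct = np.maximum(d_direct, min_dist)
        d_image = np.maximum(d_image, min_dist)
    return _g_inf(d_direct, bg) - _g_inf(d_image, bg)


def greens_fn(r1, r2, bg: OpticalBackground) -> float:
    """CW fluence Green's function (1/cm^2) of the half-space z >= 0.

    G(r1, r2) = Ginf(|r1-r2|) - Ginf(|r1-r2*|) where r2* is the mirror
    of r2 across the extrapolated boundary z = -z_b and
    Ginf(r) = exp(-mu_eff r) / (4 pi D r).  Symmetric in its arguments.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.allclose(r1, r2):
        raise ValueError("greens_fn is singular at coincident points")
    return float(_half_space_g(r1, r2, bg))


# ---------------------------------------------------------------------------
# Sensing matrix


@dataclass
class SensingMatrix:
    """Dense Rytov sensitivity matrix.

    Rows are (detector, source) measurement pairs in ``layout.pair_list``
    order, columns are voxels in the grid's layer-major flat order.
    Entries are nonnegative: a positive absorption perturbation increases
    the Rytov datum -ln(phi/phi0).
    """

    values: np.ndarray
    layout: OptodeLayout
    grid: VoxelGrid
    bg: OpticalBackground
    row_map: tuple[tuple[int, int], ...] = field(repr=False, default=())
    col_map: np.ndarray | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.row_map:
            self.row_map = self.layout.pair_list
        if self.col_map is None:
            self.col_map = np.arange(self.grid.n_voxels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def layer_block(self, iz: int) -> np.ndarray:
        return self.values[:, self.grid.layer_slice(iz)]


def build_sensing_matrix(
    layout: OptodeLayout, grid: VoxelGrid, bg: OpticalBackground
) -> SensingMatrix:
    """Assemble the linearized CW absorption sensitivity matrix.

    Row (d, s), column k (voxel r_k):

        A[(d,s),k] = (h^3 / D) * G(r_s, r_k) G(r_k, r_d) / G(r_s, r_d)

    with sources buried at the effective depth z0 = 1/(mua+musp) and
    detectors on the surface.  The Rytov normalization by the unperturbed
    source-detector Green's function makes rows dimensionless sensitivities
    per unit absorption change.  Voxel-to-optode distances below h/2 are
    clamped to h/2.
    """
    h = grid.voxel_size
    centers = grid.centers()  # (n, 3)
    min_dist = h / 2.0

    src = np.asarray(layout.sources, dtype=float).copy()
    src[:, 2] = bg.z_0  # buried isotropic source
    det = np.asarray(layout.detectors, dtype=float)

    # (m, n) source-to-voxel and (q, n) voxel-to-detector weights
    g_sv = _half_space_g(src[:, None, :], centers[None, :, :], bg, min_dist)
    g_vd = _half_space_g(det[:, None, :], centers[None, :, :], bg, min_dist)
    g_sd = _half_space_g(src[:, None, :], det[None, :, :], bg, min_dist)  # (m, q)

    rows = np.empty((layout.n_measurements, grid.n_voxels))
    for r, (d, s) in enumerate(layout.pair_list):
        rows[r] = (h**3 / bg.D) * g_sv[s] * g_vd[d] / g_sd[s, d]
    np.maximum(rows, 0.0, out=rows)  # guard tiny negative round-off
    return SensingMatrix(rows, layout, grid, bg)
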