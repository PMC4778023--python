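"""Reconstruction quality metrics.

FWHM (half-maximum) segmentation of the reconstructed volume and the
standard localization/quantification scores against the known truth:
area ratio (AR) on a depth slice, volume ratio (VR), contrast ratio
(CR), FWHM-centroid depth, and percent quantification recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.measure import label

from .phantoms import ReconVolume

__all__ = [
    "QualityReport",
    "fwhm_mask",
    "n_fwhm_components",
    "area_ratio",
    "volume_ratio",
    "contrast_ratio",
    "centroid_depth",
    "recovery_pct",
    "evaluate",
]


@dataclass
class QualityReport:
    AR: float
    VR: float
    CR: float
    centroid_depth_cm: float
    recovery_pct: float
    n_components: int

    def to_dict(self) -> dict:
        return asdict(self)


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, ReconVolume) else np.asarray(v, dtype=float)


def fwhm_mask(recon: ReconVolume) -> np.ndarray:
    """Voxels at or above half the global maximum (flat boolean mask).

    An all-zero (or non-positive) volume yields an empty mask.
    """
    v = _values(recon)
    peak = v.max(initial=0.0)
    if peak <= 0:
        return np.zeros(v.shape, dtype=bool)
    return v >= 0.5 * peak


def n_fwhm_components(recon: ReconVolume) -> int:
    """Number of 26-connected components of the FWHM mask."""
    mask = recon.grid.to_volume(fwhm_mask(recon).astype(np.uint8))
    return int(label(mask, connectivity=3).max())


def _slice_index(grid, depth_cm: float) -> int:
    iz = int(np.floor((depth_cm - grid.origin[2]) / grid.voxel_size))
    if not 0 <= iz < grid.n_layers:
        raise ValueError(f"slice depth {depth_cm} cm outside grid")
    return iz


def area_ratio(recon: ReconVolume, truth: ReconVolume, slice_depth: float) -> float:
    """AR = FWHM area of the reconstruction over the true cross-section
    area, both counted on the depth slice containing ``slice_depth``."""
    if recon.grid != truth.grid:
        raise ValueError("reconstruction and truth grids differ")
    iz = _slice_index(recon.grid, slice_depth)
    sl = recon.grid.layer_slice(iz)
    true_area = int(np.count_nonzero(truth.values[sl]))
    if true_area == 0:
        raise ValueError("true object has zero area on the requested slice")
    rec_area = int(np.count_nonzero(fwhm_mask(recon)[sl]))
    return rec_area / true_area


def volume_ratio(recon: ReconVolume, truth: ReconVolume) -> float:
    """VR = FWHM volume over true object volume (voxel counts cancel h^3)."""
    true_vox = int(np.count_nonzero(_values(truth)))
    if true_vox == 0:
        raise ValueError("true object has zero volume")
    return int(np.count_nonzero(fwhm_mask(recon))) / true_vox


def contrast_ratio(recon: ReconVolume, truth_mask) -> float:
    """CR = mean reconstruction inside the true boundary over the mean
    outside it.  A background mean of exactly zero (perfect rejection)
    returns +inf."""
    roi = _values(truth_mask).astype(bool)
    v = _values(recon)
    if not roi.any():
        raise ValueError("empty ROI")
    if roi.all():
        raise ValueError("ROI covers the whole grid; no background")
    fg = float(v[roi].mean())
    bgm = float(v[~roi].mean())
    if bgm == 0.0:
        return math.inf
    return fg / bgm


def centroid_depth(recon: ReconVolume) -> float:
    """Intensity-weighted centroid depth (cm) over the FWHM mask."""
    mask = fwhm_mask(recon)
    if not mask.any():
        raise ValueError("empty FWHM mask; no reconstructed object")
    v = _values(recon)
    z = recon.grid.centers()[:, 2]
    w = v[mask]
    return float(np.sum(w * z[mask]) / np.sum(w))


def recovery_pct(recon: ReconVolume, truth: ReconVolume) -> float:
    """Quantification recovery: 100 x mean reconstructed contrast inside
    the true object over the true contrast."""
    t = _values(truth)
    roi = t > 0
    if not roi.any():
        raise ValueError("true object is empty")
    true_contrast = float(t[roi].mean())
    if true_contrast == 0:
        raise ValueError("zero true contrast")
    return 100.0 * float(_values(recon)[roi].mean()) / true_contrast


def evaluate(
    recon: ReconVolume, truth: ReconVolume, slice_depth: float | None = None
) -> QualityReport:
    """Full quality report against a voxelized truth.

    ``slice_depth`` defaults to the true object's intensity centroid
    depth (the conventional viewing plane).
    """
    t = _values(truth)
    roi = t > 0
    if slice_depth is None:
        z = truth.grid.centers()[:, 2]
        slice_depth = float(np.sum(t[roi] * z[roi]) / np.sum(t[roi]))
    return QualityReport(
        AR=area_ratio(recon, truth, slice_depth),
        VR=volume_ratio(recon, truth),
        CR=contrast_ratio(recon, roi),
        centroid_depth_cm=centroid_depth(recon),
        recovery_pct=recovery_pct(recon, truth),
        n_components=n_fwhm_components(recon),
    )
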