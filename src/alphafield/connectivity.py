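"""Seed-ROI functional connectivity of the default mode network.

Connectivity strength between the medial prefrontal cortex (mPFC) and the
posterior cingulate cortex (PCC) is the Fisher-z-transformed Spearman
correlation of the two sphere-ROI mean BOLD time courses; its tACS-sham
contrast of post-pre changes is the ΔΔ CONNECTIVITY readout.

Default ROI centers are the MNI coordinates mPFC (1, 55, -3) and
PCC (1, -61, 38) with 10 mm radius; synthetic cohorts ship their own ROI
specs matched to their grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from nibabel.affines import apply_affine
from scipy import stats as sp_stats

from .errors import AnalysisError, InputError
from .fusion import BOLDRun, VoxelMask, _check_same_grid

RHO_CLAMP = 1e-7


@dataclass
class RoiSpec:
    """A spherical region of interest in world (mm) coordinates."""

    label: str
    center: tuple[float, float, float]
    radius: float = 10.0

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        if len(self.center) != 3:
            raise InputError("center must be an (x, y, z) triple in mm")
        if self.radius <= 0:
            raise InputError("radius must be positive")


MPFC = RoiSpec("mPFC", (1.0, 55.0, -3.0))
PCC = RoiSpec("PCC", (1.0, -61.0, 38.0))


@dataclass
class ConnectivityValue:
    """Spearman rho and its Fisher-z transform for one run."""

    rho: float
    z: float


def sphere_mask(shape: tuple[int, int, int], affine: np.ndarray, roi: RoiSpec) -> VoxelMask:
    """Voxels whose center lies within ``roi.radius`` mm of the ROI center.

    The boundary is inclusive (distance <= radius).
    """
    affine = np.asarray(affine, dtype=float)
    ijk = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    world = apply_affine(affine, ijk.reshape(-1, 3))
    dist2 = ((world - np.asarray(roi.center)) ** 2).sum(axis=1)
    sel = (dist2 <= roi.radius**2).reshape(shape)
    if not sel.any():
        raise InputError(f"ROI {roi.label!r} does not intersect the grid")
    return VoxelMask(sel, affine)


def roi_series(bold: BOLDRun, mask: VoxelMask) -> np.ndarray:
    """Per-timepoint mean BOLD over the masked voxels."""
    _check_same_grid(bold.values.shape[:3], bold.affine,
                     mask.selected.shape, mask.affine, "BOLD and ROI mask")
    if mask.count == 0:
        raise InputError("empty ROI mask")
    return bold.values[mask.selected].mean(axis=0)


def fisherz_spearman(a: np.ndarray, b: np.ndarray) -> ConnectivityValue:
    """Spearman rank correlation with Fisher-z transform.

    Ties receive average ranks; |rho| is clamped to ``1 - 1e-7`` before
    atanh so perfectly monotone series yield a finite z of the right sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("series must be 1-D and of equal length")
    if a.size < 3:
        raise InputError("need at least 3 timepoints")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise AnalysisError("constant series has no rank correlation")
    rho = float(sp_stats.spearmanr(a, b).statistic)
    if abs(abs(rho) - 1.0) < 1e-12:  # roundoff on perfectly monotone pairs
        rho = float(np.sign(rho))
    z = float(np.arctanh(np.clip(rho, -(1 - RHO_CLAMP), 1 - RHO_CLAMP)))
    return ConnectivityValue(rho=rho, z=z)


def connectivity_contrast(
    z_post_tacs: float, z_pre_tacs: float, z_post_sham: float, z_pre_sham: float
) -> float:
    """ΔΔ CONNECTIVITY: (post - pre) under tACS minus (post - pre) under sham,
    on Fisher-z values."""
    vals = (z_post_tacs, z_pre_tacs, z_post_sham, z_pre_sham)
    if not all(np.isfinite(v) for v in vals):
        raise InputError("all four z values must be finite")
    return (z_post_tacs - z_pre_tacs) - (z_post_sham - z_pre_sham)
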