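"""EEG-informed fMRI fusion: alpha regressor, voxelwise GLM, dose masks.

The chain implemented here turns the band-limited alpha envelope of the
occipital EEG channels into a BOLD-scale regressor (canonical double-gamma
HRF convolution, TR-bin downsampling to the 0.5 Hz acquisition rate,
channel averaging), fits an ordinary least-squares GLM in every voxel,
averages the four pre/post t-maps per subject, and derives the two
subject-specific dose masks: the k most negatively alpha-coupled occipital
gray-matter voxels (MASK_alphaBOLD) and the k highest-field gray-matter
voxels (MASK_strong), whose mask-averaged electric-field magnitudes are the
EFIELD predictors of the regression model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from scipy.signal import fftconvolve

from .errors import AnalysisError, InputError
from .spectral import DEFAULT_CHANNELS, EEGRun, band_envelope

HRF_DURATION = 32.0  # seconds; kernel support of the double-gamma response


def _check_same_grid(shape_a, affine_a, shape_b, affine_b, what="volumes"):
    if tuple(shape_a) != tuple(shape_b):
        raise InputError(f"{what} have different grids: {tuple(shape_a)} vs {tuple(shape_b)}")
    if affine_a is not None and affine_b is not None:
        if not np.array_equal(np.asarray(affine_a), np.asarray(affine_b)):
            raise InputError(
                f"{what} have different affines:\n{np.asarray(affine_a)}\nvs\n{np.asarray(affine_b)}"
            )


@dataclass
class BOLDRun:
    """One 4-D BOLD run: ``values`` is ``(x, y, z, t)`` in arbitrary units."""

    values: np.ndarray
    tr: float
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 4:
            raise InputError(f"BOLD values must be 4-D, got shape {self.values.shape}")
        if self.tr <= 0:
            raise InputError("tr must be positive")
        if self.affine.shape != (4, 4):
            raise InputError("affine must be 4x4")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[-1]


@dataclass
class TMap:
    """3-D map of GLM t-statistics with residual degrees of freedom."""

    t: np.ndarray
    dof: int
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 3:
            raise InputError("t must be 3-D")
        if self.dof <= 0:
            raise InputError("dof must be positive")


@dataclass
class FieldMap:
    """3-D electric-field magnitude map in V/m."""

    magnitude: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.magnitude.ndim != 3:
            raise InputError("magnitude must be 3-D")
        if np.any(self.magnitude < 0):
            raise InputError("field magnitudes must be nonnegative")


@dataclass
class VoxelMask:
    """Boolean voxel selection on a 3-D grid."""

    selected: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 3:
            raise InputError("mask must be 3-D")

    @property
    def count(self) -> int:
        return int(self.selected.sum())

    def intersect(self, other: "VoxelMask") -> "VoxelMask":
        _check_same_grid(self.selected.shape, self.affine,
                         other.selected.shape, other.affine, "masks")
        return VoxelMask(self.selected & other.selected, self.affine)


def canonical_hrf(dt: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak value 1.

    Response gamma has mode 6 s, undershoot gamma mode 16 s with ratio 1/6
    (both rate 1 /s), over a ``duration``-second support.
    """
    if dt <= 0 or duration <= 0:
        raise InputError("dt and duration must be positive")
    t = np.arange(round(duration / dt)) * dt
    h = sp_stats.gamma.pdf(t, a=7.0) - sp_stats.gamma.pdf(t, a=17.0) / 6.0
    return h / h.max()


def warmup_volumes(tr: float, duration: float = HRF_DURATION) -> int:
    """Number of initial volumes still inside the HRF convolution warm-up.

    These volumes are retained by the GLM but flagged so sensitivity checks
    can drop them.
    """
    return math.ceil(duration / tr)


def hrf_bin_downsample(
    envelope: np.ndarray, fs: float, tr: float, n_volumes: int,
    duration: float = HRF_DURATION,
) -> np.ndarray:
    """Convolve envelope(s) with the canonical HRF and average per TR bin.

    ``envelope`` is ``(..., n_samples)`` at rate ``fs``; output is
    ``(..., n_volumes)``, volume ``i`` being the mean of the convolved
    signal over ``[i*tr, (i+1)*tr)``.
    """
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    spt = round(tr * fs)
    if abs(spt - tr * fs) > 1e-9:
        raise InputError("tr must be an integer number of EEG samples")
    needed = n_volumes * spt
    if env.shape[-1] < needed:
        raise InputError(
            f"EEG covers {env.shape[-1] / fs:.1f} s but the scan needs "
            f"{n_volumes * tr:.1f} s"
        )
    kernel = canonical_hrf(1.0 / fs, duration)
    conv = fftconvolve(env, kernel[None, :], axes=-1)[..., :needed]
    binned = conv.reshape(env.shape[0], n_volumes, spt).mean(axis=-1)
    return binned if np.asarray(envelope).ndim > 1 else binned[0]


def build_alpha_regressor(
    run: EEGRun,
    iaf: float,
    tr: float,
    n_volumes: int,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    halfwidth: float = 2.0,
) -> np.ndarray:
    """Alpha-envelope BOLD regressor for one run, length ``n_volumes``.

    Per channel: band-limited Hilbert envelope -> HRF convolution -> TR-bin
    averaging; the per-channel regressors are then averaged. The first
    :func:`warmup_volumes` samples carry convolution warm-up and are flagged
    for (optional) sensitivity analyses but retained.
    """
    env = band_envelope(run, iaf, channels=channels, halfwidth=halfwidth)
    binned = hrf_bin_downsample(env, run.sampling_rate, tr, n_volumes)
    return binned.mean(axis=0)


def voxelwise_glm(bold: BOLDRun, regressor: np.ndarray, drift_order: int = 1) -> TMap:
    """Per-voxel OLS of the BOLD series on the alpha regressor.

    The design matrix holds the regressor, an intercept, and Legendre-style
    polynomial drift terms up to ``drift_order`` on a [-1, 1] time axis.
    Returns the t-statistic of the regressor coefficient per voxel
    (negative alpha-BOLD coupling gives negative t) and the residual
    degrees of freedom ``T - (drift_order + 2)``.
    """
    reg = np.asarray(regressor, dtype=float)
    T = bold.n_volumes
    if reg.shape != (T,):
        raise InputError(f"regressor length {reg.shape} does not match {T} volumes")
    if np.ptp(reg) == 0:
        raise AnalysisError("constant regressor: design matrix is rank deficient")
    tax = np.linspace(-1.0, 1.0, T)
    X = np.column_stack([reg, np.ones(T)] + [tax**k for k in range(1, drift_order + 1)])
    dof = T - X.shape[1]
    if dof <= 0:
        raise AnalysisError("not enough volumes for the requested drift order")

    Y = bold.values.reshape(-1, T).T.astype(float)  # (T, V)
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / dof
    # zero-variance voxels (e.g. exactly constant synthetic background) get
    # t = 0 rather than 0/0; exactly-coupled noiseless voxels keep a huge
    # finite t from the float64 residual floor
    se = np.sqrt(np.maximum(sigma2, 1e-60) * xtx_inv[0, 0])
    t = B[0] / se
    return TMap(t.reshape(bold.values.shape[:3]), dof=dof, affine=bold.affine)


def average_tmaps(maps: list[TMap]) -> TMap:
    """Voxelwise arithmetic mean of t-maps on identical grids.

    By default the caller passes the four pre/post maps (both sessions) of
    one subject; the pooled map assumes the alpha-BOLD topography does not
    differ between sessions or runs. The combined map keeps the smallest
    per-map dof as a conservative bookkeeping value.
    """
    if not maps:
        raise InputError("no t-maps supplied")
    first = maps[0]
    for m in maps[1:]:
        _check_same_grid(first.t.shape, first.affine, m.t.shape, m.affine, "t-maps")
    t = np.mean([m.t for m in maps], axis=0)
    return TMap(t, dof=min(m.dof for m in maps), affine=first.affine)


def select_topk_mask(
    source: np.ndarray | TMap | FieldMap,
    restrict: VoxelMask,
    k: int,
    direction: str = "most-negative",
) -> VoxelMask:
    """Select the ``k`` most extreme voxels of ``source`` within ``restrict``.

    ``direction`` is ``"most-negative"`` (alpha-BOLD masks) or ``"largest"``
    (field-strength masks). Ties are broken by ascending linear voxel index,
    which makes the selection deterministic across platforms.
    """
    if isinstance(source, TMap):
        values, src_aff = source.t, source.affine
    elif isinstance(source, FieldMap):
        values, src_aff = source.magnitude, source.affine
    else:
        values, src_aff = np.asarray(source, dtype=float), None
    _check_same_grid(values.shape, src_aff, restrict.selected.shape, restrict.affine,
                     "source and restriction")
    if direction not in ("most-negative", "largest"):
        raise InputError(f"unknown direction {direction!r}")
    avail = restrict.count
    if not 0 < k <= avail:
        raise InputError(f"k = {k} voxels requested but the restriction has {avail}")
    idx = np.flatnonzero(restrict.selected.ravel())
    vals = values.ravel()[idx]
    key = vals if direction == "most-negative" else -vals
    order = np.argsort(key, kind="stable")  # stable: ties keep ascending index
    chosen = idx[order[:k]]
    sel = np.zeros(values.size, dtype=bool)
    sel[chosen] = True
    return VoxelMask(sel.reshape(values.shape), restrict.affine)


def mean_field(field: FieldMap, mask: VoxelMask) -> float:
    """Mask-averaged electric-field magnitude (the EFIELD dose), in V/m."""
    _check_same_grid(field.magnitude.shape, field.affine,
                     mask.selected.shape, mask.affine, "field map and mask")
    if mask.count == 0:
        raise InputError("empty mask")
    return float(field.magnitude[mask.selected].mean())
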