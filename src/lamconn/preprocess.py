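"""Time-point censoring and nuisance regression for paired contrast series.

Censoring drops an effective-TR pair whenever either constituent volume has a
motion-derivative Euclidean norm above 0.4 mm, an outlier fraction of at
least 10% of in-mask voxels, or is a dummy volume.  Nuisance regression then
removes, per voxel: six motion parameters and their derivatives, Legendre
polynomial drift up to fifth order, the mean ventricular CSF signal, and a
locally averaged white-matter regressor (ANATICOR-style).  Residuals are
normalized by the voxel's pre-regression temporal mean, so downstream
connectivity works on unit-free fluctuation series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.signal import fftconvolve

from .contrast import PairedSeries

logger = logging.getLogger(__name__)

__all__ = [
    "MotionTrace",
    "CensorMask",
    "censor",
    "outlier_fraction",
    "regress_nuisance",
    "regress_evoked",
    "legendre_basis",
]


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray  # (T, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must be (T, 6)")

    @property
    def n_volumes(self) -> int:
        return len(self.params)

    @property
    def derivative(self) -> np.ndarray:
        """Backward difference; first volume's derivative is zero by convention."""
        d = np.zeros_like(self.params)
        d[1:] = np.diff(self.params, axis=0)
        return d

    @property
    def enorm(self) -> np.ndarray:
        """Euclidean norm of the 6 motion derivatives per volume.

        Rotations in degrees are used numerically as mm-equivalents, the
        common convention for the 0.4 mm threshold.
        """
        return np.sqrt(np.sum(self.derivative**2, axis=1))


@dataclass
class CensorMask:
    """Which effective-TR pairs survive, and why the others were dropped."""

    keep: np.ndarray  # (P,) bool
    reasons: list  # per pair, set subset of {"dummy", "motion", "outlier"}

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.reasons) != len(self.keep):
            raise ValueError("reasons/keep length mismatch")

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.keep))


def legendre_basis(n_time: int, order: int = 5) -> np.ndarray:
    """Orthogonal polynomial drift basis, orders 0..order, columns unit-norm."""
    x = np.linspace(-1.0, 1.0, n_time)
    cols = [legendre.legval(x, np.eye(order + 1)[k]) for k in range(order + 1)]
    X = np.column_stack(cols)
    return X / np.linalg.norm(X, axis=0)


def outlier_fraction(
    data: np.ndarray,
    mask: np.ndarray,
    polynomial_order: int = 5,
    mad_factor: float = 4.5,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Per-volume fraction of in-mask voxels deviating from their polynomial trend.

    Each voxel's series is detrended with Legendre polynomials up to
    ``polynomial_order``; a voxel is flagged at time t when its residual
    exceeds ``mad_factor`` times the voxel's residual MAD.  Zero-variance
    voxels are never flagged.  Volumes marked in ``exclude`` (e.g. dummies)
    do not enter the trend fit or the MAD but still get a reported fraction.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    T = data.shape[-1]
    fit = np.ones(T, dtype=bool) if exclude is None else ~np.asarray(exclude, dtype=bool)
    if int(fit.sum()) < polynomial_order + 2:
        raise ValueError("need at least polynomial_order + 2 time points")
    Y = data[mask].T  # (T, n_vox)
    X = legendre_basis(T, polynomial_order)
    beta = np.linalg.lstsq(X[fit], Y[fit], rcond=None)[0]
    resid = Y - X @ beta
    rf = resid[fit]
    mad = np.median(np.abs(rf - np.median(rf, axis=0)), axis=0)
    flagged = np.abs(resid) > mad_factor * mad
    # a voxel whose MAD is zero up to float rounding of the trend fit is
    # constant, not an outlier source
    scale = np.median(np.abs(Y[fit]), axis=0)
    flagged[:, mad <= 1e-9 * np.maximum(scale, 1.0)] = False
    return flagged.sum(axis=1) / Y.shape[1]


def censor(
    motion: MotionTrace,
    series: PairedSeries,
    enorm_thresh: float = 0.4,
    outlier_frac: float = 0.10,
    volume_outlier_frac: np.ndarray | None = None,
    dummy_volumes: np.ndarray | None = None,
) -> CensorMask:
    """Censor pairs by motion, outlier fraction, and dummy status.

    ``volume_outlier_frac`` is the per-original-volume outlier fraction
    (e.g. from :func:`outlier_fraction` on the raw run); a pair is censored
    when either of its volumes has enorm > ``enorm_thresh``, outlier
    fraction >= ``outlier_frac`` (inclusive), or is flagged as a dummy.
    """
    enorm = motion.enorm
    P = series.n_pairs
    keep = np.ones(P, dtype=bool)
    reasons: list[set] = [set() for _ in range(P)]
    for p in range(P):
        vols = (int(series.nulled_indices[p]), int(series.control_indices[p]))
        for v in vols:
            if dummy_volumes is not None and dummy_volumes[v]:
                reasons[p].add("dummy")
            if v < len(enorm) and enorm[v] > enorm_thresh:
                reasons[p].add("motion")
            if volume_outlier_frac is not None and volume_outlier_frac[v] >= outlier_frac:
                reasons[p].add("outlier")
        if reasons[p]:
            keep[p] = False
    if not np.any(keep):
        raise ValueError("no usable data: all pairs censored")
    logger.info("censoring kept %d of %d pairs", int(keep.sum()), P)
    return CensorMask(keep=keep, reasons=reasons)


def _pair_motion(motion: MotionTrace, series: PairedSeries) -> np.ndarray:
    """Motion parameters at pair granularity: mean of the two constituent volumes."""
    p = motion.params
    return 0.5 * (p[series.nulled_indices] + p[series.control_indices])


def _design_matrix(
    motion_pairs: np.ndarray,
    n_time: int,
    keep: np.ndarray,
    extra: list[np.ndarray],
    poly_order: int,
) -> np.ndarray:
    deriv = np.zeros_like(motion_pairs)
    deriv[1:] = np.diff(motion_pairs, axis=0)
    cols = [legendre_basis(n_time, poly_order), motion_pairs, deriv] + [
        np.asarray(e, dtype=float).reshape(n_time, -1) for e in extra
    ]
    X = np.column_stack(cols)
    return X


def _drop_collinear(Xk: np.ndarray) -> np.ndarray:
    """Return Xk with collinear columns removed (rank-revealing QR via pivoted
    least squares on the Gram matrix)."""
    rank = np.linalg.matrix_rank(Xk)
    if rank == Xk.shape[1]:
        return Xk
    warnings.warn("rank-deficient nuisance design; dropping collinear columns")
    keep_cols: list[int] = []
    for j in range(Xk.shape[1]):
        trial = Xk[:, keep_cols + [j]]
        if np.linalg.matrix_rank(trial) == len(keep_cols) + 1:
            keep_cols.append(j)
    return Xk[:, keep_cols]


def regress_nuisance(
    series: PairedSeries,
    motion: MotionTrace,
    csf_mask: np.ndarray,
    wm_mask: np.ndarray,
    censor_mask: CensorMask,
    gm_mask: np.ndarray | None = None,
    poly_order: int = 5,
    wm_radius: float = 15.0,
) -> np.ndarray:
    """Remove nuisance structure from the paired contrast series.

    Fits, per voxel over kept pairs only: Legendre drift (orders
    0..``poly_order``), six pair-level motion parameters and their
    derivatives, the mean CSF signal, and the mean raw white-matter signal
    within ``wm_radius`` mm of the voxel (local white-matter regressor).
    Residuals are divided by the voxel's pre-regression mean over kept pairs.

    Returns a 4D array shaped like ``series.vaper`` with censored pairs set
    to NaN; voxels with nonpositive mean are entirely NaN.
    """
    data = series.vaper
    shape3 = data.shape[:3]
    keep = censor_mask.keep
    Tk = int(keep.sum())
    if Tk < poly_order + 2:
        raise ValueError("too few kept pairs for the requested polynomial order")
    analysis_mask = np.asarray(gm_mask, dtype=bool) if gm_mask is not None else np.ones(shape3, bool)

    # global regressors on the kept grid
    csf_sig = np.nanmean(data[np.asarray(csf_mask, bool)], axis=0)
    motion_pairs = _pair_motion(motion, series)
    X = _design_matrix(motion_pairs, series.n_pairs, keep, [csf_sig], poly_order)
    Xk = X[keep]
    if not np.all(np.isfinite(Xk)):
        raise ValueError("nuisance regressors contain non-finite values")
    Xk = _drop_collinear(Xk)

    vox = np.array(np.where(analysis_mask)).T  # (n_vox, 3) voxel indices
    Y = data[analysis_mask].T[keep]  # (Tk, n_vox)
    mu = np.nanmean(Y, axis=0)
    good = np.isfinite(mu) & (mu > 0)

    # shared projection
    beta, *_ = np.linalg.lstsq(Xk, np.nan_to_num(Y), rcond=None)
    R = Y - Xk @ beta

    # local white-matter regressor: mean raw vaper signal of WM voxels within
    # wm_radius mm of each analysis voxel, computed as a spherical-kernel
    # convolution, residualized against the shared design, then projected out
    wm = np.asarray(wm_mask, bool)
    if wm.any():
        vsize = (
            np.sqrt(np.sum(series.affine[:3, :3] ** 2, axis=0))
            if series.affine is not None
            else np.ones(3)
        )
        rad = np.ceil(wm_radius / vsize).astype(int)
        grids = np.meshgrid(
            *[np.arange(-r, r + 1) * s for r, s in zip(rad, vsize)], indexing="ij"
        )
        kernel = ((grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= wm_radius**2).astype(float)
        counts = np.round(fftconvolve(wm.astype(float), kernel, mode="same"))
        counts = np.maximum(counts, 0.0)[analysis_mask]  # (n_vox,)
        Wdat = np.where(wm[..., None], np.nan_to_num(data), 0.0)
        kp = np.where(keep)[0]
        Wloc = np.empty((Tk, len(vox)))
        for i, t in enumerate(kp):
            Wloc[i] = fftconvolve(Wdat[..., t], kernel, mode="same")[analysis_mask]
        Wloc /= np.maximum(counts, 1.0)
        Wres = Wloc - Xk @ np.linalg.lstsq(Xk, Wloc, rcond=None)[0]
        num = np.einsum("tj,tj->j", R, Wres)
        den = np.einsum("tj,tj->j", Wres, Wres)
        usable = good & (counts > 0) & (den > 1e-12)
        coef = np.where(usable, num / np.where(den > 1e-12, den, 1.0), 0.0)
        R -= Wres * coef

    R /= np.where(good, mu, np.nan)
    R[:, ~good] = np.nan

    out = np.full(data.shape, np.nan)
    sub = np.full((len(vox), series.n_pairs), np.nan)
    sub[:, keep] = R.T
    out[analysis_mask] = sub
    return out


def regress_evoked(
    values: np.ndarray,
    evoked: np.ndarray,
    region_mask: np.ndarray,
) -> np.ndarray:
    """Residualize laminar series against a shared evoked response.

    ``values`` is (vertex, depth, time); within ``region_mask`` (per-vertex
    bool) each series is residualized against [constant, evoked]; outside the
    mask data are returned unchanged.  A zero-variance regressor is a no-op
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    evoked = np.asarray(evoked, dtype=float).ravel()
    region_mask = np.asarray(region_mask, dtype=bool)
    out = values.copy()
    if not np.any(region_mask):
        return out
    if values.shape[-1] != len(evoked):
        raise ValueError("evoked regressor length must match time axis")
    e = evoked - evoked.mean()
    denom = e @ e
    if denom <= 1e-30:
        warnings.warn("evoked regressor has zero variance; skipping regression")
        return out
    Y = values[region_mask].reshape(-1, len(evoked))  # (n_series, T)
    finite = np.all(np.isfinite(Y), axis=1)
    Z = Y[finite]
    Z = Z - Z.mean(axis=1, keepdims=True)
    Z = Z - np.outer(Z @ e / denom, e)
    Y[finite] = Z
    out[region_mask] = Y.reshape(values[region_mask].shape)
    return out
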