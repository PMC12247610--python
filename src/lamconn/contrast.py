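"""Contrast construction from interleaved blood-nulled / control acquisitions.

The functional acquisition alternates between a blood-signal-suppressed
("nulled") volume and an unprepared control volume.  Dynamic subtraction of
the nulled from the control volume isolates the intravascular
(blood-volume/perfusion weighted) signal, and dividing by the control volume
cancels the common multiplicative T2*-weighted (BOLD) factor:

    vaper[v, t] = (C[v, t] - N[v, t]) / C[v, t]

The control series itself is retained as a conventional BOLD signal.  The
same sequence with a magnetization-transfer preparation yields the
anatomical contrast (ctrl - mt) / mt, which is bright where the
macromolecular proton fraction is high (white > gray matter).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeSeries",
    "PairedSeries",
    "split_conditions",
    "compute_vaper",
    "compute_mt_anatomical",
    "effective_timing",
]

NULLED = "nulled"
CONTROL = "control"
MT = "mt"
MT_CONTROL = "mt_control"


@dataclass
class VolumeSeries:
    """A 4D acquisition: (X, Y, Z, T) data with a per-volume condition schedule."""

    data: np.ndarray  # (X, Y, Z, T)
    affine: np.ndarray  # (4, 4) voxel -> mm
    volume_tr: float  # seconds
    schedule: list  # per-volume condition labels
    te: float = 0.020  # seconds, metadata only
    dummy_flags: np.ndarray | None = None  # per-volume bool
    orig_indices: np.ndarray | None = None  # indices into the original run

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (X, Y, Z, T)")
        if self.volume_tr <= 0:
            raise ValueError("volume_tr must be positive")
        self.schedule = list(self.schedule)
        if len(self.schedule) != self.data.shape[3]:
            raise ValueError("schedule length must equal the number of volumes")
        if self.dummy_flags is None:
            self.dummy_flags = np.zeros(self.n_volumes, dtype=bool)
        else:
            self.dummy_flags = np.asarray(self.dummy_flags, dtype=bool)
            if len(self.dummy_flags) != self.n_volumes:
                raise ValueError("dummy_flags length must equal the number of volumes")
        if self.orig_indices is None:
            self.orig_indices = np.arange(self.n_volumes)
        else:
            self.orig_indices = np.asarray(self.orig_indices, dtype=int)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt(np.sum(self.affine[:3, :3] ** 2, axis=0))

    def subset(self, idx: np.ndarray) -> "VolumeSeries":
        idx = np.asarray(idx, dtype=int)
        return VolumeSeries(
            data=self.data[..., idx],
            affine=self.affine,
            volume_tr=self.volume_tr,
            schedule=[self.schedule[i] for i in idx],
            te=self.te,
            dummy_flags=self.dummy_flags[idx],
            orig_indices=self.orig_indices[idx],
        )


@dataclass
class PairedSeries:
    """Nulled/control volumes combined into effective-TR pairs.

    ``vaper`` is the unitless dynamic-division contrast, ``bold`` the control
    volumes.  ``control_indices``/``nulled_indices`` point back at the
    original run so pair-granularity censoring can consult per-volume
    statistics; ``pair_times`` is the midpoint of each pair in seconds.
    """

    vaper: np.ndarray  # (X, Y, Z, P)
    bold: np.ndarray  # (X, Y, Z, P)
    effective_tr: float
    control_indices: np.ndarray
    nulled_indices: np.ndarray
    pair_times: np.ndarray
    affine: np.ndarray | None = None
    n_nonpositive_control: int = 0

    @property
    def n_pairs(self) -> int:
        return self.vaper.shape[3]


def effective_timing(volume_tr: float) -> float:
    """Effective sampling interval of the paired contrast: one nulled plus
    one control volume, i.e. twice the volume TR."""
    if volume_tr <= 0:
        raise ValueError("volume_tr must be positive")
    return 2.0 * volume_tr


def split_conditions(series: VolumeSeries) -> tuple[VolumeSeries, VolumeSeries]:
    """Split an interleaved run into its nulled and control sub-series.

    Dummy volumes are excluded; temporal order and original volume indices
    are preserved.  If the two conditions have unequal counts, both are
    truncated to the shorter one with a warning.
    """
    sched = np.array(series.schedule)
    keep = ~series.dummy_flags
    n_idx = np.where((sched == NULLED) & keep)[0]
    c_idx = np.where((sched == CONTROL) & keep)[0]
    if len(n_idx) == 0 or len(c_idx) == 0:
        raise ValueError("schedule must contain both nulled and control volumes")
    n = min(len(n_idx), len(c_idx))
    if len(n_idx) != len(c_idx):
        warnings.warn(
            f"unequal condition counts ({len(n_idx)} nulled, {len(c_idx)} control); "
            f"truncating to {n} pairs"
        )
    return series.subset(n_idx[:n]), series.subset(c_idx[:n])


def compute_vaper(
    control: VolumeSeries,
    nulled: VolumeSeries,
    mask: np.ndarray | None = None,
) -> PairedSeries:
    """Dynamic subtraction + division contrast from paired volumes.

    Each nulled volume is paired with the temporally nearest control volume
    of its interleave cycle (the k-th nulled with the k-th control, whichever
    condition leads).  Positive values indicate blood-signal suppression.
    Nonpositive control values inside the mask are set missing (NaN) and
    counted.
    """
    if control.n_volumes != nulled.n_volumes:
        raise ValueError("control and nulled series must have equal volume counts")
    C = control.data
    N = nulled.data
    bad = C <= 0
    if mask is not None:
        bad = bad & mask[..., None].astype(bool)
    n_bad = int(np.sum(bad))
    if n_bad:
        frac = n_bad / bad.size
        logger.warning("%d nonpositive control values (%.3g%%) set missing", n_bad, 100 * frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaper = (C - N) / C
    vaper[bad] = np.nan
    vaper[~np.isfinite(vaper)] = np.nan
    tr = control.volume_tr
    times = 0.5 * (control.orig_indices + nulled.orig_indices) * tr
    return PairedSeries(
        vaper=vaper,
        bold=C.copy(),
        effective_tr=effective_timing(tr),
        control_indices=control.orig_indices.copy(),
        nulled_indices=nulled.orig_indices.copy(),
        pair_times=times,
        affine=control.affine,
        n_nonpositive_control=n_bad,
    )


def pair_series(series: VolumeSeries, mask: np.ndarray | None = None) -> PairedSeries:
    """Convenience wrapper: split an interleaved run and compute the contrast."""
    nulled, control = split_conditions(series)
    return compute_vaper(control, nulled, mask=mask)


def compute_mt_anatomical(ctrl_mean: np.ndarray, mt_mean: np.ndarray) -> np.ndarray:
    """Magnetization-transfer anatomical contrast (ctrl - mt) / mt.

    Inputs are mean volumes over the non-censored volumes of each condition.
    Nonpositive MT values yield missing voxels.
    """
    ctrl_mean = np.asarray(ctrl_mean, dtype=float)
    mt_mean = np.asarray(mt_mean, dtype=float)
    if ctrl_mean.shape != mt_mean.shape:
        raise ValueError("mean volumes must have the same shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (ctrl_mean - mt_mean) / mt_mean
    out[mt_mean <= 0] = np.nan
    return out
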