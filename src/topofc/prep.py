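"""ROI-signal cleaning: volume dropping, detrending, band-pass, confound regression.

The chain mirrors standard resting-state practice at the region-signal level:
drop the first volumes (scanner equilibration), remove each region's linear
trend, band-pass to 0.01-0.08 Hz (zero-phase Butterworth), then regress out
nuisance signals (white matter, CSF, 24 motion parameters) by least squares.
The mean global signal is deliberately not regressed. A motion-exclusion rule
flags subjects whose head motion exceeds 1.5 mm translation or 1.5 deg rotation
on any axis (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import SubjectTimeSeries

__all__ = [
    "ConfoundSet",
    "MotionSummary",
    "drop_initial_volumes",
    "detrend_linear",
    "bandpass",
    "regress_confounds",
    "assess_motion",
    "friston24",
    "preprocess",
]

BUTTER_ORDER = 2  # per pass; applied forward-backward, so effective order 4


@dataclass
class ConfoundSet:
    """Nuisance regressors: a (T, k) matrix plus column labels."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if mat.ndim != 2:
            raise ValueError("confound matrix must be 2-D")
        self.matrix = mat
        if not self.labels:
            self.labels = [f"confound_{i}" for i in range(mat.shape[1])]
        if len(self.labels) != mat.shape[1]:
            raise ValueError("label count does not match confound columns")

    @property
    def n_confounds(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def empty(cls, n_timepoints: int) -> "ConfoundSet":
        return cls(matrix=np.empty((n_timepoints, 0)), labels=[])


@dataclass(frozen=True)
class MotionSummary:
    """Per-subject head-motion extrema and the exclusion decision."""

    max_translation_mm: np.ndarray
    max_rotation_deg: np.ndarray
    excluded: bool


def drop_initial_volumes(ts: SubjectTimeSeries, k: int = 10) -> SubjectTimeSeries:
    """Remove the first ``k`` volumes (default 10, e.g. 185 -> 175)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_timepoints:
        raise ValueError(f"cannot drop {k} volumes from a {ts.n_timepoints}-volume series")
    return ts.with_values(ts.values[k:], n_dropped=ts.n_dropped + k)


def detrend_linear(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Remove each region's least-squares linear trend (and mean)."""
    if ts.n_timepoints < 3:
        raise ValueError("detrending needs at least 3 time points")
    t = np.arange(ts.n_timepoints, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ beta)


def bandpass(ts: SubjectTimeSeries, low: float = 0.01, high: float = 0.08) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass (default 0.01-0.08 Hz).

    A second-order Butterworth applied forward and backward (``sosfiltfilt``),
    giving zero phase shift — phase distortion would alter Pearson
    correlations — and a monotone amplitude response. The DC component lies in
    the stop band and is removed.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyquist} Hz")
    sos = signal.butter(BUTTER_ORDER, [low, high], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return ts.with_values(filtered)


def regress_confounds(ts: SubjectTimeSeries, confounds: ConfoundSet) -> SubjectTimeSeries:
    """Residualize every region on the confounds (intercept always included).

    The output is orthogonal to every confound column. An empty confound set
    reduces to mean-centering. Rank-deficient designs are rejected.
    """
    if confounds.matrix.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confounds have {confounds.matrix.shape[0]} rows but series has {ts.n_timepoints}"
        )
    design = np.column_stack([np.ones(ts.n_timepoints), confounds.matrix])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("confound design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ beta)


def friston24(params: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body motion parameters to the 24-parameter set.

    Columns: p, p^2, p(t-1), p(t-1)^2 for each of the 6 parameters, with the
    lagged rows zero-padded at t = 0.
    """
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, p**2, lag, lag**2])


def assess_motion(params: np.ndarray, trans_mm: float = 1.5, rot_deg: float = 1.5) -> MotionSummary:
    """Apply the head-motion exclusion rule to a (T, 6) motion table.

    Columns 0-2 are translations in mm, 3-5 rotations in degrees. A subject is
    excluded iff any |translation| exceeds ``trans_mm`` or any |rotation|
    exceeds ``rot_deg`` — strictly greater, so a value exactly at the threshold
    is retained.
    """
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion table must have 6 columns (3 translations mm, 3 rotations deg)")
    if not np.all(np.isfinite(p)):
        raise ValueError("motion table contains non-finite values")
    max_t = np.abs(p[:, :3]).max(axis=0)
    max_r = np.abs(p[:, 3:]).max(axis=0)
    excluded = bool(np.any(max_t > trans_mm) or np.any(max_r > rot_deg))
    return MotionSummary(max_translation_mm=max_t, max_rotation_deg=max_r, excluded=excluded)


def preprocess(
    ts: SubjectTimeSeries,
    drop: int = 10,
    low: float = 0.01,
    high: float = 0.08,
    confounds: ConfoundSet | None = None,
) -> SubjectTimeSeries:
    """Fixed cleaning chain: drop -> detrend -> band-pass -> confound regression."""
    out = drop_initial_volumes(ts, drop) if drop else ts
    out = detrend_linear(out)
    out = bandpass(out, low=low, high=high)
    if confounds is None:
        confounds = ConfoundSet.empty(out.n_timepoints)
    return regress_confounds(out, confounds)
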