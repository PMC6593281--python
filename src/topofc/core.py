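"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SubjectTimeSeries", "SparsityGrid", "default_grid"]


@dataclass
class SubjectTimeSeries:
    """One subject's ROI signal matrix.

    Parameters
    ----------
    values : (T, N) float array
        BOLD-like signals, rows are time points, columns are regions.
    tr_seconds : float
        Repetition time in seconds (sampling interval of the rows).
    subject_id : str
        Identifier used in manifests and error messages.
    n_dropped : int
        Number of initial volumes already removed from the start of the scan.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    subject_id: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T, N) array")
        if self.values.shape[0] < 2:
            raise ValueError("time series needs at least 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in series {self.subject_id!r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, *, n_dropped: int | None = None) -> "SubjectTimeSeries":
        """Copy of this series with new signal values (metadata preserved)."""
        new = replace(self, values=values)
        if n_dropped is not None:
            new.n_dropped = n_dropped
        return new


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered grid of sparsity (edge-density) thresholds.

    The default grid spans 0.05 to 0.5 in steps of 0.01 — 46 values — so that
    metric curves summarize topology over a wide, toolbox-conventional range of
    network densities rather than at one arbitrary threshold.
    """

    values: np.ndarray = field(default_factory=lambda: _default_values())

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("grid must be a non-empty 1-D sequence")
        if np.any(vals <= 0) or np.any(vals >= 1):
            raise ValueError("sparsity values must lie in (0, 1)")
        if vals.size > 1 and np.any(np.diff(vals) <= 0):
            raise ValueError("sparsity values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)


def _default_values() -> np.ndarray:
    return np.round(np.linspace(0.05, 0.50, 46), 10)


def default_grid() -> SparsityGrid:
    """The 46-point grid 0.05, 0.06, ..., 0.50."""
    return SparsityGrid()
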