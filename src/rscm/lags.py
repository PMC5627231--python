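"""Peak-time lags, depletion times and lag-aligned phase correlations.

The regulatory cascade resource -> transcript -> enzyme responds to a
substrate pulse with a delay at each stage.  The lag between two stages is
defined operationally as the difference between the times at which their
simulated profiles attain their global maxima.  Depletion times locate when
a nutrient is effectively exhausted; lag-aligned correlations quantify how
linearly two stages track each other once the delay is removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DomainError
from .simulate import Trajectory

__all__ = [
    "NOT_DEPLETED",
    "InconclusivePeakError",
    "InsufficientOverlapError",
    "LagTable",
    "peak_time",
    "lag_table",
    "depletion_time",
    "align_and_correlate",
    "write_lag_report",
]

#: Sentinel returned when a series never crosses the depletion threshold.
NOT_DEPLETED = math.inf


class InconclusivePeakError(RuntimeError):
    """A series is still rising at the end of the trajectory."""

    def __init__(self, series: str):
        super().__init__(f"series {series!r} peaks at the horizon; "
                         "extend the simulation to resolve its maximum")
        self.series = series


class InsufficientOverlapError(ValueError):
    """Shifted series overlap on fewer than the minimum number of points."""


@dataclass(frozen=True)
class LagTable:
    """Peak times (days) of the six regulatory series and their lags.

    ``lag_RT`` is transcript peak minus resource peak, ``lag_TE`` enzyme peak
    minus transcript peak, and ``lag_RE = lag_RT + lag_TE`` exactly.  Values
    are kept at the trajectory's grid resolution; rounding to the 0.1-day
    reporting resolution happens in :meth:`to_frame`.
    """

    t_peak_rho1: float
    t_peak_tau1: float
    t_peak_e1: float
    t_peak_rho2: float
    t_peak_tau2: float
    t_peak_e2: float

    @property
    def lag_RT1(self) -> float:
        return self.t_peak_tau1 - self.t_peak_rho1

    @property
    def lag_TE1(self) -> float:
        return self.t_peak_e1 - self.t_peak_tau1

    @property
    def lag_RE1(self) -> float:
        return self.lag_RT1 + self.lag_TE1

    @property
    def lag_RT2(self) -> float:
        return self.t_peak_tau2 - self.t_peak_rho2

    @property
    def lag_TE2(self) -> float:
        return self.t_peak_e2 - self.t_peak_tau2

    @property
    def lag_RE2(self) -> float:
        return self.lag_RT2 + self.lag_TE2

    def lag(self, kind: str, pathway: int) -> float:
        """Look up a lag by kind ('RT', 'TE' or 'RE') and pathway (1 or 2)."""
        return getattr(self, f"lag_{kind}{pathway}")

    def to_frame(self, resolution: float = 0.1) -> pd.DataFrame:
        """Long-format report, values rounded to ``resolution`` days."""
        rows = []
        for i in (1, 2):
            rows.append(("t_peak_rho", i, getattr(self, f"t_peak_rho{i}")))
            rows.append(("t_peak_tau", i, getattr(self, f"t_peak_tau{i}")))
            rows.append(("t_peak_e", i, getattr(self, f"t_peak_e{i}")))
            for kind in ("RT", "TE", "RE"):
                rows.append((f"lag_{kind}", i, self.lag(kind, i)))
        df = pd.DataFrame(rows, columns=["quantity", "pathway", "value_days"])
        df["value_days"] = (df["value_days"] / resolution).round() * resolution
        return df


def peak_time(times: np.ndarray, values: np.ndarray) -> float:
    """Time of the global maximum of a sampled series.

    Ties are broken to the earliest time (``argmax`` returns the first
    maximal index).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0 or times.shape != values.shape:
        raise DomainError("times and values must be non-empty and equally long")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise DomainError("times must be strictly increasing")
    return float(times[int(np.argmax(values))])


def lag_table(traj: Trajectory) -> LagTable:
    """Peak times and pairwise lags of the six regulatory series.

    Raises :class:`InconclusivePeakError` if any series attains its maximum
    at the final grid point, i.e. is still rising when the simulation ends.
    """
    peaks = {}
    for name in ("rho1", "tau1", "e1", "rho2", "tau2", "e2"):
        t = peak_time(traj.times, traj.series(name))
        if t >= traj.times[-1]:
            raise InconclusivePeakError(name)
        peaks[name] = t
    return LagTable(
        t_peak_rho1=peaks["rho1"], t_peak_tau1=peaks["tau1"], t_peak_e1=peaks["e1"],
        t_peak_rho2=peaks["rho2"], t_peak_tau2=peaks["tau2"], t_peak_e2=peaks["e2"],
    )


def depletion_time(
    times: np.ndarray,
    values: np.ndarray,
    fraction: float = 0.01,
    reference: str = "auto",
) -> float:
    """First time after the series' maximum that it falls below a threshold.

    The threshold is ``fraction`` times a reference level: the initial value
    for species present at t=0, the global maximum for transient species that
    start at zero (``reference='auto'``; 'initial' and 'max' force either).
    Crossing times are linearly interpolated between grid points.  Returns
    :data:`NOT_DEPLETED` (infinity) if the threshold is never crossed.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if not 0.0 < fraction < 1.0:
        raise DomainError(f"fraction must lie in (0, 1), got {fraction}")
    if times.size == 0 or times.shape != values.shape:
        raise DomainError("times and values must be non-empty and equally long")
    vmax = float(values.max())
    if vmax <= 0:
        raise DomainError("series never attains a positive value")
    if reference == "auto":
        # species already present at t=0 are referenced to their initial
        # level; transient species (start at or near zero) to their maximum
        ref = float(values[0]) if values[0] > fraction * vmax else vmax
    elif reference == "initial":
        ref = float(values[0])
    elif reference == "max":
        ref = vmax
    else:
        raise DomainError(f"unknown reference {reference!r}")
    if ref <= 0:
        raise DomainError("reference level is not positive")
    threshold = fraction * ref
    i_max = int(np.argmax(values))
    below = np.nonzero(values[i_max:] < threshold)[0]
    if below.size == 0:
        return NOT_DEPLETED
    j = i_max + int(below[0])
    if j == 0:
        return float(times[0])
    # linear interpolation on the bracketing segment
    t0, t1 = times[j - 1], times[j]
    v0, v1 = values[j - 1], values[j]
    if v0 == v1:
        return float(t1)
    return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))


def align_and_correlate(
    series_a: np.ndarray,
    series_b: np.ndarray,
    lag: float,
    grid_step: float,
    min_overlap: int = 10,
) -> float:
    """Pearson correlation of two series after removing a known delay.

    ``series_b`` is shifted *earlier* by ``lag`` days (it is the delayed
    responder), both series are truncated to the overlapping window, and the
    Pearson correlation coefficient of the aligned pair is returned.  The
    series must share a uniform grid of spacing ``grid_step``; the shift is
    rounded to the nearest whole number of grid steps.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("series must be one-dimensional and equally long")
    if grid_step <= 0:
        raise DomainError(f"grid_step must be > 0, got {grid_step}")
    k = int(round(lag / grid_step))
    if abs(k) >= a.size:
        raise InsufficientOverlapError(
            f"lag of {lag} d leaves no overlap on a series of {a.size} points")
    if k >= 0:
        a_al, b_al = a[: a.size - k], b[k:]
    else:
        a_al, b_al = a[-k:], b[: a.size + k]
    if a_al.size < min_overlap:
        raise InsufficientOverlapError(
            f"aligned overlap of {a_al.size} points is below the minimum {min_overlap}")
    return float(np.corrcoef(a_al, b_al)[0, 1])


def write_lag_report(table: LagTable, path: str | Path) -> None:
    """Write the lag table as tab-separated text at 0.1-day resolution."""
    table.to_frame().to_csv(path, sep="\t", index=False)
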