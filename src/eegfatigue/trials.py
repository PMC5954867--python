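"""Phase-segmented linear regression of trial series.

Learning-curve metrics (errors, completion time, subjective fatigue)
over repeated trials typically show distinct phases: rapid improvement
while the task is learned, a plateau, then deterioration as fatigue
builds.  Each phase is summarized by an ordinary-least-squares line
``value = intercept + slope * trial`` with its R².  Segmentation is
either at user-supplied breakpoints (each breakpoint starts a new
phase) or automatic: an exhaustive scan over breakpoint placements
minimizing the total sum of squared errors, with a minimum phase
length of 3 trials, ties broken toward fewer phases and then earlier
breakpoints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PhaseFit", "fit_phase", "segment_phases", "SegmentedTrendRegressor"]


@dataclass
class PhaseFit:
    """OLS summary of one phase (1-based inclusive trial range)."""

    start_trial: int
    end_trial: int
    slope: float
    intercept: float
    r_squared: float
    n: int
    sse: float = 0.0

    def predict(self, trials) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(trials, dtype=float)


def _coerce_series(series, values=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept (trials, values) arrays or a DataFrame with a ``trial``
    column plus one value column."""
    if values is not None:
        t = np.asarray(series, dtype=float)
        y = np.asarray(values, dtype=float)
    elif isinstance(series, pd.DataFrame):
        if "trial" not in series.columns:
            raise ValueError("trial series DataFrame needs a 'trial' column")
        value_cols = [c for c in series.columns if c != "trial"]
        if len(value_cols) != 1:
            raise ValueError(
                f"expected exactly one value column, got {value_cols}; "
                "select the metric first"
            )
        t = series["trial"].to_numpy(dtype=float)
        y = series[value_cols[0]].to_numpy(dtype=float)
    else:
        raise ValueError("pass (trials, values) arrays or a two-column DataFrame")
    if t.shape != y.shape:
        raise ValueError("trials and values must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trial indices must be strictly increasing")
    return t, y


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form OLS: slope, intercept, R^2, SSE."""
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0:
        raise ValueError("zero variance in trial index")
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * tbar)
    resid = y - (intercept + slope * t)
    sse = float(resid @ resid)
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0:
        # constant series: the flat line is exact, R^2 defined as 1
        r2 = 1.0 if np.allclose(resid, 0) else 0.0
    else:
        r2 = 1.0 - sse / sst
    return slope, intercept, r2, sse


def fit_phase(series, values=None, start: int | None = None, end: int | None = None) -> PhaseFit:
    """Fit one OLS line over the inclusive trial range ``start..end``.

    ``series`` is either an array of trial indices (with ``values``)
    or a DataFrame with columns ``trial`` and one metric.  At least two
    trials are required; the fit is exact (R² = 1) on noise-free linear
    data.
    """
    t, y = _coerce_series(series, values)
    start = int(t[0]) if start is None else start
    end = int(t[-1]) if end is None else end
    sel = (t >= start) & (t <= end)
    t, y = t[sel], y[sel]
    if t.size < 2:
        raise ValueError(f"need at least 2 trials in [{start}, {end}], got {t.size}")
    slope, intercept, r2, sse = _ols(t, y)
    return PhaseFit(
        start_trial=start,
        end_trial=end,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n=int(t.size),
        sse=sse,
    )


def _scan_breakpoints(
    t: np.ndarray, y: np.ndarray, max_phases: int, min_length: int
) -> list[int]:
    """Exhaustive SSE-minimizing breakpoint search.

    Breakpoints are trial indices that *start* a new phase.  Ties are
    broken toward fewer phases, then lexicographically earlier
    breakpoints.
    """
    n = t.size
    positions = list(range(n))  # candidate segment-start offsets

    def sse_of(segments: list[tuple[int, int]]) -> float:
        total = 0.0
        for a, b in segments:  # half-open sample offsets
            total += _ols(t[a:b], y[a:b])[3]
        return total

    best: tuple[float, int, tuple[int, ...]] | None = None
    for n_phases in range(1, max_phases + 1):
        for cut in itertools.combinations(positions[1:], n_phases - 1):
            bounds = [0, *cut, n]
            if any(b - a < min_length for a, b in zip(bounds, bounds[1:])):
                continue
            key = (
                round(sse_of(list(zip(bounds, bounds[1:]))), 12),
                n_phases,
                tuple(int(t[c]) for c in cut),
            )
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError(
            f"no breakpoint placement satisfies min phase length {min_length}"
        )
    return list(best[2])


def segment_phases(
    series,
    values=None,
    breakpoints: Sequence[int] | str = "auto",
    max_phases: int = 3,
    min_length: int = 3,
) -> list[PhaseFit]:
    """Fit piecewise OLS lines over phases of a trial series.

    ``breakpoints`` is a sorted list of trial indices, each starting a
    new phase (e.g. ``[8, 13]`` gives phases 1-7, 8-12, 13-end), or
    ``"auto"`` to scan all placements of up to ``max_phases - 1``
    breakpoints (phases at least ``min_length`` trials long) for the
    minimum total SSE.
    """
    t, y = _coerce_series(series, values)
    if isinstance(breakpoints, str):
        if breakpoints != "auto":
            raise ValueError(f"unknown breakpoints mode {breakpoints!r}")
        bps = _scan_breakpoints(t, y, max_phases=max_phases, min_length=min_length)
    else:
        bps = [int(b) for b in breakpoints]
        if sorted(bps) != bps or len(set(bps)) != len(bps):
            raise ValueError(f"breakpoints must be sorted and unique, got {bps}")
        if bps and (bps[0] <= t[0] or bps[-1] > t[-1]):
            raise ValueError(
                f"breakpoints {bps} outside trial range ({int(t[0])}, {int(t[-1])}]"
            )
    edges = [int(t[0]), *bps, int(t[-1]) + 1]
    return [
        fit_phase(t, y, start=a, end=b - 1) for a, b in zip(edges, edges[1:])
    ]


class SegmentedTrendRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn regressor wrapping the phase-segmented OLS fit.

    ``X`` is the trial index (shape (n, 1) or (n,)), ``y`` the metric.

    Parameters
    ----------
    breakpoints : list of int or "auto"
        Trial indices starting new phases, or automatic SSE scan.
    max_phases, min_length : int
        Search space of the automatic scan.

    Attributes
    ----------
    phases_ : list of PhaseFit
    breakpoints_ : list of int
    """

    def __init__(self, breakpoints="auto", max_phases: int = 3, min_length: int = 3):
        self.breakpoints = breakpoints
        self.max_phases = max_phases
        self.min_length = min_length

    def fit(self, X, y):
        t = np.ravel(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        self.phases_ = segment_phases(
            t,
            y,
            breakpoints=self.breakpoints,
            max_phases=self.max_phases,
            min_length=self.min_length,
        )
        self.breakpoints_ = [p.start_trial for p in self.phases_[1:]]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "phases_"):
            raise ValueError("regressor must be fitted before predict")
        t = np.ravel(np.asarray(X, dtype=float))
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            phase = self.phases_[-1]
            for p in self.phases_:
                if ti <= p.end_trial:
                    phase = p
                    break
            out[i] = phase.intercept + phase.slope * ti
        return out
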