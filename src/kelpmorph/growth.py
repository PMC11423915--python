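"""Growth-rate estimation from time-lapse cell counts.

Cell counts N(t) of a growing embryo follow N = N0 · r^t; fitting a straight
line to log N against t gives log r as the slope, and the doubling time is
τ = 1/log2(r).  Observation times are aligned so that t = 0 is the phase
I → II transition (the first longitudinal cell division), and the fit uses
observations with −48 h ≤ t ≤ 72 h (endpoints included).  Which observation
is t0 is an *input* — a flag on the series — because detecting the first
longitudinal division is an orientation question that belongs to the blade
stage, not to regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DEFAULT_FIT_WINDOW_H",
    "GrowthSeries",
    "GrowthFit",
    "InsufficientDataError",
    "align_series",
    "fit_growth_rate",
    "summarise_growth",
]

logger = logging.getLogger("kelpmorph")

#: Fit window around the phase I→II transition, hours, endpoints inclusive.
DEFAULT_FIT_WINDOW_H = (-48.0, 72.0)


class InsufficientDataError(ValueError):
    """Too few usable observations to fit a growth rate."""


@dataclass(frozen=True)
class GrowthSeries:
    """Time-stamped cell counts for one embryo.

    ``t0_index`` marks the first observation at/after the first longitudinal
    division (``None`` until alignment information is supplied).
    """

    embryo_id: str
    times_h: np.ndarray
    n_cells: np.ndarray
    t0_index: int | None = None
    stage_group: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        n = np.asarray(self.n_cells)
        if t.shape != n.shape or t.ndim != 1:
            raise ValueError("times and counts must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"series {self.embryo_id!r}: times not strictly increasing")
        if np.any(n < 1):
            raise ValueError(f"series {self.embryo_id!r}: cell counts must be >= 1")
        if np.any(np.diff(n) < 0):
            raise ValueError(f"series {self.embryo_id!r}: cell counts decrease (cells cannot merge)")
        if self.t0_index is not None and not (0 <= self.t0_index < t.size):
            raise ValueError(f"series {self.embryo_id!r}: t0_index out of range")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "n_cells", n)


@dataclass(frozen=True)
class GrowthFit:
    """Fitted exponential growth: N = N0 · r^t."""

    embryo_id: str
    r: float  # per-hour multiplicative rate
    log_n0: float  # natural-log intercept
    doubling_time_h: float  # τ = 1/log2(r); inf when r == 1
    r2: float
    n_points: int
    window_h: tuple[float, float] = DEFAULT_FIT_WINDOW_H
    stage_group: str | None = None


def align_series(series: GrowthSeries) -> GrowthSeries:
    """Shift times so the flagged t0 observation sits at t = 0."""
    if series.t0_index is None:
        raise ValueError(
            f"series {series.embryo_id!r}: no t0 (phase I→II transition) flagged"
        )
    return replace(
        series, times_h=series.times_h - series.times_h[series.t0_index]
    )


def fit_growth_rate(
    series: GrowthSeries,
    window: tuple[float, float] = DEFAULT_FIT_WINDOW_H,
) -> GrowthFit:
    """OLS of log N on t within ``window`` (inclusive); τ = 1/log2(r).

    The series must already be aligned (t = 0 at the phase I→II transition)
    or carry a t0 flag, in which case it is aligned here.
    """
    if series.t0_index is not None and series.times_h[series.t0_index] != 0.0:
        series = align_series(series)
    lo, hi = window
    mask = (series.times_h >= lo) & (series.times_h <= hi)
    t = series.times_h[mask]
    n = series.n_cells[mask].astype(float)
    if t.size < 3:
        raise InsufficientDataError(
            f"series {series.embryo_id!r}: {t.size} observation(s) in window "
            f"[{lo}, {hi}] h, need >= 3"
        )
    if np.ptp(t) == 0:
        raise InsufficientDataError(f"series {series.embryo_id!r}: zero time spread")
    res = sps.linregress(t, np.log(n))
    r = math.exp(res.slope)
    if r > 1.0:
        tau = 1.0 / math.log2(r)
    else:
        tau = math.inf
        logger.warning(
            "series %r: non-increasing fit (r=%.6g), doubling time infinite",
            series.embryo_id,
            r,
        )
    return GrowthFit(
        embryo_id=series.embryo_id,
        r=r,
        log_n0=float(res.intercept),
        doubling_time_h=tau,
        r2=float(res.rvalue) ** 2,
        n_points=int(t.size),
        window_h=(float(lo), float(hi)),
        stage_group=series.stage_group,
    )


def summarise_growth(
    fits: Iterable[GrowthFit], by_stage: bool = True
) -> dict[str, dict[str, float]]:
    """Per-group mean and dispersion of doubling time.

    Groups on ``stage_group`` (everything pools into 'all' when
    ``by_stage=False`` or labels are absent).  Infinite doubling times are
    excluded from the means with a logged count.
    """
    groups: dict[str, list[GrowthFit]] = {}
    for f in fits:
        key = f.stage_group if (by_stage and f.stage_group) else "all"
        groups.setdefault(key, []).append(f)
    if not groups:
        raise ValueError("no growth fits to summarise")
    out: dict[str, dict[str, float]] = {}
    for key, fs in groups.items():
        taus = np.array([f.doubling_time_h for f in fs])
        finite = taus[np.isfinite(taus)]
        n_inf = int(taus.size - finite.size)
        if n_inf:
            logger.warning(
                "group %r: excluding %d non-growing fit(s) from the mean", key, n_inf
            )
        if finite.size == 0:
            raise ValueError(f"group {key!r}: no finite doubling times")
        out[key] = {
            "n": int(taus.size),
            "n_finite": int(finite.size),
            "mean_tau_h": float(finite.mean()),
            "sd_tau_h": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
            "mean_r": float(np.mean([f.r for f in fs])),
        }
    return out
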