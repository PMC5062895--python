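"""Formation kinetics of nicotine from puff-time series.

Nicotine collected in mainstream smoke decreases with puff duration —
longer draws give secondary reactions more time to consume it.  Under
first-order kinetics the yield at puff time t is N0 * exp(-k t), so a
regression of ln(yield) on puff time gives the formation-side rate constant
(minus the slope) and, extrapolated back to zero puff time, the original
amount of nicotine (exp of the intercept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError


@dataclass(frozen=True)
class PuffSeries:
    """Yields (GC-area counts) measured at increasing puff times (seconds)."""

    points: tuple[tuple[float, float], ...]

    def __init__(self, points: Iterable[tuple[float, float]]) -> None:
        pts = tuple((float(t), float(y)) for t, y in points)
        if len(pts) < 2:
            raise InsufficientDataError(f"need at least 2 points, got {len(pts)}")
        times = [t for t, _ in pts]
        if any(t <= 0 for t in times):
            raise DomainError("puff times must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("puff times must be strictly increasing")
        if any(y <= 0 for _, y in pts):
            raise DomainError("yields must be positive (log-linear fit)")
        object.__setattr__(self, "points", pts)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def yields(self) -> np.ndarray:
        return np.array([y for _, y in self.points])


@dataclass(frozen=True)
class FormationFit:
    """Log-linear fit of a puff-time series.

    ``k_formation`` is minus the slope (s^-1) when the series decays;
    ``initial_amount`` is exp(intercept), the zero-puff-time extrapolation of
    the original nicotine amount.  ``non_decaying`` flags a positive slope,
    which is inconsistent with first-order loss.
    """

    k_formation: float
    initial_amount: float
    slope: float
    intercept: float
    r_squared: float
    non_decaying: bool = False


def fit_formation(series: PuffSeries) -> FormationFit:
    """Ordinary least squares of ln(yield) on puff time."""
    x = series.times
    y = np.log(series.yields)
    if np.ptp(y) == 0.0:
        # constant yields: zero slope, the common yield is the initial amount
        return FormationFit(
            k_formation=0.0,
            initial_amount=float(series.yields[0]),
            slope=0.0,
            intercept=float(y[0]),
            r_squared=1.0,
        )
    res = stats.linregress(x, y)
    slope = float(res.slope)
    return FormationFit(
        k_formation=-slope if slope <= 0 else 0.0,
        initial_amount=float(np.exp(res.intercept)),
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(min(max(res.rvalue ** 2, 0.0), 1.0)),
        non_decaying=slope > 0,
    )


def compare_initial_amount(fit: FormationFit, observed_c0: float) -> float:
    """Ratio of the extrapolated initial amount to an independently observed C0.

    A ratio near one means the puff-time extrapolation and the
    temperature-sweep peak agree on how much nicotine was originally present.
    """
    if observed_c0 <= 0:
        raise DomainError(f"observed C0 must be positive, got {observed_c0}")
    return fit.initial_amount / observed_c0
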