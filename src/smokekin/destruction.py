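"""End-to-end destruction analysis of a temperature-yield series.

The yield of a pyrolysis product swept across furnace temperatures is
unimodal: formation dominates below the peak, destruction above it.  At the
peak the two rates balance, so the peak yield is taken as the reference
concentration C0 and every higher-temperature yield is attributed to
first-order destruction over the fixed residence time:

    k(T) = ln(C0 / yield(T)) / t      for T > T_peak.

An Arrhenius regression of the resulting k(T) table gives the activation
energy and pre-exponential factor, and a per-temperature modified-Arrhenius
exponent n reconciles the fitted parameters with each measured k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import rate_laws
from .errors import (
    DomainError,
    DestructionRegimeError,
    EmptyDestructionWindowError,
    InsufficientDataError,
    NoPeakError,
    SmokekinError,
)
from .rate_laws import (
    ArrheniusParameters,
    Constants,
    ModifiedArrheniusExponent,
    RateConstantTable,
)


@dataclass(frozen=True)
class TemperatureYieldSeries:
    """One analyte's yield across pyrolysis temperatures.

    ``points`` are (temperature in kelvin, yield in GC-area counts) pairs with
    strictly increasing temperatures; ``residence_time`` is the time each gas
    parcel spends in the reaction zone (seconds).
    """

    points: tuple[tuple[float, float], ...]
    sample_id: str = ""
    analyte: str = "nicotine"
    residence_time: float = 2.0

    def __post_init__(self) -> None:
        pts = tuple((float(T), float(y)) for T, y in self.points)
        if len(pts) < 3:
            raise DomainError(f"need at least 3 points, got {len(pts)}")
        temps = [T for T, _ in pts]
        if any(T <= 0 for T in temps):
            raise DomainError("temperatures must be positive kelvin")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise DomainError("temperatures must be strictly increasing")
        if any(y < 0 for _, y in pts):
            raise DomainError("yields must be nonnegative")
        if not self.residence_time > 0:
            raise DomainError(f"residence time must be positive, got {self.residence_time}")
        object.__setattr__(self, "points", pts)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([T for T, _ in self.points])

    @property
    def yields(self) -> np.ndarray:
        return np.array([y for _, y in self.points])


@dataclass(frozen=True)
class DestructionResult:
    """Everything the destruction pipeline extracts from one series."""

    peak_temperature: float
    c0: float
    rate_constants: RateConstantTable
    arrhenius: ArrheniusParameters
    exponents: ModifiedArrheniusExponent
    k_average: float
    excluded_points: tuple[tuple[float, str], ...] = ()


def find_peak(series: TemperatureYieldSeries) -> tuple[float, float]:
    """Locate the yield maximum; its yield becomes the reference C0.

    Ties are broken toward the lowest temperature (earliest formation).
    """
    y = series.yields
    if np.all(y == 0):
        raise NoPeakError("all yields are zero: no peak")
    i = int(np.argmax(y))  # argmax returns the first maximum: low-T tie-break
    return float(series.temperatures[i]), float(y[i])


def destruction_window(
    series: TemperatureYieldSeries, strict: bool = False
) -> tuple[RateConstantTable, tuple[tuple[float, str], ...]]:
    """Classify post-peak points into usable rate constants and exclusions.

    Points above the peak with 0 < yield < C0 yield ``k = ln(C0/yield)/t``;
    yields at or above C0 (noise) and zero yields (infinite rate) are excluded
    with a reason.  In strict mode an above-C0 yield raises instead.
    """
    t_peak, c0 = find_peak(series)
    post = [(T, y) for T, y in series.points if T > t_peak]
    if not post:
        raise EmptyDestructionWindowError(
            f"no temperatures above the peak at {t_peak} K: empty destruction window"
        )
    kept: list[tuple[float, float]] = []
    excluded: list[tuple[float, str]] = []
    for T, y in post:
        if y >= c0:
            if strict:
                raise DestructionRegimeError(
                    f"post-peak yield {y} at {T} K is not below C0={c0}"
                )
            excluded.append((T, f"yield {y} >= C0 {c0}"))
        elif y <= 0:
            excluded.append((T, "zero yield: rate constant undefined"))
        else:
            kept.append((T, rate_laws.k_from_yield_ratio(c0, y, series.residence_time)))
    return RateConstantTable(kept), tuple(excluded)


def compute_rate_constants(
    series: TemperatureYieldSeries, strict: bool = False
) -> RateConstantTable:
    """Per-temperature destruction rate constants over the post-peak window."""
    table, _ = destruction_window(series, strict=strict)
    return table


def average_rate_constant(table: RateConstantTable) -> float:
    """Arithmetic mean of the rate constants over the destruction window."""
    if len(table) == 0:
        raise InsufficientDataError("empty rate-constant table: no average")
    return float(np.mean(table.rate_constants))


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except SmokekinError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc


def run_destruction_analysis(
    series: TemperatureYieldSeries,
    constants: Constants = Constants(),
    strict: bool = False,
) -> DestructionResult:
    """Full destruction analysis of one temperature-yield series.

    Composes peak detection, rate-constant extraction, the Arrhenius fit, the
    per-temperature modified-Arrhenius exponent solve and the window-average
    rate constant.  Deterministic for a fixed input; stage failures are
    re-raised with a stage label.
    """
    t_peak, c0 = _stage("peak-detection", find_peak, series)
    table, excluded = _stage("rate-constants", destruction_window, series, strict)
    arr = _stage("arrhenius-fit", rate_laws.fit_arrhenius, table, constants)
    exponents = _stage(
        "exponent-solve",
        lambda: ModifiedArrheniusExponent(
            (T, rate_laws.solve_temperature_exponent(k, arr, T, constants))
            for T, k in table
        ),
    )
    k_avg = _stage("average-k", average_rate_constant, table)
    return DestructionResult(
        peak_temperature=t_peak,
        c0=c0,
        rate_constants=table,
        arrhenius=arr,
        exponents=exponents,
        k_average=k_avg,
        excluded_points=excluded,
    )


def reference_exponent(result: DestructionResult, T_ref: float = 673.0) -> tuple[float, float]:
    """The (T, n) entry closest to a reference temperature (default 673 K).

    673 K is the canonical worked-example temperature for these kinetics; the
    nearest in-window entry is returned so reports can always quote it.
    """
    if len(result.exponents) == 0:
        raise InsufficientDataError("no exponent entries")
    return min(result.exponents, key=lambda e: abs(e[0] - T_ref))
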