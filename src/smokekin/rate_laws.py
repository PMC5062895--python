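"""First-order and Arrhenius rate expressions for pyrolysis kinetics.

The pseudo-first-order description treats the disappearance of a pyrolysis
product (here nicotine in the 673-973 K window) as exponential decay over a
fixed residence time, with a temperature-dependent rate constant k(T).  The
temperature dependence is captured either by the plain Arrhenius law

    k = A * exp(-Ea / (R*T))

or by the Kooij-type modified Arrhenius law with a power-law prefactor

    k = A * T**n * exp(-Ea / (R*T)).

Activation energies are stored in J/mol throughout; reporting layers may
rescale to kJ/mol, but no computation in this module ever mixes the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, DestructionRegimeError, InsufficientDataError

#: Universal gas constant, J K^-1 mol^-1.
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class Constants:
    """Physical constants used by the rate laws.

    Parameters
    ----------
    R : float
        Universal gas constant in J K^-1 mol^-1 (default 8.314).
    """

    R: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise DomainError(f"gas constant must be positive, got {self.R}")


@dataclass(frozen=True)
class ArrheniusParameters:
    """Arrhenius parameters (Ea, A) with regression diagnostics.

    Attributes
    ----------
    Ea : float
        Activation energy in J/mol.
    A : float
        Pre-exponential factor in s^-1.
    r_squared : float
        Coefficient of determination of the ln k vs 1/T regression
        (1.0 for parameters that were stated rather than fitted).
    n_points : int
        Number of (T, k) pairs behind the fit.
    """

    Ea: float
    A: float
    r_squared: float = 1.0
    n_points: int = 2

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise DomainError(f"pre-exponential factor must be positive, got {self.A}")
        if self.n_points < 2:
            raise DomainError(f"n_points must be >= 2, got {self.n_points}")
        if not (0.0 <= self.r_squared <= 1.0):
            raise DomainError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    @property
    def Ea_kJ_per_mol(self) -> float:
        return self.Ea / 1000.0


@dataclass(frozen=True)
class RateConstantTable:
    """Per-temperature pseudo-first-order rate constants.

    ``entries`` is an ordered sequence of (T in kelvin, k in s^-1) pairs with
    strictly increasing temperatures and strictly positive rate constants.
    """

    entries: tuple[tuple[float, float], ...]

    def __init__(self, entries: Iterable[tuple[float, float]]) -> None:
        ent = tuple((float(T), float(k)) for T, k in entries)
        for T, k in ent:
            if T <= 0:
                raise DomainError(f"temperature must be positive kelvin, got {T}")
            if k <= 0:
                raise DomainError(f"rate constant must be positive, got {k} at T={T}")
        temps = [T for T, _ in ent]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise DomainError("temperatures must be strictly increasing")
        object.__setattr__(self, "entries", ent)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([T for T, _ in self.entries])

    @property
    def rate_constants(self) -> np.ndarray:
        return np.array([k for _, k in self.entries])


@dataclass(frozen=True)
class ModifiedArrheniusExponent:
    """Temperature exponents n of the modified Arrhenius law, per temperature."""

    entries: tuple[tuple[float, float], ...]

    def __init__(self, entries: Iterable[tuple[float, float]]) -> None:
        ent = tuple((float(T), float(n)) for T, n in entries)
        for T, n in ent:
            if not math.isfinite(n):
                raise DomainError(f"non-finite exponent at T={T}")
        object.__setattr__(self, "entries", ent)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def first_order_concentration(c0: float, k: float, t: float) -> float:
    """Concentration after first-order decay: ``c0 * exp(-k*t)``.

    Parameters are the initial concentration (any nonnegative unit, e.g.
    GC-area counts), the rate constant in s^-1 and the elapsed time in s.
    """
    if c0 < 0 or k < 0 or t < 0:
        raise DomainError(f"c0, k, t must be nonnegative, got ({c0}, {k}, {t})")
    return c0 * math.exp(-k * t)


def arrhenius_k(params: ArrheniusParameters, T: float, constants: Constants = Constants()) -> float:
    """Arrhenius rate constant ``A * exp(-Ea/(R*T))`` at temperature T (K)."""
    if T <= 0:
        raise DomainError(f"temperature must be positive kelvin, got {T}")
    return params.A * math.exp(-params.Ea / (constants.R * T))


def k_from_yield_ratio(c0: float, c: float, t: float) -> float:
    """Pseudo-first-order rate constant from a concentration ratio.

    Inverts the integrated first-order law: ``k = ln(c0/c) / t``.  Requires
    the destruction regime ``0 < c <= c0``; a yield exceeding the reference
    concentration cannot be explained by decay.
    """
    if c0 <= 0:
        raise DomainError(f"c0 must be positive, got {c0}")
    if t <= 0:
        raise DomainError(f"time must be positive, got {t}")
    if c > c0:
        raise DestructionRegimeError(
            f"yield {c} exceeds reference concentration {c0}: not a destruction regime"
        )
    if c <= 0:
        raise DomainError(f"yield must be positive (got {c}); k would be infinite")
    return math.log(c0 / c) / t


def fit_arrhenius(
    table: RateConstantTable, constants: Constants = Constants()
) -> ArrheniusParameters:
    """Ordinary least squares of ln k on 1/T.

    Returns ``Ea = -slope * R`` and ``A = exp(intercept)`` together with the
    r-squared of the same regression.  A perfectly flat table (all k equal)
    degenerates to Ea = 0, A = k with r_squared = 1.
    """
    if len(table) < 2:
        raise InsufficientDataError(
            f"need at least 2 (T, k) points for an Arrhenius fit, got {len(table)}"
        )
    x = 1.0 / table.temperatures
    y = np.log(table.rate_constants)
    if np.ptp(x) == 0.0:
        raise InsufficientDataError("all temperatures equal: cannot regress on 1/T")
    if np.ptp(y) == 0.0:
        # flat line: zero activation energy, A equals the common rate constant
        return ArrheniusParameters(Ea=0.0, A=float(np.exp(y[0])), r_squared=1.0,
                                   n_points=len(table))
    res = stats.linregress(x, y)
    r2 = min(max(res.rvalue ** 2, 0.0), 1.0)
    return ArrheniusParameters(
        Ea=float(-res.slope * constants.R),
        A=float(np.exp(res.intercept)),
        r_squared=float(r2),
        n_points=len(table),
    )


def solve_temperature_exponent(
    k: float,
    params: ArrheniusParameters,
    T: float,
    constants: Constants = Constants(),
) -> float:
    """Temperature exponent n of the modified Arrhenius law at one temperature.

    Solves ``k = A * T**n * exp(-Ea/(R*T))`` for n in closed form:

        n = [ln k - ln A + Ea/(R*T)] / ln T

    which is exact because the law is monotone in n at fixed T.
    """
    if k <= 0:
        raise DomainError(f"rate constant must be positive, got {k}")
    if T <= 1:
        raise DomainError(f"temperature must exceed 1 K (ln T != 0), got {T}")
    return (math.log(k) - math.log(params.A) + params.Ea / (constants.R * T)) / math.log(T)


def modified_arrhenius_k(
    params: ArrheniusParameters,
    n: float,
    T: float,
    constants: Constants = Constants(),
) -> float:
    """Modified (Kooij) Arrhenius rate constant ``A * T**n * exp(-Ea/(R*T))``."""
    if T <= 0:
        raise DomainError(f"temperature must be positive kelvin, got {T}")
    return params.A * T ** n * math.exp(-params.Ea / (constants.R * T))
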