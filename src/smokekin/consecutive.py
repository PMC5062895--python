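"""Consecutive first-order reaction model Nic -> I -> Product.

A two-step series reaction with rate constants k1 (destruction of nicotine,
producing the pyridinyl-radical intermediate I) and k2 (conversion of the
intermediate to the stable product, pyridine).  The coupled linear system

    d[Nic]/dt     = -k1 [Nic]
    d[I]/dt       =  k1 [Nic] - k2 [I]
    d[Product]/dt =  k2 [I]

has closed-form solutions from the initial state ([Nic]0, 0, 0):

    [Nic](t)     = [Nic]0 exp(-k1 t)
    [I](t)       = k1 [Nic]0 / (k2 - k1) * (exp(-k1 t) - exp(-k2 t))
    [Product](t) = [Nic]0 * [1 + (k2 exp(-k1 t) - k1 exp(-k2 t)) / (k1 - k2)]

The product expression is the standard mass-conserving form: it is zero at
t = 0 and satisfies [Nic] + [I] + [Product] = [Nic]0 identically.  When
k2 << k1 the product reduces to the single-exponential approximation
[Nic]0 (1 - exp(-k2 t)), which is what makes the unobserved intermediate
inferable from the measured precursor and product alone.

Concentrations are in GC-area counts (a relative, uncalibrated unit); all
ratios of counts cancel the calibration factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, SmokekinError

# relative |k1 - k2| threshold below which the equal-rate analytic limit is used
_EQUAL_RATE_RTOL = 1e-6


@dataclass(frozen=True)
class ConsecutiveModel:
    """Parameters of the series reaction Nic --k1--> I --k2--> Product.

    Attributes
    ----------
    k1 : float
        Destruction rate constant of nicotine, s^-1.
    k2 : float
        Conversion rate constant of the intermediate, s^-1.
    nic0 : float
        Initial nicotine concentration [Nic]0, GC-area counts.
    t : float
        Residence (puff) time in seconds used by summary operations;
        2.0 s is representative of cigarette smoking.
    """

    k1: float
    k2: float
    nic0: float
    t: float = 2.0

    def __post_init__(self) -> None:
        if not self.k1 > 0 or not self.k2 > 0:
            raise DomainError(f"rate constants must be positive, got k1={self.k1}, k2={self.k2}")
        if not self.nic0 > 0:
            raise DomainError(f"[Nic]0 must be positive, got {self.nic0}")
        if self.t < 0:
            raise DomainError(f"residence time must be nonnegative, got {self.t}")


@dataclass(frozen=True)
class SpeciesTrajectory:
    """Time courses of the three species on a common time grid."""

    times: np.ndarray
    nic: np.ndarray
    intermediate: np.ndarray
    product: np.ndarray


@dataclass(frozen=True)
class DerivedSummary:
    """Scalar summary used to interpret the destruction kinetics.

    ``ratio_nic_to_sum`` compares the original nicotine with everything the
    model says it became (inferred intermediate plus measured product);
    ``pct_transferred_intact`` is the percentage of nicotine not converted to
    the product, i.e. available to transfer into mainstream smoke unchanged.
    """

    intermediate_at_t: float
    product_max: float
    ratio_nic_to_sum: float
    ratio_product_to_nic: float
    pct_transferred_intact: float


def _check_time(t: float) -> None:
    if t < 0:
        raise DomainError(f"time must be nonnegative, got {t}")


def nic_at(model: ConsecutiveModel, t: float) -> float:
    """Nicotine concentration ``[Nic]0 * exp(-k1 t)``."""
    _check_time(t)
    return model.nic0 * math.exp(-model.k1 * t)


def intermediate_at(model: ConsecutiveModel, t: float) -> float:
    """Intermediate concentration [I](t).

    Uses ``k1 [Nic]0 exp(-k2 t) expm1((k2 - k1) t) / (k2 - k1)``, which is the
    closed form rewritten around ``expm1`` so the difference of exponentials
    never suffers catastrophic cancellation.  Within a relative difference of
    1e-6 between the rate constants the analytic equal-rate limit
    ``[Nic]0 k t exp(-k t)`` is used instead (the raw formula divides by zero).
    """
    _check_time(t)
    k1, k2 = model.k1, model.k2
    if abs(k1 - k2) <= _EQUAL_RATE_RTOL * max(k1, k2):
        k = 0.5 * (k1 + k2)
        return model.nic0 * k * t * math.exp(-k * t)
    return model.k1 * model.nic0 * math.exp(-k2 * t) * math.expm1((k2 - k1) * t) / (k2 - k1)


def product_at(model: ConsecutiveModel, t: float) -> float:
    """Product concentration [Product](t), mass-conserving closed form."""
    _check_time(t)
    k1, k2 = model.k1, model.k2
    if abs(k1 - k2) <= _EQUAL_RATE_RTOL * max(k1, k2):
        k = 0.5 * (k1 + k2)
        return model.nic0 * (1.0 - math.exp(-k * t) * (1.0 + k * t))
    return model.nic0 * (
        1.0 + (k2 * math.exp(-k1 * t) - k1 * math.exp(-k2 * t)) / (k1 - k2)
    )


def product_simplified(model: ConsecutiveModel, t: float) -> float:
    """Rate-determining-step approximation ``[Nic]0 (1 - exp(-k2 t))``.

    Valid when k2 << k1 (the second step limits the overall rate): the
    exp(-k1 t) transient has decayed and the product grows on the k2 scale.
    """
    _check_time(t)
    return -model.nic0 * math.expm1(-model.k2 * t)


def invert_k2_from_product(nic0: float, product_max: float, t: float) -> float:
    """Solve the simplified product law for k2.

    ``k2 = -ln(1 - product_max/nic0) / t`` — the inverse of
    :func:`product_simplified`, used to estimate the second rate constant from
    the measured product maximum and the original precursor concentration.
    """
    if nic0 <= 0:
        raise DomainError(f"[Nic]0 must be positive, got {nic0}")
    if t <= 0:
        raise DomainError(f"time must be positive, got {t}")
    if product_max < 0:
        raise DomainError(f"product concentration must be nonnegative, got {product_max}")
    if product_max >= nic0:
        raise DomainError(
            f"product {product_max} must be below the precursor {nic0}: "
            "yield cannot exceed what was available"
        )
    return -math.log1p(-product_max / nic0) / t


def time_of_max_intermediate(model: ConsecutiveModel) -> float:
    """Time at which [I](t) peaks: ``ln(k1/k2) / (k1 - k2)`` (1/k when k1 = k2).

    The formula is symmetric under swapping k1 and k2.
    """
    k1, k2 = model.k1, model.k2
    if abs(k1 - k2) <= 1e-12 * max(k1, k2):
        return 1.0 / (0.5 * (k1 + k2))
    return math.log(k1 / k2) / (k1 - k2)


def ode_oracle(model: ConsecutiveModel, times: np.ndarray) -> SpeciesTrajectory:
    """Numerically integrate the coupled rate equations.

    Serves as an independent cross-check of the closed-form solutions: the
    three linear ODEs are integrated from ([Nic]0, 0, 0) with tight tolerances
    (rtol 1e-10), so agreement to ~1e-6 relative validates the analytic path.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise DomainError("times must be a nonempty 1-D grid")
    if times[0] < 0:
        raise DomainError("times must be nonnegative")
    if np.any(np.diff(times) < 0):
        raise DomainError("time grid must be ascending")

    k1, k2 = model.k1, model.k2

    def rhs(_t, y):
        nic, inter, _prod = y
        return [-k1 * nic, k1 * nic - k2 * inter, k2 * inter]

    y0 = [model.nic0, 0.0, 0.0]
    t_end = float(times[-1])
    if t_end == 0.0:
        n = times.size
        return SpeciesTrajectory(
            times=times,
            nic=np.full(n, model.nic0),
            intermediate=np.zeros(n),
            product=np.zeros(n),
        )
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        t_eval=times,
        rtol=1e-10,
        atol=model.nic0 * 1e-12,
        method="LSODA",
    )
    if not sol.success:  # pragma: no cover - linear system, should not fail
        raise SmokekinError(f"ODE integration failed: {sol.message}")
    return SpeciesTrajectory(
        times=times,
        nic=sol.y[0],
        intermediate=sol.y[1],
        product=sol.y[2],
    )


def derived_summary(model: ConsecutiveModel, product_max: float) -> DerivedSummary:
    """Summary ratios linking the model to the measured product maximum.

    The intermediate is inferred at the model's residence time; the measured
    product maximum (pyridine) closes the budget.  ``ratio_nic_to_sum`` below
    one indicates conversion channels beyond the single modeled route.
    """
    if product_max < 0:
        raise DomainError(f"product maximum must be nonnegative, got {product_max}")
    if product_max > model.nic0:
        raise DomainError(
            f"product maximum {product_max} exceeds [Nic]0 {model.nic0}"
        )
    inter = intermediate_at(model, model.t)
    denom = inter + product_max
    if denom == 0:
        raise DomainError("intermediate + product is zero: ratio undefined")
    ratio_product_to_nic = product_max / model.nic0
    return DerivedSummary(
        intermediate_at_t=inter,
        product_max=product_max,
        ratio_nic_to_sum=model.nic0 / denom,
        ratio_product_to_nic=ratio_product_to_nic,
        pct_transferred_intact=100.0 * (1.0 - ratio_product_to_nic),
    )
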