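"""Synthetic temperature-yield and puff-time data with known ground truth.

The generator emulates the structure the analysis assumes: a unimodal
yield-vs-temperature curve produced by competing first-order formation and
destruction processes (both Arrhenius in temperature), and exponentially
decaying puff-time series.  Because the generating parameters are known,
every pipeline stage can be exercised as a parameter-recovery experiment.

Two curve models are available:

``"ideal"`` (default)
    Formation-limited rise below the peak, ``y = S * (1 - exp(-k_f t))``,
    and first-order decay of the peak concentration above it,
    ``y = C0 * exp(-k_d t)`` with C0 the peak yield.  This is exactly the
    idealization the destruction pipeline inverts (rates balance at the
    peak; all post-peak decline is destruction of C0), so the noise-free
    round trip recovers the generating (Ea, A) to machine precision.

``"batch"``
    The product form ``y = S * (1 - exp(-k_f t)) * exp(-k_d t)``: each
    temperature is an independent batch in which the formed amount also
    decays.  Physically more literal, but the peak yield then already
    contains destruction survival, so the pipeline's peak-as-C0 convention
    underestimates every rate constant by k_d(T_peak) and the recovered Ea
    is biased by several percent even without noise.

Noise is multiplicative lognormal (median 1), the natural choice for
strictly positive, heteroscedastic GC-area counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .destruction import TemperatureYieldSeries
from .errors import DomainError
from .formation import PuffSeries
from .rate_laws import ArrheniusParameters, Constants

#: Default pyrolysis temperature grid: 473-973 K in 50 K steps (200-700 C).
DEFAULT_TEMPERATURES: tuple[float, ...] = tuple(np.arange(473.0, 974.0, 50.0))

# Formation-side defaults: Ea ~ 60 kJ/mol with the pre-exponential factor set
# so the noise-free peak of the ES1-like curve falls at ~673 K (400 C).
_ES1_FORMATION = ArrheniusParameters(Ea=60_000.0, A=1.2e5)
# SM1 forms later; this A puts the SM1-like peak at ~773 K (500 C).
_SM1_FORMATION = ArrheniusParameters(Ea=60_000.0, A=2.2e4)
_ES1_DESTRUCTION = ArrheniusParameters(Ea=108_850.0, A=2.1e6)
_SM1_DESTRUCTION = ArrheniusParameters(Ea=136_520.0, A=3.0e7)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for one simulated temperature sweep.

    ``y_scale`` is the precursor pool in GC-area counts; formation and
    destruction parameters are Arrhenius pairs; ``noise_sd`` is the relative
    standard deviation of the multiplicative lognormal noise.  A seed is
    mandatory whenever noise is requested.
    """

    y_scale: float = 8.0e8
    formation_params: ArrheniusParameters = _ES1_FORMATION
    destruction_params: ArrheniusParameters = _ES1_DESTRUCTION
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    residence_time: float = 2.0
    noise_sd: float = 0.02
    seed: int | None = None
    replicates: int = 1
    curve_model: str = "ideal"
    sample_id: str = "ES1"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if len(self.temperatures) < 3:
            raise DomainError("need at least 3 temperatures")
        if self.curve_model not in ("ideal", "batch"):
            raise DomainError(f"unknown curve model {self.curve_model!r}")
        if not self.y_scale > 0:
            raise DomainError(f"y_scale must be positive, got {self.y_scale}")
        if not self.residence_time > 0:
            raise DomainError("residence time must be positive")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")


def _arrhenius_grid(params: ArrheniusParameters, T: np.ndarray, R: float) -> np.ndarray:
    return params.A * np.exp(-params.Ea / (R * T))


def noise_free_curve(config: SyntheticConfig, constants: Constants = Constants()) -> np.ndarray:
    """The deterministic yield curve of the configured model, per temperature."""
    T = np.asarray(config.temperatures, dtype=float)
    t = config.residence_time
    kf = _arrhenius_grid(config.formation_params, T, constants.R)
    kd = _arrhenius_grid(config.destruction_params, T, constants.R)
    formed = config.y_scale * -np.expm1(-kf * t)
    survival = np.exp(-kd * t)
    batch = formed * survival
    if config.curve_model == "batch":
        return batch
    # ideal: peak located where the batch competition peaks; formation-limited
    # rise below it, first-order decay of the peak concentration above it
    ip = int(np.argmax(batch))
    c0 = formed[ip]
    return np.where(T <= T[ip], formed, c0 * survival)


def _lognormal_factors(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(sd ** 2))
    return np.exp(rng.normal(0.0, sigma, size=n))


def _rng(seed: int | None, replicate: int) -> np.random.Generator:
    # the replicate index perturbs a documented sub-seed of the base seed
    return np.random.default_rng((int(seed), int(replicate)))


def generate_yield_curve(
    config: SyntheticConfig,
    replicate: int = 0,
    constants: Constants = Constants(),
) -> TemperatureYieldSeries:
    """One simulated temperature-yield series, deterministic given the seed."""
    y = noise_free_curve(config, constants)
    if config.noise_sd > 0 and config.seed is None:
        raise DomainError("a seed is mandatory when noise_sd > 0")
    if config.noise_sd > 0:
        y = y * _lognormal_factors(_rng(config.seed, replicate), config.noise_sd, y.size)
    return TemperatureYieldSeries(
        points=tuple(zip(config.temperatures, y)),
        sample_id=config.sample_id,
        analyte="nicotine",
        residence_time=config.residence_time,
    )


def generate_puff_series(
    n0: float,
    k: float,
    puff_times: Sequence[float] = (2.0, 5.0, 10.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PuffSeries:
    """Exponentially decaying puff-time series ``n0 * exp(-k t)`` plus noise."""
    if n0 <= 0:
        raise DomainError(f"n0 must be positive, got {n0}")
    if k < 0:
        raise DomainError(f"rate constant must be nonnegative, got {k}")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be nonnegative, got {noise_sd}")
    if noise_sd > 0 and seed is None:
        raise DomainError("a seed is mandatory when noise_sd > 0")
    times = np.asarray(puff_times, dtype=float)
    y = n0 * np.exp(-k * times)
    if noise_sd > 0:
        y = y * _lognormal_factors(_rng(seed, 0), noise_sd, y.size)
    return PuffSeries(tuple(zip(times, y)))


def fixture_es1(**overrides) -> SyntheticConfig:
    """ES1-like configuration: destruction Ea 108.85 kJ/mol, A 2.1e6 s^-1,
    precursor pool 8.0e8 counts, peak near 673 K."""
    cfg = SyntheticConfig(
        y_scale=8.0e8,
        formation_params=_ES1_FORMATION,
        destruction_params=_ES1_DESTRUCTION,
        sample_id="ES1",
    )
    return replace(cfg, **overrides) if overrides else cfg


def fixture_sm1(**overrides) -> SyntheticConfig:
    """SM1-like configuration: destruction Ea 136.52 kJ/mol, A 3.0e7 s^-1,
    peak near 773 K.  The precursor pool is one tenth of ES1's, an
    approximation of the roughly tenfold nicotine difference between the two
    cigarettes."""
    cfg = SyntheticConfig(
        y_scale=8.0e7,
        formation_params=_SM1_FORMATION,
        destruction_params=_SM1_DESTRUCTION,
        sample_id="SM1",
    )
    return replace(cfg, **overrides) if overrides else cfg


def ground_truth(config: SyntheticConfig) -> dict:
    """The generating parameters as a plain dict (sidecar for recovery tests)."""
    return {
        "sample_id": config.sample_id,
        "y_scale": config.y_scale,
        "formation": {"Ea_J_per_mol": config.formation_params.Ea, "A_per_s": config.formation_params.A},
        "destruction": {"Ea_J_per_mol": config.destruction_params.Ea, "A_per_s": config.destruction_params.A},
        "residence_time_s": config.residence_time,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "curve_model": config.curve_model,
    }
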