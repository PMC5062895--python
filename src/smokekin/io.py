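"""CSV input, JSON/markdown reports and run configuration.

Temperatures may be supplied in Celsius (the natural unit for furnace
sweeps) or kelvin; conversion happens once at this boundary using 273.15 and
everything downstream is kelvin.  Reports are written with canonical float
formatting so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .consecutive import ConsecutiveModel, DerivedSummary
from .destruction import DestructionResult, TemperatureYieldSeries, reference_exponent
from .errors import ParseError, SmokekinError
from .formation import FormationFit, PuffSeries

SCHEMA_VERSION = "1"
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class RunConfig:
    """User-facing knobs shared by the analysis commands.

    ``report_precision`` controls only formatting (2 decimals for kJ/mol and
    ratios, 2 significant digits for counts); internal values are never
    rounded.
    """

    residence_time: float = 2.0
    gas_constant: float = 8.314
    temp_unit: str = "celsius"
    strict_mode: bool = False
    seed: int | None = None
    report_precision: int = 2

    def __post_init__(self) -> None:
        if not self.residence_time > 0:
            raise ParseError(f"residence_time must be positive, got {self.residence_time}")
        if not self.gas_constant > 0:
            raise ParseError(f"gas_constant must be positive, got {self.gas_constant}")
        if self.temp_unit not in ("celsius", "kelvin"):
            raise ParseError(f"temp_unit must be celsius or kelvin, got {self.temp_unit!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def merged(self, **flags: Any) -> "RunConfig":
        """Override config-file values with explicitly set CLI flags."""
        set_flags = {k: v for k, v in flags.items() if v is not None}
        return replace(self, **set_flags) if set_flags else self


def _to_kelvin(values: pd.Series, temp_unit: str) -> pd.Series:
    return values + CELSIUS_OFFSET if temp_unit == "celsius" else values


def _read_csv(path: str | Path, required: tuple[str, str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    bad_lines = []
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        # +2: one for the header, one for 1-based line numbering
        bad_lines += [int(i) + 2 for i in df.index[coerced.isna()]]
        df[col] = coerced
    if bad_lines:
        raise ParseError(f"{path}: non-numeric values on line(s) {sorted(set(bad_lines))}")
    return df


def read_temperature_series(
    path: str | Path,
    config: RunConfig = RunConfig(),
    sample_id: str = "",
    analyte: str = "nicotine",
) -> TemperatureYieldSeries:
    """Read a `temperature,yield` CSV into a validated kelvin-unit series."""
    df = _read_csv(path, ("temperature", "yield"))
    temps = _to_kelvin(df["temperature"], config.temp_unit)
    dup = temps[temps.duplicated()]
    if not dup.empty:
        lines = [int(i) + 2 for i in dup.index]
        raise ParseError(f"{path}: duplicate temperature rows on line(s) {lines}")
    order = temps.argsort(kind="stable")
    points = tuple(zip(temps.iloc[order], df["yield"].iloc[order]))
    try:
        return TemperatureYieldSeries(
            points=points,
            sample_id=sample_id,
            analyte=analyte,
            residence_time=config.residence_time,
        )
    except SmokekinError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_puff_series(path: str | Path) -> PuffSeries:
    """Read a `puff_time_s,yield` CSV into a validated puff series."""
    df = _read_csv(path, ("puff_time_s", "yield"))
    times = df["puff_time_s"]
    dup = times[times.duplicated()]
    if not dup.empty:
        lines = [int(i) + 2 for i in dup.index]
        raise ParseError(f"{path}: duplicate puff-time rows on line(s) {lines}")
    order = times.argsort(kind="stable")
    try:
        return PuffSeries(tuple(zip(times.iloc[order], df["yield"].iloc[order])))
    except SmokekinError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_temperature_series(
    series: TemperatureYieldSeries, path: str | Path, temp_unit: str = "kelvin"
) -> None:
    temps = series.temperatures
    if temp_unit == "celsius":
        temps = temps - CELSIUS_OFFSET
    pd.DataFrame({"temperature": temps, "yield": series.yields}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_puff_series(series: PuffSeries, path: str | Path) -> None:
    pd.DataFrame({"puff_time_s": series.times, "yield": series.yields}).to_csv(
        path, index=False, float_format="%.17g"
    )


def _canonical(obj: Any) -> Any:
    """Round floats to 12 significant digits so reports are byte-stable."""
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def destruction_report(result: DestructionResult, sample_id: str = "") -> dict:
    """JSON-ready report of a destruction analysis (Table-1-shaped core)."""
    T_ref, n_ref = reference_exponent(result)
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "destruction",
        "sample_id": sample_id,
        "peak": {"temperature_K": result.peak_temperature, "yield_counts": result.c0},
        "c0": result.c0,
        "rate_constants": [
            {"temperature_K": T, "k_per_s": k} for T, k in result.rate_constants
        ],
        "arrhenius": {
            "Ea_kJ_per_mol": result.arrhenius.Ea_kJ_per_mol,
            "A_per_s": result.arrhenius.A,
            "r_squared": result.arrhenius.r_squared,
            "n_points": result.arrhenius.n_points,
        },
        "exponents": [{"temperature_K": T, "n": n} for T, n in result.exponents],
        "reference_exponent": {"temperature_K": T_ref, "n": n_ref},
        "k_average_per_s": result.k_average,
        "excluded_points": [
            {"temperature_K": T, "reason": reason} for T, reason in result.excluded_points
        ],
    }


def formation_report(fit: FormationFit) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "formation",
        "slope_per_s": fit.slope,
        "k_formation_per_s": fit.k_formation,
        "intercept_ln_counts": fit.intercept,
        "initial_amount_counts": fit.initial_amount,
        "r_squared": fit.r_squared,
        "non_decaying": fit.non_decaying,
    }


def consecutive_report(model: ConsecutiveModel, summary: DerivedSummary) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "consecutive",
        "k1_per_s": model.k1,
        "k2_per_s": model.k2,
        "nic0_counts": model.nic0,
        "residence_time_s": model.t,
        "intermediate_counts": summary.intermediate_at_t,
        "product_max_counts": summary.product_max,
        "ratio_nic_to_sum": summary.ratio_nic_to_sum,
        "ratio_product_to_nic": summary.ratio_product_to_nic,
        "pct_transferred_intact": summary.pct_transferred_intact,
    }


def write_report(report: dict, path: str | Path, markdown_path: str | Path | None = None) -> None:
    """Write a JSON report (and optionally a human-readable markdown view)."""
    if not report:
        raise SmokekinError("refusing to write an empty report")
    text = json.dumps(_canonical(report), indent=2, sort_keys=True) + "\n"
    Path(path).write_text(text)
    if markdown_path is not None:
        Path(markdown_path).write_text(render_markdown(report))


def render_markdown(report: dict, precision: int = 2) -> str:
    """Human-readable report; destruction reports get a Table-1-shaped row."""
    if not report:
        raise SmokekinError("empty report")
    kind = report.get("kind", "unknown")
    lines = [f"# smokekin {kind} report", ""]
    if kind == "destruction":
        arr = report["arrhenius"]
        lines += [
            "| Cigarette | Ea (kJ mol^-1) | A (s^-1) |",
            "|---|---|---|",
            f"| {report.get('sample_id') or 'sample'} | "
            f"{arr['Ea_kJ_per_mol']:.{precision}f} | {arr['A_per_s']:.1e} |",
            "",
            f"- peak: {report['peak']['temperature_K']:.2f} K, "
            f"C0 = {report['c0']:.2e} counts",
            f"- r^2 of Arrhenius fit: {arr['r_squared']:.4f} ({arr['n_points']} points)",
            f"- average destruction rate constant: {report['k_average_per_s']:.{precision}f} s^-1",
            f"- modified-Arrhenius exponent n at "
            f"{report['reference_exponent']['temperature_K']:.0f} K: "
            f"{report['reference_exponent']['n']:.{precision}f}",
            f"- excluded points: {len(report['excluded_points'])}",
        ]
    elif kind == "formation":
        lines += [
            f"- slope: {report['slope_per_s']:.4f} s^-1",
            f"- formation rate constant: {report['k_formation_per_s']:.{precision}f} s^-1",
            f"- initial amount (zero-puff extrapolation): {report['initial_amount_counts']:.2e} counts",
            f"- r^2: {report['r_squared']:.4f}",
        ]
    elif kind == "consecutive":
        lines += [
            f"- k1 = {report['k1_per_s']:.{precision}f} s^-1, "
            f"k2 = {report['k2_per_s']:.{precision}f} s^-1, t = {report['residence_time_s']:.1f} s",
            f"- [Nic]0 = {report['nic0_counts']:.2e} counts",
            f"- inferred intermediate: {report['intermediate_counts']:.2e} counts",
            f"- [Nic]0 / (I + product): {report['ratio_nic_to_sum']:.{precision}f}",
            f"- product / [Nic]0: {report['ratio_product_to_nic']:.{precision}f}",
            f"- transferred intact: {report['pct_transferred_intact']:.0f} %",
        ]
    else:
        lines += [f"- keys: {sorted(report)}"]
    return "\n".join(lines) + "\n"
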