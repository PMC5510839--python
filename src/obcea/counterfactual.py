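"""Counterfactual projections of maternal deaths and intrapartum stillbirths.

Compares observed hospital-year outcomes with steady-state projections
anchored at a reference (pre-intervention) year:

* ``steady_MMR`` — the reference-year maternal mortality ratio applied to
  each later year's delivery volume;
* ``steady_CFR`` — the reference-year case-fatality rates for obstetric
  hemorrhage (OH) and hypertensive disorders of pregnancy (HDoP) applied to
  each later year's observed caseload, with other-cause deaths passed
  through (or optionally scaled by deliveries);
* ``steady_SBR`` — the reference-year intrapartum stillbirth rate applied
  to each later year's deliveries.

Deaths averted in a year are the projected minus the observed count.  A
national secular-trend adjustment (annualized rate of change, ARC) bounds
how much of the steady-MMR estimate a country-wide decline could explain.

Deliveries are used as the denominator of the MMR and SBR; the small gap
between deliveries and live births is ignored throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence

import pandas as pd

from .daly import (AgeProfile, DalyParameters, daly_per_maternal_death,
                   daly_per_stillbirth)

__all__ = [
    "HospitalYearRecord",
    "CounterfactualConfig",
    "AvertedSummary",
    "cfr",
    "predicted_deaths_steady_mmr",
    "predicted_deaths_steady_cfr",
    "averted_stillbirths_steady_sbr",
    "arc_adjustment",
    "averted_to_dalys",
    "read_series",
    "write_series",
    "series_to_frame",
    "round_half_up",
]

SERIES_COLUMNS = [
    "year", "deliveries", "maternal_deaths_total", "deaths_OH", "deaths_HDoP",
    "deaths_other", "cases_OH", "cases_HDoP", "stillbirths_intrapartum",
]

Condition = Literal["OH", "HDoP"]


class UndefinedCfrError(ZeroDivisionError):
    """Case-fatality rate requested for a condition with zero cases."""


class ConfigError(ValueError):
    """Counterfactual configuration inconsistent with the series."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class HospitalYearRecord:
    """One facility-year of deliveries, deaths by cause, caseloads and stillbirths.

    Counts are floats so that Monte Carlo perturbations (fractional
    pseudo-counts) can reuse the same container; :meth:`validate` enforces
    the strict integer-data invariants and is applied when reading real
    series from disk or generating synthetic ones.
    """

    year: int
    deliveries: float
    maternal_deaths_total: float
    deaths_OH: float
    deaths_HDoP: float
    deaths_other: float
    cases_OH: float
    cases_HDoP: float
    stillbirths_intrapartum: float

    def __post_init__(self) -> None:
        for name in SERIES_COLUMNS[1:]:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v!r})")
        if self.deliveries <= 0:
            raise ValueError("deliveries must be > 0")

    def validate(self) -> "HospitalYearRecord":
        """Check the accounting invariants of an observed (integer) record."""
        if abs(self.deaths_OH + self.deaths_HDoP + self.deaths_other
               - self.maternal_deaths_total) > 1e-9:
            raise ValueError(
                f"year {self.year}: cause-specific deaths do not sum to the total")
        for cond in ("OH", "HDoP"):
            deaths = getattr(self, f"deaths_{cond}")
            cases = getattr(self, f"cases_{cond}")
            if deaths > cases:
                raise ValueError(f"year {self.year}: deaths_{cond} > cases_{cond}")
            if cases > self.deliveries:
                raise ValueError(f"year {self.year}: cases_{cond} > deliveries")
        return self


@dataclass(frozen=True)
class CounterfactualConfig:
    method: Literal["steady_MMR", "steady_CFR", "steady_SBR"] = "steady_CFR"
    reference_year: int = 2007
    other_cause_mode: Literal["hold_observed", "scale_by_deliveries"] = "hold_observed"
    rounding: Literal["round_yearly", "keep_fractional"] = "round_yearly"
    arc_rate: float | None = None

    def __post_init__(self) -> None:
        if self.arc_rate is not None and not -1.0 < self.arc_rate < 1.0:
            raise ConfigError("arc_rate must lie in (-1, 1)")


@dataclass(frozen=True)
class AvertedSummary:
    """Per-year and total predicted, observed and averted counts."""

    method: str
    outcome: Literal["maternal_deaths", "stillbirths"]
    years: tuple[int, ...]
    predicted: tuple[float, ...]          # fractional projections
    predicted_rounded: tuple[int, ...]
    observed: tuple[float, ...]
    averted: tuple[float, ...]            # per the rounding convention
    averted_fractional: tuple[float, ...]

    @property
    def total_predicted(self) -> float:
        return sum(self.averted) + sum(self.observed)

    @property
    def total_averted(self) -> float:
        return sum(self.averted)

    @property
    def total_averted_fractional(self) -> float:
        return sum(self.averted_fractional)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years,
            "predicted": self.predicted,
            "predicted_rounded": self.predicted_rounded,
            "observed": self.observed,
            "averted": self.averted,
            "averted_fractional": self.averted_fractional,
        })

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total_averted"] = self.total_averted
        d["total_averted_fractional"] = self.total_averted_fractional
        return d


def read_series(path) -> list[HospitalYearRecord]:
    """Read a hospital-year series from CSV and validate every record."""
    frame = pd.read_csv(path)
    missing = set(SERIES_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"series CSV missing columns: {sorted(missing)}")
    records = [
        HospitalYearRecord(**{c: (int(row["year"]) if c == "year" else float(row[c]))
                              for c in SERIES_COLUMNS}).validate()
        for _, row in frame.iterrows()
    ]
    return sorted(records, key=lambda r: r.year)


def series_to_frame(series: Sequence[HospitalYearRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in series], columns=SERIES_COLUMNS)


def write_series(series: Sequence[HospitalYearRecord], path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def _reference(series: Sequence[HospitalYearRecord],
               config: CounterfactualConfig) -> HospitalYearRecord:
    for rec in series:
        if rec.year == config.reference_year:
            return rec
    raise ConfigError(
        f"reference year {config.reference_year} not present in the series")


def cfr(record: HospitalYearRecord, condition: Condition) -> float:
    """Case-fatality rate: condition deaths over condition cases, unrounded."""
    cases = getattr(record, f"cases_{condition}")
    deaths = getattr(record, f"deaths_{condition}")
    if cases <= 0:
        raise UndefinedCfrError(
            f"CFR undefined for {condition} in {record.year}: zero cases")
    return deaths / cases


def _summarize(method: str, outcome: str,
               series: Sequence[HospitalYearRecord],
               predicted: Sequence[float], observed: Sequence[float],
               config: CounterfactualConfig) -> AvertedSummary:
    rounded = [round_half_up(p) for p in predicted]
    averted_frac = [p - o for p, o in zip(predicted, observed)]
    if config.rounding == "round_yearly":
        averted = [float(r - o) for r, o in zip(rounded, observed)]
    else:
        averted = list(averted_frac)
    return AvertedSummary(
        method=method, outcome=outcome,
        years=tuple(r.year for r in series),
        predicted=tuple(predicted), predicted_rounded=tuple(rounded),
        observed=tuple(observed), averted=tuple(averted),
        averted_fractional=tuple(averted_frac))


def predicted_deaths_steady_mmr(series: Sequence[HospitalYearRecord],
                                config: CounterfactualConfig) -> AvertedSummary:
    """Project maternal deaths holding the reference-year MMR constant."""
    ref = _reference(series, config)
    ratio = ref.maternal_deaths_total / ref.deliveries
    predicted = [r.deliveries * ratio for r in series]
    observed = [r.maternal_deaths_total for r in series]
    return _summarize("steady_MMR", "maternal_deaths", series, predicted,
                      observed, config)


def predicted_deaths_steady_cfr(series: Sequence[HospitalYearRecord],
                                config: CounterfactualConfig) -> AvertedSummary:
    """Project maternal deaths holding reference-year condition CFRs constant.

    Per-year projection = cases_OH * CFR_OH(ref) + cases_HDoP * CFR_HDoP(ref)
    plus the other-cause term (observed other-cause deaths by default, or
    the reference-year other-cause count scaled by deliveries).
    """
    ref = _reference(series, config)
    cfr_oh = cfr(ref, "OH")
    cfr_hdop = cfr(ref, "HDoP")
    predicted = []
    for rec in series:
        if config.other_cause_mode == "hold_observed":
            other = rec.deaths_other
        else:
            other = ref.deaths_other * rec.deliveries / ref.deliveries
        predicted.append(rec.cases_OH * cfr_oh + rec.cases_HDoP * cfr_hdop + other)
    observed = [r.maternal_deaths_total for r in series]
    return _summarize("steady_CFR", "maternal_deaths", series, predicted,
                      observed, config)


def averted_stillbirths_steady_sbr(series: Sequence[HospitalYearRecord],
                                   config: CounterfactualConfig) -> AvertedSummary:
    """Project intrapartum stillbirths holding the reference-year SBR constant."""
    ref = _reference(series, config)
    rate = ref.stillbirths_intrapartum / ref.deliveries
    predicted = [r.deliveries * rate for r in series]
    observed = [r.stillbirths_intrapartum for r in series]
    return _summarize("steady_SBR", "stillbirths", series, predicted,
                      observed, config)


def arc_adjustment(series: Sequence[HospitalYearRecord],
                   config: CounterfactualConfig) -> float:
    """Deaths averted attributable to the national secular trend.

    Under an annualized rate of change ``arc_rate`` the no-intervention MMR
    declines as ``MMR_ref * (1 + arc_rate)^(year - ref)``; the attributable
    share is the steady-MMR projection minus this declining projection,
    summed over post-reference years.  Reported as context, never
    subtracted from the headline averted counts.
    """
    if config.arc_rate is None:
        raise ConfigError("arc_rate must be set for the ARC adjustment")
    ref = _reference(series, config)
    mmr_ref = ref.maternal_deaths_total / ref.deliveries
    total = 0.0
    for rec in series:
        t = rec.year - config.reference_year
        if t <= 0:
            continue
        total += rec.deliveries * mmr_ref * (1.0 - (1.0 + config.arc_rate) ** t)
    return total


def averted_to_dalys(summary: AvertedSummary, profile: AgeProfile,
                     params: DalyParameters) -> float:
    """Convert an averted-count summary to DALYs averted.

    Uses the fractional averted total (rounding is a presentation
    convention) and dispatches on the summary's outcome: maternal deaths
    carry YLL + YLD, stillbirths carry YLL only.
    """
    if summary.outcome == "maternal_deaths":
        per_event = daly_per_maternal_death(profile, params)
    elif summary.outcome == "stillbirths":
        per_event = daly_per_stillbirth(profile, params)
    else:  # pragma: no cover - outcome is a closed literal
        raise ValueError(f"unknown outcome {summary.outcome!r}")
    return summary.total_averted_fractional * per_event
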