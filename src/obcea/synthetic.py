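"""Synthetic hospital-year series and budget ledgers.

Emulates the structure of the observed study data — a growing delivery
caseload, rising prevalence of obstetric hemorrhage (OH) and hypertensive
disorders of pregnancy (HDoP), and falling case-fatality rates (the
intervention effect) — with the minimal count-noise model consistent with
the analysis: binomial caseloads and condition deaths, Poisson other-cause
deaths, binomial stillbirths.  Rate trends are log-linear so rates stay in
(0, 1) over long horizons.

:func:`known_truth` returns the closed-form expectations of the
counterfactual estimators under the generative model, enabling
parameter-recovery tests of the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .counterfactual import (CounterfactualConfig, HospitalYearRecord,
                             round_half_up)
from .costing import BudgetEntry, RoleRateTable, value_time

__all__ = ["ScenarioConfig", "generate_series", "generate_ledger", "known_truth"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative model for a facility-year outcome series.

    Defaults are calibrated to the observed 2007-2011 series: 6,049
    deliveries growing ~11.5%/yr; OH prevalence 0.9% rising ~44%/yr (log
    scale); HDoP prevalence 5.3% rising ~25%/yr; OH CFR 14.8% falling
    ~43%/yr; HDoP CFR 3.1% falling ~23%/yr; other-cause mortality
    ~2.0/1,000 deliveries; stillbirth rate 9.1/1,000 falling ~17%/yr.
    ``*_trend`` values are per-year log-rate slopes (intervention effects
    for the CFR trends); a null scenario sets the CFR and SBR trends to 0.

    Alternatively the smooth trends can be replaced by explicit per-year
    schedules (``*_by_year`` tuples, one value per year), which is how
    :meth:`from_series` calibrates a scenario exactly to an observed
    series.
    """

    start_year: int = 2007
    n_years: int = 5
    deliveries0: float = 6049.0
    delivery_growth: float = 0.115
    prev0_OH: float = 54 / 6049
    prev_trend_OH: float = 0.438
    prev0_HDoP: float = 321 / 6049
    prev_trend_HDoP: float = 0.252
    cfr0_OH: float = 8 / 54
    cfr_trend_OH: float = -0.556
    cfr0_HDoP: float = 10 / 321
    cfr_trend_HDoP: float = -0.259
    other_death_rate: float = 12 / 6049
    sbr0: float = 55 / 6049
    sbr_trend: float = -0.185
    deliveries_by_year: tuple[float, ...] | None = None
    prev_OH_by_year: tuple[float, ...] | None = None
    prev_HDoP_by_year: tuple[float, ...] | None = None
    cfr_OH_by_year: tuple[float, ...] | None = None
    cfr_HDoP_by_year: tuple[float, ...] | None = None
    other_rate_by_year: tuple[float, ...] | None = None
    sbr_by_year: tuple[float, ...] | None = None
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.deliveries0 <= 0:
            raise ValueError("deliveries0 must be > 0")
        for name in ("prev0_OH", "prev0_HDoP", "cfr0_OH", "cfr0_HDoP",
                     "other_death_rate", "sbr0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v!r})")
        for name in ("deliveries_by_year", "prev_OH_by_year",
                     "prev_HDoP_by_year", "cfr_OH_by_year",
                     "cfr_HDoP_by_year", "other_rate_by_year", "sbr_by_year"):
            sched = getattr(self, name)
            if sched is None:
                continue
            if len(sched) != self.n_years:
                raise ValueError(f"{name} must have one value per year")
            if name != "deliveries_by_year" and not all(
                    0.0 <= v <= 1.0 for v in sched):
                raise ValueError(f"{name} values must lie in [0, 1]")

    @classmethod
    def from_series(cls, series, **overrides) -> "ScenarioConfig":
        """Calibrate a scenario exactly to an observed hospital-year series:
        every yearly rate becomes the observed rate, so the noise-free
        generator reproduces the observed counts (up to rounding)."""
        series = sorted(series, key=lambda r: r.year)
        return cls(
            start_year=series[0].year,
            n_years=len(series),
            deliveries0=series[0].deliveries,
            deliveries_by_year=tuple(r.deliveries for r in series),
            prev_OH_by_year=tuple(r.cases_OH / r.deliveries for r in series),
            prev_HDoP_by_year=tuple(r.cases_HDoP / r.deliveries for r in series),
            cfr_OH_by_year=tuple(r.deaths_OH / r.cases_OH for r in series),
            cfr_HDoP_by_year=tuple(r.deaths_HDoP / r.cases_HDoP for r in series),
            other_rate_by_year=tuple(r.deaths_other / r.deliveries for r in series),
            sbr_by_year=tuple(r.stillbirths_intrapartum / r.deliveries
                              for r in series),
            **overrides,
        )

    # -- expected (noise-free) trajectories ---------------------------------

    def deliveries(self, t: int) -> float:
        if self.deliveries_by_year is not None:
            return self.deliveries_by_year[t]
        return self.deliveries0 * (1.0 + self.delivery_growth) ** t

    @staticmethod
    def _rate(base: float, trend: float, t: int) -> float:
        return min(base * math.exp(trend * t), 1.0)

    def prevalence(self, cond: str, t: int) -> float:
        sched = getattr(self, f"prev_{cond}_by_year")
        if sched is not None:
            return sched[t]
        return self._rate(getattr(self, f"prev0_{cond}"),
                          getattr(self, f"prev_trend_{cond}"), t)

    def cfr(self, cond: str, t: int) -> float:
        sched = getattr(self, f"cfr_{cond}_by_year")
        if sched is not None:
            return sched[t]
        return self._rate(getattr(self, f"cfr0_{cond}"),
                          getattr(self, f"cfr_trend_{cond}"), t)

    def other_rate(self, t: int) -> float:
        if self.other_rate_by_year is not None:
            return self.other_rate_by_year[t]
        return self.other_death_rate

    def sbr(self, t: int) -> float:
        if self.sbr_by_year is not None:
            return self.sbr_by_year[t]
        return self._rate(self.sbr0, self.sbr_trend, t)


def generate_series(config: ScenarioConfig) -> list[HospitalYearRecord]:
    """Draw one synthetic hospital-year series.

    With ``config.noise`` off, counts are the rounded expectations of the
    generative model (useful for calibration checks); otherwise cases,
    deaths and stillbirths carry binomial/Poisson noise.  Reproducible by
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for t in range(config.n_years):
        deliveries = round_half_up(config.deliveries(t))
        counts = {}
        for cond in ("OH", "HDoP"):
            prev, fatality = config.prevalence(cond, t), config.cfr(cond, t)
            if config.noise:
                cases = int(rng.binomial(deliveries, prev))
                deaths = int(rng.binomial(cases, fatality))
            else:
                cases = round_half_up(deliveries * prev)
                deaths = round_half_up(deliveries * prev * fatality)
            counts[cond] = (cases, deaths)
        if config.noise:
            other = int(rng.poisson(config.other_rate(t) * deliveries))
            stillbirths = int(rng.binomial(deliveries, config.sbr(t)))
        else:
            other = round_half_up(config.other_rate(t) * deliveries)
            stillbirths = round_half_up(deliveries * config.sbr(t))
        records.append(HospitalYearRecord(
            year=config.start_year + t,
            deliveries=deliveries,
            maternal_deaths_total=counts["OH"][1] + counts["HDoP"][1] + other,
            deaths_OH=counts["OH"][1],
            deaths_HDoP=counts["HDoP"][1],
            deaths_other=other,
            cases_OH=counts["OH"][0],
            cases_HDoP=counts["HDoP"][0],
            stillbirths_intrapartum=stillbirths,
        ).validate())
    return records


def known_truth(config: ScenarioConfig) -> dict[str, float]:
    """Closed-form expectations of the counterfactual estimators.

    Under the generative model the steady-CFR estimator (reference = first
    year, other-cause deaths held observed) is conditionally unbiased:
    given reference cases ``c > 0`` the estimated reference CFR
    ``deaths/c`` has expectation equal to the true CFR, so the expected
    estimate of deaths averted is the true expected averted count::

        E[averted] = sum_t E[cases_t] * (CFR_0 - CFR_t)

    summed over both conditions.  Analogous identities give the
    steady-MMR and steady-SBR expectations.  (All expectations ignore the
    integer rounding of expected deliveries, an error < 1 delivery/year.)
    """
    averted_cfr = 0.0
    averted_mmr = 0.0
    averted_sbr = 0.0
    mmr0 = (config.prevalence("OH", 0) * config.cfr("OH", 0)
            + config.prevalence("HDoP", 0) * config.cfr("HDoP", 0)
            + config.other_rate(0))
    for t in range(config.n_years):
        deliveries = config.deliveries(t)
        for cond in ("OH", "HDoP"):
            averted_cfr += (deliveries * config.prevalence(cond, t)
                            * (config.cfr(cond, 0) - config.cfr(cond, t)))
        mmr_t = (config.prevalence("OH", t) * config.cfr("OH", t)
                 + config.prevalence("HDoP", t) * config.cfr("HDoP", t)
                 + config.other_rate(t))
        averted_mmr += deliveries * (mmr0 - mmr_t)
        averted_sbr += deliveries * (config.sbr(0) - config.sbr(t))
    return {
        "averted_deaths_cfr": averted_cfr,
        "averted_deaths_mmr": averted_mmr,
        "averted_stillbirths_sbr": averted_sbr,
    }


def generate_ledger(n_trips: int, roster: list[tuple[str, int, float]],
                    rates: RoleRateTable | None = None, seed: int = 0,
                    organization_cost: float = 3000.0,
                    participant_cost: float = 20000.0,
                    host_cost: float = 4000.0,
                    cost_jitter: float = 0.25) -> list[BudgetEntry]:
    """Synthetic per-trip budget ledger.

    ``roster`` lists (role, headcount, days) per trip; its opportunity-cost
    value fills the time_value category exactly via :func:`value_time`.
    The three monetary categories are drawn uniformly within
    ``+/- cost_jitter`` of their per-trip means.
    """
    if n_trips < 0:
        raise ValueError("n_trips must be >= 0")
    rates = rates or RoleRateTable()
    rng = np.random.default_rng(seed)
    tv = value_time([(role, count * days) for role, count, days in roster], rates)
    entries: list[BudgetEntry] = []
    for i in range(n_trips):
        label = f"trip-{i + 1:02d}"
        for funder, mean in (("organization", organization_cost),
                             ("participant", participant_cost),
                             ("host_government", host_cost)):
            lo, hi = mean * (1 - cost_jitter), mean * (1 + cost_jitter)
            entries.append(BudgetEntry(label, funder, float(rng.uniform(lo, hi))))
        entries.append(BudgetEntry(label, "time_value", tv))
    return entries
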