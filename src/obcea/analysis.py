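"""End-to-end analysis: configuration, point estimates, and the Monte
Carlo model closure tying the DALY engine, counterfactuals, costing and
sensitivity machinery together.

The deterministic report evaluates four scenarios — discounted or
undiscounted DALYs, with or without stillbirths — at the base-case
parameter values.  The probabilistic analysis perturbs the yearly
prevalences, case-fatality rates and counts (normal, mean +/- 1.96 SE;
binomial SE for rates, Poisson SE for counts) and the DALY/costing
assumptions (uniform), and propagates each joint draw through the same
pipeline the point estimate uses.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import datasets
from .counterfactual import (AvertedSummary, CounterfactualConfig,
                             HospitalYearRecord, arc_adjustment,
                             averted_stillbirths_steady_sbr, averted_to_dalys,
                             predicted_deaths_steady_cfr,
                             predicted_deaths_steady_mmr, read_series)
from .costing import (DEFAULT_GDP_PER_CAPITA, BudgetEntry, cost_table, icer,
                      read_ledger, total_cost)
from .daly import AgeProfile, DalyParameters
from .sensitivity import (ParameterSpec, SimulationResult, TornadoEntry,
                          mid_parameters, run_monte_carlo, tornado)

__all__ = [
    "AnalysisConfig",
    "default_sensitivity_specs",
    "build_model",
    "point_estimates",
    "run_psa",
    "run_tornado",
]

#: National secular decline in the maternal mortality ratio over the study
#: period (annualized rate of change), used for the attribution bound.
DEFAULT_ARC_RATE = -0.036


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce the end-to-end analysis."""

    series_path: str | None = None   # None -> packaged fixture
    ledger_path: str | None = None
    daly_params: DalyParameters = field(default_factory=DalyParameters)
    profile: AgeProfile = field(default_factory=AgeProfile)
    counterfactual: CounterfactualConfig = field(
        default_factory=lambda: CounterfactualConfig(arc_rate=DEFAULT_ARC_RATE))
    gdp_per_capita: float = DEFAULT_GDP_PER_CAPITA
    include_stillbirths: bool = True
    time_value_variation: float = 0.25
    seed: int = 12345
    n_draws: int = 10_000

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from a JSON or YAML config file."""
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        kwargs = dict(raw)
        if "daly_params" in kwargs:
            kwargs["daly_params"] = DalyParameters.from_dict(kwargs["daly_params"])
        if "profile" in kwargs:
            kwargs["profile"] = AgeProfile.from_dict(kwargs["profile"])
        if "counterfactual" in kwargs:
            kwargs["counterfactual"] = CounterfactualConfig(**kwargs["counterfactual"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["daly_params"] = self.daly_params.to_dict()
        d["profile"] = self.profile.to_dict()
        return d

    def load_series(self) -> list[HospitalYearRecord]:
        if self.series_path is None:
            return datasets.load_hospital_years()
        return read_series(self.series_path)

    def load_ledger(self) -> list[BudgetEntry]:
        if self.ledger_path is None:
            return datasets.load_budget()
        return read_ledger(self.ledger_path)


# ---------------------------------------------------------------------------
# sensitivity specifications
# ---------------------------------------------------------------------------

def default_sensitivity_specs(series: Sequence[HospitalYearRecord],
                              ledger: Sequence[BudgetEntry],
                              config: AnalysisConfig | None = None,
                              ) -> list[ParameterSpec]:
    """The standard probabilistic-sensitivity parameter set.

    DALY assumptions and the professional-time valuation vary uniformly
    within their stated ranges; each post-reference year's prevalences,
    CFRs and counts vary normally with bounds at +/- 1.96 SE (binomial SE
    for rates, Poisson SE for counts), truncated at zero for counts.
    """
    config = config or AnalysisConfig()
    p = config.profile
    specs = [
        ParameterSpec("average_age", "uniform", 26.9, p.average_age_at_death, 32.9),
        ParameterSpec("remaining_life_expectancy", "uniform",
                      39.1, p.remaining_life_expectancy, 47.7),
        ParameterSpec("stillbirth_life_expectancy", "uniform",
                      55.1, p.stillbirth_life_expectancy, 67.3),
        ParameterSpec("disability_weight", "uniform", 0.2,
                      config.daly_params.disability_weight_D, 0.4),
        ParameterSpec("disability_multiplier", "uniform", 1.0,
                      config.daly_params.disability_multiplier_M, 3.0),
    ]
    tv = total_cost(ledger).by_funder["time_value"]
    v = config.time_value_variation
    specs.append(ParameterSpec("professional_time", "uniform",
                               (1 - v) * tv, tv, (1 + v) * tv))

    ref_year = config.counterfactual.reference_year
    for rec in series:
        if rec.year <= ref_year:
            continue
        y = rec.year
        for cond in ("OH", "HDoP"):
            cases = getattr(rec, f"cases_{cond}")
            prev = cases / rec.deliveries
            se_prev = math.sqrt(prev * (1 - prev) / rec.deliveries)
            specs.append(ParameterSpec(
                f"prev_{cond}_{y}", "normal",
                prev - 1.96 * se_prev, prev, prev + 1.96 * se_prev,
                truncate_at_zero=True))
            fatality = getattr(rec, f"deaths_{cond}") / cases
            se_cfr = math.sqrt(fatality * (1 - fatality) / cases)
            specs.append(ParameterSpec(
                f"cfr_{cond}_{y}", "normal",
                fatality - 1.96 * se_cfr, fatality, fatality + 1.96 * se_cfr,
                truncate_at_zero=True))
        deaths = rec.maternal_deaths_total
        se_d = math.sqrt(deaths)
        specs.append(ParameterSpec(
            f"maternal_deaths_{y}", "normal",
            deaths - 1.96 * se_d, deaths, deaths + 1.96 * se_d,
            truncate_at_zero=True))
        sb = rec.stillbirths_intrapartum
        se_sb = math.sqrt(sb)
        specs.append(ParameterSpec(
            f"stillbirths_{y}", "normal",
            sb - 1.96 * se_sb, sb, sb + 1.96 * se_sb,
            truncate_at_zero=True))
    return specs


# ---------------------------------------------------------------------------
# the pipeline closure
# ---------------------------------------------------------------------------

def _perturb_series(series: Sequence[HospitalYearRecord],
                    params: Mapping[str, float],
                    ref_year: int, method: str) -> list[HospitalYearRecord]:
    """Apply one parameter draw to the observed series.

    The reference year is never perturbed.  Cases follow the drawn
    prevalences, condition deaths the drawn CFRs (clipped to [0, 1]); the
    yearly total is the sum of parts for the CFR method, or the drawn
    total-death count for the MMR method.  The resulting fractional
    pseudo-counts deliberately bypass the integer-data validation.
    """
    out = []
    for rec in series:
        y = rec.year
        if y <= ref_year:
            out.append(rec)
            continue
        new = {}
        for cond in ("OH", "HDoP"):
            prev = params.get(f"prev_{cond}_{y}",
                              getattr(rec, f"cases_{cond}") / rec.deliveries)
            fat = params.get(f"cfr_{cond}_{y}",
                             getattr(rec, f"deaths_{cond}")
                             / getattr(rec, f"cases_{cond}"))
            fat = min(max(fat, 0.0), 1.0)
            cases = max(prev, 0.0) * rec.deliveries
            new[f"cases_{cond}"] = cases
            new[f"deaths_{cond}"] = cases * fat
        if method == "steady_MMR":
            total = max(params.get(f"maternal_deaths_{y}",
                                   rec.maternal_deaths_total), 0.0)
        else:
            total = (new["deaths_OH"] + new["deaths_HDoP"] + rec.deaths_other)
        out.append(HospitalYearRecord(
            year=y, deliveries=rec.deliveries,
            maternal_deaths_total=total,
            deaths_OH=new["deaths_OH"], deaths_HDoP=new["deaths_HDoP"],
            deaths_other=rec.deaths_other,
            cases_OH=new["cases_OH"], cases_HDoP=new["cases_HDoP"],
            stillbirths_intrapartum=max(
                params.get(f"stillbirths_{y}", rec.stillbirths_intrapartum), 0.0),
        ))
    return out


def build_model(series: Sequence[HospitalYearRecord],
                ledger: Sequence[BudgetEntry],
                config: AnalysisConfig | None = None):
    """Return the end-to-end closure mapping a parameter draw to outputs.

    Outputs: averted maternal deaths and stillbirths (fractional totals),
    DALYs averted (maternal, stillbirth, total per the stillbirth flag),
    total cost, and the ICER.
    """
    config = config or AnalysisConfig()
    cf = dataclasses.replace(config.counterfactual, rounding="keep_fractional")
    breakdown = total_cost(ledger)
    nontime_cost = breakdown.total - breakdown.by_funder["time_value"]
    base_tv = breakdown.by_funder["time_value"]
    ref_year = cf.reference_year
    base_profile = config.profile
    base_params = config.daly_params

    def model(params: Mapping[str, float]) -> dict[str, float]:
        profile = dataclasses.replace(
            base_profile,
            average_age_at_death=params.get(
                "average_age", base_profile.average_age_at_death),
            remaining_life_expectancy=params.get(
                "remaining_life_expectancy",
                base_profile.remaining_life_expectancy),
            stillbirth_life_expectancy=params.get(
                "stillbirth_life_expectancy",
                base_profile.stillbirth_life_expectancy),
        )
        dparams = dataclasses.replace(
            base_params,
            disability_weight_D=min(max(params.get(
                "disability_weight", base_params.disability_weight_D), 0.0), 1.0),
            disability_multiplier_M=max(params.get(
                "disability_multiplier", base_params.disability_multiplier_M), 0.0),
        )
        perturbed = _perturb_series(series, params, ref_year, cf.method)
        if cf.method == "steady_MMR":
            maternal = predicted_deaths_steady_mmr(perturbed, cf)
        else:
            maternal = predicted_deaths_steady_cfr(perturbed, cf)
        stillbirths = averted_stillbirths_steady_sbr(perturbed, cf)

        dalys_m = averted_to_dalys(maternal, profile, dparams)
        dalys_sb = averted_to_dalys(stillbirths, profile, dparams)
        dalys_total = dalys_m + (dalys_sb if config.include_stillbirths else 0.0)
        cost = nontime_cost + params.get("professional_time", base_tv)
        result = icer(cost, dalys_total, config.gdp_per_capita)
        return {
            "averted_maternal_deaths": maternal.total_averted_fractional,
            "averted_stillbirths": stillbirths.total_averted_fractional,
            "dalys_maternal": dalys_m,
            "dalys_stillbirths": dalys_sb,
            "dalys_total": dalys_total,
            "total_cost": cost,
            "icer": result.icer,
        }

    return model


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def point_estimates(config: AnalysisConfig | None = None) -> dict:
    """Deterministic base-case report.

    Averted-count summaries under all three counterfactuals, the cost
    breakdown, the secular-trend attribution bound, and the four scenario
    rows (discounted / undiscounted x with / without stillbirths).
    """
    config = config or AnalysisConfig()
    series = config.load_series()
    ledger = config.load_ledger()
    cf = config.counterfactual

    maternal_cfr = predicted_deaths_steady_cfr(series, cf)
    maternal_mmr = predicted_deaths_steady_mmr(series, cf)
    stillbirths = averted_stillbirths_steady_sbr(series, cf)
    breakdown = total_cost(ledger)
    headline = (maternal_mmr if cf.method == "steady_MMR" else maternal_cfr)

    scenarios = {}
    for discounted in (True, False):
        dparams = (config.daly_params if discounted
                   else config.daly_params.undiscounted())
        dalys_m = averted_to_dalys(headline, config.profile, dparams)
        dalys_sb = averted_to_dalys(stillbirths, config.profile, dparams)
        for with_sb in (True, False):
            dalys = dalys_m + (dalys_sb if with_sb else 0.0)
            result = icer(breakdown.total, dalys, config.gdp_per_capita)
            key = (f"{'discounted' if discounted else 'undiscounted'}"
                   f"_{'with' if with_sb else 'without'}_stillbirths")
            scenarios[key] = {"dalys_averted": dalys, **result.to_dict()}

    report = {
        "maternal_steady_CFR": maternal_cfr.to_dict(),
        "maternal_steady_MMR": maternal_mmr.to_dict(),
        "stillbirths_steady_SBR": stillbirths.to_dict(),
        "cost": breakdown.to_dict(),
        "cost_table_total": float(cost_table(ledger).loc["TOTAL", "total_rounded"]),
        "scenarios": scenarios,
    }
    if cf.arc_rate is not None:
        report["arc_attributable_deaths"] = arc_adjustment(series, cf)
    return report


def run_psa(config: AnalysisConfig | None = None,
            n_draws: int | None = None,
            seed: int | None = None) -> SimulationResult:
    """Probabilistic sensitivity analysis with the standard parameter set."""
    config = config or AnalysisConfig()
    series = config.load_series()
    ledger = config.load_ledger()
    specs = default_sensitivity_specs(series, ledger, config)
    model = build_model(series, ledger, config)
    return run_monte_carlo(model, specs,
                           n_draws=n_draws or config.n_draws,
                           seed=config.seed if seed is None else seed)


def run_tornado(config: AnalysisConfig | None = None,
                output: str = "icer") -> list[TornadoEntry]:
    """One-way sensitivity of the ICER over the standard parameter set."""
    config = config or AnalysisConfig()
    series = config.load_series()
    ledger = config.load_ledger()
    specs = default_sensitivity_specs(series, ledger, config)
    model = build_model(series, ledger, config)
    return tornado(model, specs, mid_parameters(specs), output=output)
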