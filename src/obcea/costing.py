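"""Program costing and incremental cost-effectiveness ratio (ICER).

Aggregates a budget ledger of dated line items across four funder
categories — the implementing organization, individual participants, the
host government, and the imputed opportunity-cost value of volunteered
professional time — and computes the ICER against GDP-per-capita
thresholds (WHO-CHOICE convention: below 1x GDP per capita is highly
cost-effective, below 3x is cost-effective).

Amounts are real base-year USD.  Published budget tables round each line
item to the nearest $100; :func:`cost_table` reproduces that presentation
convention, while :func:`total_cost` always sums the raw amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BudgetEntry",
    "RoleRateTable",
    "CostBreakdown",
    "IcerResult",
    "FUNDERS",
    "total_cost",
    "cost_table",
    "value_time",
    "adjust_inflation",
    "icer",
    "read_ledger",
    "write_ledger",
]

FUNDERS = ("organization", "participant", "host_government", "time_value")

Funder = Literal["organization", "participant", "host_government", "time_value"]

#: WHO-CHOICE GDP-per-capita benchmark (USD), 2007-2011 Ghana average.
DEFAULT_GDP_PER_CAPITA = 1268.0


class UndefinedIcerError(ValueError):
    """ICER requested with zero or negative incremental DALYs averted."""


@dataclass(frozen=True)
class BudgetEntry:
    """One cost line item: a trip, meeting or capital purchase, by funder."""

    label: str
    funder: Funder
    amount: float

    def __post_init__(self) -> None:
        if self.funder not in FUNDERS:
            raise ValueError(f"unknown funder {self.funder!r}; expected one of {FUNDERS}")
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValueError(f"amount must be finite and >= 0 (got {self.amount!r})")


@dataclass(frozen=True)
class RoleRateTable:
    """Daily opportunity-cost rates (USD per 10-hour day) by professional role."""

    rates: Mapping[str, float] = None

    _DEFAULTS = {
        "physician": 1100.0,
        "nurse_anesthetist": 750.0,
        "midwife": 500.0,
        "engineer": 500.0,
        "nurse_practitioner": 500.0,
        "consultant": 500.0,
        "nurse": 330.0,
        "resident": 330.0,
        "biostatistician": 330.0,
    }

    def __post_init__(self) -> None:
        rates = dict(self._DEFAULTS if self.rates is None else self.rates)
        if any(v <= 0 for v in rates.values()):
            raise ValueError("all role rates must be > 0")
        object.__setattr__(self, "rates", rates)

    def rate(self, role: str) -> float:
        try:
            return self.rates[role]
        except KeyError:
            raise ValueError(f"unknown role {role!r}; known roles: {sorted(self.rates)}") from None


@dataclass(frozen=True)
class CostBreakdown:
    total: float
    by_funder: dict[str, float]
    shares: dict[str, float]

    def to_dict(self) -> dict:
        return {"total": self.total, "by_funder": self.by_funder, "shares": self.shares}


@dataclass(frozen=True)
class IcerResult:
    total_cost: float
    total_dalys_averted: float
    icer: float
    threshold_class: Literal["highly_cost_effective", "cost_effective", "not_cost_effective"]
    gdp_per_capita: float

    def to_dict(self) -> dict:
        return {
            "total_cost": self.total_cost,
            "total_dalys_averted": self.total_dalys_averted,
            "icer": self.icer,
            "threshold_class": self.threshold_class,
            "gdp_per_capita": self.gdp_per_capita,
        }


def total_cost(ledger: Sequence[BudgetEntry]) -> CostBreakdown:
    """Sum a ledger's raw amounts, with per-funder subtotals and shares."""
    if not ledger:
        raise ValueError("ledger is empty")
    by_funder = {f: 0.0 for f in FUNDERS}
    for entry in ledger:
        by_funder[entry.funder] += entry.amount
    total = sum(by_funder.values())
    shares = {f: (v / total if total > 0 else 0.0) for f, v in by_funder.items()}
    return CostBreakdown(total=total, by_funder=by_funder, shares=shares)


def cost_table(ledger: Sequence[BudgetEntry], round_to: int = 100) -> pd.DataFrame:
    """Per-label cost table in the published presentation convention.

    Each label's funder amounts are summed and the label total is rounded
    to the nearest ``round_to`` dollars; the TOTAL row sums the rounded
    label totals (so the grand total matches a table whose rows were
    rounded before summation).
    """
    if not ledger:
        raise ValueError("ledger is empty")
    frame = pd.DataFrame([(e.label, e.funder, e.amount) for e in ledger],
                         columns=["label", "funder", "amount"])
    labels = list(dict.fromkeys(frame["label"]))  # preserve ledger order
    wide = (frame.pivot_table(index="label", columns="funder", values="amount",
                              aggfunc="sum", fill_value=0.0)
            .reindex(labels)
            .reindex(columns=list(FUNDERS), fill_value=0.0))
    wide["total"] = wide.sum(axis=1)
    # half-up, not banker's: published tables round $x50 ties upward
    wide["total_rounded"] = np.floor(wide["total"] / round_to + 0.5) * round_to
    total_row = wide.sum(axis=0)
    total_row.name = "TOTAL"
    return pd.concat([wide, total_row.to_frame().T])


def value_time(person_days: Iterable[tuple[str, float]],
               rates: RoleRateTable | None = None) -> float:
    """Opportunity-cost value of volunteered professional time.

    ``person_days`` is an iterable of (role, days); the value is the sum of
    days times the role's daily rate.
    """
    rates = rates or RoleRateTable()
    total = 0.0
    for role, days in person_days:
        if days < 0:
            raise ValueError("days must be >= 0")
        total += days * rates.rate(role)
    return total


def adjust_inflation(amount: float, year: int, index: Mapping[int, float],
                     base_year: int = 2015) -> float:
    """Convert a nominal amount to base-year dollars with a deflator index.

    Returns ``amount * index[base_year] / index[year]``; an identity index
    leaves the amount unchanged.
    """
    try:
        num, den = index[base_year], index[year]
    except KeyError as exc:
        raise KeyError(f"year {exc.args[0]} missing from the deflator index") from None
    if den <= 0:
        raise ValueError("deflator values must be > 0")
    return amount * num / den


def icer(total_cost: float, dalys_averted: float,
         gdp_per_capita: float = DEFAULT_GDP_PER_CAPITA,
         comparator_cost: float = 0.0) -> IcerResult:
    """Incremental cost-effectiveness ratio and WHO-CHOICE threshold class.

    ICER = (program cost - comparator cost) / DALYs averted.  The
    comparator (null) cost defaults to zero: the counterfactual program
    spends nothing.
    """
    if dalys_averted <= 0:
        raise UndefinedIcerError(
            "ICER undefined: DALYs averted must be > 0 (no effect or harm)")
    value = (total_cost - comparator_cost) / dalys_averted
    if value < gdp_per_capita:
        cls = "highly_cost_effective"
    elif value < 3.0 * gdp_per_capita:
        cls = "cost_effective"
    else:
        cls = "not_cost_effective"
    return IcerResult(total_cost=total_cost, total_dalys_averted=dalys_averted,
                      icer=value, threshold_class=cls,
                      gdp_per_capita=gdp_per_capita)


def read_ledger(path) -> list[BudgetEntry]:
    """Read a budget ledger CSV with columns label, funder, amount."""
    frame = pd.read_csv(path)
    missing = {"label", "funder", "amount"} - set(frame.columns)
    if missing:
        raise ValueError(f"ledger CSV missing columns: {sorted(missing)}")
    return [BudgetEntry(label=str(r.label), funder=str(r.funder), amount=float(r.amount))
            for r in frame.itertuples()]


def write_ledger(ledger: Sequence[BudgetEntry], path) -> None:
    pd.DataFrame([(e.label, e.funder, e.amount) for e in ledger],
                 columns=["label", "funder", "amount"]).to_csv(path, index=False)
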