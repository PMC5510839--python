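"""Probabilistic (Monte Carlo) and one-way (tornado) sensitivity analysis.

Parameters are declared as :class:`ParameterSpec` (uniform on [low, high]
or normal with mean ``mid`` and sd ``(high - mid) / 1.96``, i.e. bounds
read as mean +/- 1.96 SE).  :func:`run_monte_carlo` propagates independent
joint draws through an arbitrary model closure and summarizes each output
by its mean and percentile 95% interval.  :func:`tornado` evaluates the
model at each parameter's 5th and 95th percentile with all others held at
their mid value, ranking parameters by the induced output swing;
"variance share" is the normalized squared swing.  A rank-correlation
based contribution-to-variance measure is also available from the raw
Monte Carlo draws via :func:`variance_contributions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterSpec",
    "SimulationResult",
    "TornadoEntry",
    "draw_parameters",
    "run_monte_carlo",
    "tornado",
    "variance_contributions",
]

ModelFn = Callable[[Mapping[str, float]], Mapping[str, float]]


@dataclass(frozen=True)
class ParameterSpec:
    """Declarative distribution for one model input.

    ``uniform`` draws on [low, high]; ``normal`` draws from
    N(mid, ((high - mid)/1.96)^2).  ``truncate_at_zero`` clips draws at 0,
    for count-like quantities.  ``target`` names the model input the draw
    perturbs (free-form; the model closure interprets it).
    """

    name: str
    kind: Literal["uniform", "normal"]
    low: float
    mid: float
    high: float
    target: str = ""
    truncate_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not (self.low <= self.mid <= self.high):
            raise ValueError(
                f"{self.name}: require low <= mid <= high "
                f"(got {self.low}, {self.mid}, {self.high})")
        if self.kind == "normal" and self.high > self.mid and self.sd <= 0:
            raise ValueError(f"{self.name}: normal sd must be > 0")

    @property
    def sd(self) -> float:
        """Standard deviation implied by reading high as mid + 1.96 sd."""
        return (self.high - self.mid) / 1.96

    @property
    def degenerate(self) -> bool:
        return self.low == self.high

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.degenerate:
            out = np.full(size, self.mid) if size is not None else self.mid
            return out
        if self.kind == "uniform":
            out = rng.uniform(self.low, self.high, size=size)
        else:
            out = rng.normal(self.mid, self.sd, size=size)
        if self.truncate_at_zero:
            out = np.maximum(out, 0.0)
        return out

    def percentile(self, q: float) -> float:
        """Quantile of the spec's distribution (q in [0, 1])."""
        if self.degenerate:
            return self.mid
        if self.kind == "uniform":
            value = self.low + q * (self.high - self.low)
        else:
            value = stats.norm.ppf(q, loc=self.mid, scale=self.sd)
        if self.truncate_at_zero:
            value = max(value, 0.0)
        return float(value)


@dataclass(frozen=True)
class SimulationResult:
    """Monte Carlo summary: per-output mean and percentile 95% interval."""

    summary: pd.DataFrame        # index: output name; columns mean, p2.5, p97.5
    draws: pd.DataFrame          # one row per accepted draw (params + outputs)
    n_draws: int
    seed: int
    n_rejected: int = 0

    def mean(self, output: str) -> float:
        return float(self.summary.loc[output, "mean"])

    def ci(self, output: str) -> tuple[float, float]:
        row = self.summary.loc[output]
        return float(row["p2.5"]), float(row["p97.5"])

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "n_rejected": self.n_rejected,
            "outputs": {
                name: {"mean": float(row["mean"]),
                       "p2.5": float(row["p2.5"]),
                       "p97.5": float(row["p97.5"])}
                for name, row in self.summary.iterrows()
            },
        }


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    value_at_p5: float
    value_at_p95: float
    swing: float
    variance_share: float

    def to_dict(self) -> dict:
        return {"name": self.name, "value_at_p5": self.value_at_p5,
                "value_at_p95": self.value_at_p95, "swing": self.swing,
                "variance_share": self.variance_share}


def draw_parameters(specs: Sequence[ParameterSpec],
                    rng: np.random.Generator | int) -> dict[str, float]:
    """One joint draw, independent across parameters."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    _check_unique(specs)
    return {spec.name: float(spec.sample(rng)) for spec in specs}


def _check_unique(specs: Sequence[ParameterSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter names in specs")


def mid_parameters(specs: Sequence[ParameterSpec]) -> dict[str, float]:
    """All parameters at their mid (base-case) value."""
    return {s.name: s.mid for s in specs}


def run_monte_carlo(model: ModelFn, specs: Sequence[ParameterSpec],
                    n_draws: int, seed: int,
                    max_reject_fraction: float = 0.01) -> SimulationResult:
    """Propagate ``n_draws`` independent joint draws through ``model``.

    Draws on which the model raises are recorded and rejected; if more
    than ``max_reject_fraction`` of draws fail the run aborts with a
    diagnostic carrying the first failure.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    _check_unique(specs)
    rng = np.random.default_rng(seed)
    # draw the full matrix up front: reproducible and column-wise vectorized
    matrix = {spec.name: np.atleast_1d(spec.sample(rng, size=n_draws))
              for spec in specs}

    rows: list[dict[str, float]] = []
    failures: list[tuple[int, Exception]] = []
    for i in range(n_draws):
        params = {name: float(col[i]) for name, col in matrix.items()}
        try:
            outputs = model(params)
        except Exception as exc:  # noqa: BLE001 - rejection sampling by contract
            failures.append((i, exc))
            continue
        rows.append({**params, **{k: float(v) for k, v in outputs.items()}})

    if len(failures) > max_reject_fraction * n_draws:
        first = failures[0]
        raise RuntimeError(
            f"{len(failures)}/{n_draws} Monte Carlo draws failed "
            f"(> {max_reject_fraction:.0%}); first failure at draw "
            f"{first[0]}: {first[1]!r}")

    draws = pd.DataFrame(rows)
    output_names = [c for c in draws.columns if c not in matrix]
    summary = pd.DataFrame({
        "mean": draws[output_names].mean(),
        "p2.5": draws[output_names].quantile(0.025),
        "p97.5": draws[output_names].quantile(0.975),
    })
    return SimulationResult(summary=summary, draws=draws, n_draws=n_draws,
                            seed=seed, n_rejected=len(failures))


def tornado(model: ModelFn, specs: Sequence[ParameterSpec],
            base: Mapping[str, float] | None = None, output: str = "icer",
            min_share: float = 0.01) -> list[TornadoEntry]:
    """One-way sensitivity: swing of ``output`` across each parameter's
    5th-95th percentile range, others held at base (mid) values.

    Entries with variance share (normalized squared swing) below
    ``min_share`` are dropped; the rest are sorted by swing, descending.
    """
    _check_unique(specs)
    base = dict(base) if base is not None else mid_parameters(specs)
    raw: list[tuple[str, float, float]] = []
    for spec in specs:
        lo_params = {**base, spec.name: spec.percentile(0.05)}
        hi_params = {**base, spec.name: spec.percentile(0.95)}
        lo_val = float(model(lo_params)[output])
        hi_val = float(model(hi_params)[output])
        raw.append((spec.name, lo_val, hi_val))
    total_sq = sum((hi - lo) ** 2 for _, lo, hi in raw)
    entries = []
    for name, lo, hi in raw:
        swing = abs(hi - lo)
        share = swing ** 2 / total_sq if total_sq > 0 else 0.0
        if share >= min_share:
            entries.append(TornadoEntry(name=name, value_at_p5=lo,
                                        value_at_p95=hi, swing=swing,
                                        variance_share=share))
    return sorted(entries, key=lambda e: e.swing, reverse=True)


def variance_contributions(draws: pd.DataFrame, output: str,
                           parameter_names: Sequence[str]) -> pd.Series:
    """Rank-correlation contribution to variance from Monte Carlo draws.

    Squared Spearman correlation of each parameter with the output,
    normalized to sum to 1 — the convention used by spreadsheet Monte
    Carlo tools for "contribution to variance" charts.
    """
    rho2 = {}
    for name in parameter_names:
        if draws[name].nunique() <= 1:
            rho2[name] = 0.0
            continue
        rho, _ = stats.spearmanr(draws[name], draws[output])
        rho2[name] = 0.0 if math.isnan(rho) else rho ** 2
    series = pd.Series(rho2, name="variance_contribution")
    total = series.sum()
    return series / total if total > 0 else series
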