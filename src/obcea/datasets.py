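"""Packaged fixtures: the study's hospital-year outcome series, its
program budget ledger, and a synthetic life table for interpolation.

The hospital-year series and budget ledger transcribe the published study
tables.  The life table is *synthetic*: a plausible two-reference-year
grid for exercising bilinear interpolation, not a national life table.
Checksums guard against silent fixture edits.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

from .counterfactual import HospitalYearRecord, read_series
from .costing import BudgetEntry, read_ledger
from .daly import LifeTable

__all__ = [
    "fixture_path",
    "load_hospital_years",
    "load_budget",
    "load_life_table",
    "verify_checksums",
]

_DATA = resources.files("obcea") / "data"


def fixture_path(name: str) -> Path:
    path = Path(str(_DATA / name))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path


def load_hospital_years() -> list[HospitalYearRecord]:
    """The 2007-2011 hospital-year outcome series (observed data)."""
    return read_series(fixture_path("hospital_years.csv"))


def load_budget() -> list[BudgetEntry]:
    """The program budget ledger, 2015 USD, by funder category."""
    return read_ledger(fixture_path("budget.csv"))


def load_life_table() -> LifeTable:
    """Synthetic two-year life-table grid (for interpolation only)."""
    return LifeTable.from_csv(fixture_path("life_table_synthetic.csv"))


def verify_checksums() -> None:
    """Raise if any packaged fixture differs from its recorded SHA-256."""
    manifest = fixture_path("CHECKSUMS.sha256").read_text().strip().splitlines()
    for line in manifest:
        digest, name = line.split()
        actual = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
        if actual != digest:
            raise RuntimeError(f"fixture {name} checksum mismatch: {actual} != {digest}")
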