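"""Life-expectancy lookup and residual-life -> biological-age conversion.

Biological age is defined as

    bio_age = avg_life_expectancy(region, year, sex) - predicted_residual_life

against government-published average life expectancy.  The packaged table
transcribes the Taiwanese per-city values for ROC year 111 (Gregorian
2022): 22 cities/counties plus the national ("All") row, each with total /
male / female columns.  A query with no exact (region, year) row — e.g.
Matsu, which the published series does not include, or a year outside the
published range — falls back to the latest national value for the
requested sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

ROC_OFFSET = 1911  # ROC year 111 == Gregorian 2022


class LifeTableParseError(ValueError):
    pass


@dataclass
class LifeExpectancyTable:
    """(region, year, sex) -> average life expectancy, with national fallback."""

    entries: pd.DataFrame  # columns: region, year (Gregorian), total, male, female
    latest_national: dict[str, float]  # sex -> years

    def lookup(self, region: str, year: int, sex: str, calendar: str = "roc") -> tuple[float, str]:
        """Return (avg life expectancy in years, source tag).

        ``year`` is interpreted as an ROC calendar year by default
        (``calendar="gregorian"`` accepts Western years).  Exact
        (region, year, sex) matches are tagged ``"exact-lookup"``;
        anything else returns the latest national per-sex value tagged
        ``"national-fallback"``.
        """
        if sex not in ("male", "female", "total"):
            raise ValueError(f"sex must be 'male', 'female' or 'total', got {sex!r}")
        if calendar == "roc":
            year = year + ROC_OFFSET
        elif calendar != "gregorian":
            raise ValueError("calendar must be 'roc' or 'gregorian'")
        hit = self.entries[(self.entries["region"] == region) & (self.entries["year"] == year)]
        if len(hit) == 1:
            return float(hit.iloc[0][sex]), "exact-lookup"
        return self.latest_national[sex], "national-fallback"


def load_life_expectancy(source: str | Path | None = None) -> LifeExpectancyTable:
    """Load a life-expectancy CSV (region, year, total, male, female).

    With no argument, loads the packaged transcription of the published
    per-city table.  Years in the file are ROC-calendar and stored
    internally as Gregorian.  Duplicate (region, year) rows and
    non-numeric cells are parse errors reported with their row number.
    """
    if source is None:
        with resources.as_file(resources.files("bioagekit.data") / "life_expectancy_tw.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(source)

    required = ["region", "year", "total", "male", "female"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LifeTableParseError(f"missing column(s): {missing}")
    for col in ("year", "total", "male", "female"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(df.index[bad | df[col].isna()][0]) + 2  # 1-based + header
            raise LifeTableParseError(f"non-numeric or empty cell in column {col!r} at file row {row}")
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["region", "year"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise LifeTableParseError(f"duplicated (region, year) at file row {row}")

    df = df.copy()
    df["year"] = df["year"].astype(int) + ROC_OFFSET

    # sanity asserted at load: published female expectancy exceeds male everywhere
    if not (df["female"] >= df["male"]).all():
        raise LifeTableParseError("table violates female >= male life expectancy")

    national = df[df["region"] == "All"]
    if len(national) == 0:
        national = df  # degenerate user table: fall back to the latest row overall
    latest = national.loc[national["year"].idxmax()]
    latest_national = {s: float(latest[s]) for s in ("total", "male", "female")}
    return LifeExpectancyTable(entries=df, latest_national=latest_national)


def lookup_avg_age(
    table: LifeExpectancyTable, region: str, year: int, sex: str, calendar: str = "roc"
) -> tuple[float, str]:
    """Functional alias for :meth:`LifeExpectancyTable.lookup`."""
    return table.lookup(region, year, sex, calendar=calendar)


def to_biological_age(avg_age: float, residual_life_pred: float):
    """bio_age = avg_age − predicted residual life.

    Negative results are permitted (a predicted residual life exceeding the
    regional life expectancy) but flagged with a warning.  Accepts scalars
    or aligned arrays.
    """
    import numpy as np

    bio = np.asarray(avg_age, dtype=float) - np.asarray(residual_life_pred, dtype=float)
    if not np.all(np.isfinite(bio)):
        raise ValueError("inputs must be finite")
    if np.any(bio < 0):
        warnings.warn("negative biological age produced", stacklevel=2)
    if bio.ndim == 0:
        return float(bio)
    return bio


@dataclass
class BioAgeResult:
    """One conversion outcome: bio_age = avg_age_used − residual_life_pred."""

    bio_age: float
    avg_age_used: float
    avg_age_source: str
    residual_life_pred: float
    chronological_age: float


def convert_record(
    table: LifeExpectancyTable,
    residual_life_pred: float,
    chronological_age: float,
    region: str = "All",
    year: int | None = None,
    sex: str = "total",
    calendar: str = "roc",
) -> BioAgeResult:
    """Look up the reference expectancy and convert one prediction."""
    if year is None:
        avg, source = table.latest_national[sex], "national-fallback"
    else:
        avg, source = table.lookup(region, year, sex, calendar=calendar)
    return BioAgeResult(
        bio_age=to_biological_age(avg, residual_life_pred),
        avg_age_used=avg,
        avg_age_source=source,
        residual_life_pred=residual_life_pred,
        chronological_age=chronological_age,
    )
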