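"""Merge exam and mortality tables and apply the cohort exclusion rules.

The modeling cohort is built in a fixed order that mirrors the screening
ledger of the study design this package implements:

1. record exclusions — accidental deaths, under-20 participants,
   long-term-medication users (in that order);
2. drop features whose missing rate exceeds the sparse cutoff (default
   strictly greater than 90%);
3. retain only deceased records (residual life needs a death date);
4. compute the residual-life target as (death - exam) in 365.25-day years.

Each step reports counts so the row ledger always balances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bioagekit.simulate import ACCIDENTAL_CAUSE, DAYS_PER_YEAR

NON_FEATURE_COLUMNS = (
    "pid",
    "exam_date",
    "sex",
    "chronological_age",
    "long_term_medication",
    "death_date",
    "cause_of_death",
    "n_visits",
    "residual_life",
)


class IntegrityError(ValueError):
    """Input tables violate a join or date invariant."""


class ConfigurationError(ValueError):
    pass


class EmptyCohortError(ValueError):
    """Every record was filtered out."""


@dataclass
class CohortConfig:
    """Identifies the columns the exclusion rules act on."""

    accidental_causes: tuple[str, ...] = (ACCIDENTAL_CAUSE,)
    medication_flag_column: str = "long_term_medication"
    min_age: float = 20.0
    sparse_cutoff: float = 0.90


@dataclass
class ExclusionReport:
    """Per-rule removal ledger, in application order."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)
    n_output: int = 0

    def record(self, rule: str, count: int) -> None:
        self.removed[rule] = count
        self.fractions[rule] = count / self.n_input if self.n_input else 0.0

    def consistent(self) -> bool:
        return self.n_input == self.n_output + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "fractions": dict(self.fractions),
            "dropped_features": list(self.dropped_features),
            "n_output": self.n_output,
        }


def merge_records(exam: pd.DataFrame, mortality: pd.DataFrame) -> pd.DataFrame:
    """Left-align mortality follow-up onto every exam row by ``pid``.

    One output row per exam row; an exam row whose pid has no mortality
    row is an integrity error (the follow-up registry covers everyone).
    """
    if "pid" not in exam.columns or "pid" not in mortality.columns:
        raise IntegrityError("both tables need a 'pid' column")
    if mortality["pid"].duplicated().any():
        dupes = mortality.loc[mortality["pid"].duplicated(), "pid"].unique().tolist()
        raise IntegrityError(f"duplicate pids in mortality table: {dupes[:10]}")
    merged = exam.merge(
        mortality[["pid", "death_date", "cause_of_death"]], on="pid", how="left", indicator=True
    )
    unmatched = merged.loc[merged["_merge"] == "left_only", "pid"].unique().tolist()
    if unmatched:
        raise IntegrityError(f"exam pids missing from mortality table: {unmatched[:10]}")
    return merged.drop(columns="_merge")


def apply_exclusions(
    merged: pd.DataFrame, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove accidental deaths, under-20 records and medication users.

    Rules apply in that order; the report counts each rule against the rows
    still present when it runs, so the ledger sums exactly.
    """
    config = config or CohortConfig()
    if config.medication_flag_column not in merged.columns:
        raise ConfigurationError(
            f"medication flag column {config.medication_flag_column!r} absent from table"
        )
    report = ExclusionReport(n_input=len(merged))
    out = merged

    accidental = out["cause_of_death"].isin(config.accidental_causes)
    report.record("accidental_death", int(accidental.sum()))
    out = out.loc[~accidental]

    under = out["chronological_age"] < config.min_age
    report.record("under_20", int(under.sum()))
    out = out.loc[~under]

    medicated = out[config.medication_flag_column].astype(float) > 0
    report.record("long_term_medication", int(medicated.sum()))
    out = out.loc[~medicated]

    report.n_output = len(out)
    assert report.consistent()
    return out.reset_index(drop=True), report


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in NON_FEATURE_COLUMNS]


def drop_sparse_features(
    table: pd.DataFrame, cutoff: float = 0.90
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features whose missing fraction is *strictly* above ``cutoff``."""
    if not 0.0 < cutoff <= 1.0:
        raise ConfigurationError("cutoff must lie in (0, 1]")
    rates = table[feature_columns(table)].isna().mean()
    dropped = sorted(rates.index[rates > cutoff])
    return table.drop(columns=dropped), dropped


def retain_deceased(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows with a death date (residual life is only defined there)."""
    out = table.loc[table["death_date"].notna()].reset_index(drop=True)
    if len(out) == 0:
        raise EmptyCohortError("no deceased records remain; cannot form a residual-life cohort")
    return out


def compute_residual_life(exam_date, death_date) -> float | pd.Series:
    """(death - exam) in days / 365.25, vectorised over Series inputs."""
    exam_date = pd.to_datetime(exam_date)
    death_date = pd.to_datetime(death_date)
    delta = death_date - exam_date
    if isinstance(delta, pd.Series):
        if (delta.dt.days < 0).any():
            raise IntegrityError("death date precedes exam date")
        return delta.dt.days / DAYS_PER_YEAR
    if delta.days < 0:
        raise IntegrityError("death date precedes exam date")
    return delta.days / DAYS_PER_YEAR


def build_cohort(
    exam: pd.DataFrame,
    mortality: pd.DataFrame,
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full pipeline: merge -> exclusions -> sparse drop -> deceased -> target.

    Returns the modeling cohort (with a ``residual_life`` column) and the
    exclusion report.  Idempotent: running it on its own output (with the
    residual_life column removed and tables re-derived) changes nothing.
    """
    config = config or CohortConfig()
    merged = merge_records(exam, mortality)
    filtered, report = apply_exclusions(merged, config)
    filtered, dropped = drop_sparse_features(filtered, config.sparse_cutoff)
    report.dropped_features = dropped
    n_before = len(filtered)
    cohort = retain_deceased(filtered)
    report.record("not_deceased", n_before - len(cohort))
    report.n_output = len(cohort)
    cohort = cohort.copy()
    cohort["residual_life"] = compute_residual_life(cohort["exam_date"], cohort["death_date"]).to_numpy()
    if (cohort["residual_life"] <= 0).any():
        # death == exam yields 0; keep strictly positive targets
        zero = cohort["residual_life"] <= 0
        report.record("zero_residual_life", int(zero.sum()))
        cohort = cohort.loc[~zero].reset_index(drop=True)
        report.n_output = len(cohort)
    if len(cohort) == 0:
        raise EmptyCohortError("cohort empty after residual-life computation")
    assert report.consistent()
    return cohort, report


def feature_missing_manifest(table: pd.DataFrame) -> pd.Series:
    """Per-feature missing rate of the cohort (the feature manifest)."""
    return table[feature_columns(table)].isna().mean()
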