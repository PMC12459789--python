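"""Synthetic health-examination cohorts with feature-dependent mortality.

The generator emulates the structure of a health-screening registry with
mortality follow-up: repeated exam visits per person, three feature blocks
(self-reported questionnaire, anthropometry, laboratory), block-specific
missingness (including near-total missingness in questionnaire items),
under-20 participants, long-term-medication users, and accidental deaths.

The mortality model is deliberately simple and fully known so that recovery
is testable: a person's age at death is

    death_age = baseline_life_expectancy
                + sum_f effect_f * z_f          (latent feature z-scores)
                + categorical level offsets
                + Normal(0, noise_sd)

truncated below so death always falls after the last exam.  Measured
feature values are the person-level latents plus a small per-visit
measurement jitter, so residual life is learnable from the exam table.

Accidental deaths receive an extra exponential deduction from their death
time; including them therefore biases a residual-life regressor downward,
which makes the cohort-builder's exclusion rule empirically testable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FOLLOWUP_CUTOFF = pd.Timestamp("2018-11-30")
DAYS_PER_YEAR = 365.25

NATURAL_CAUSES = (
    "malignant tumor",
    "heart disease",
    "cerebrovascular disease",
    "pneumonia",
    "diabetes mellitus",
)
ACCIDENTAL_CAUSE = "accidental injury"

#: columns that are never masked by :func:`inject_missingness`
PROTECTED_COLUMNS = ("pid", "exam_date", "sex", "chronological_age", "long_term_medication")


class ConfigurationError(ValueError):
    """Raised when a :class:`CohortSimConfig` field is invalid."""


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_persons
        Number of simulated individuals (each may have several exam visits).
    visits_mean, visits_max
        Mean (geometric) and cap of the per-person visit count.
    n_continuous, n_categorical
        Continuous features are split over the three blocks as roughly
        60% laboratory (``lab_``), 20% anthropometry (``an_``) and 20%
        questionnaire (``qn_``); categoricals (``qc_``, 2–5 levels) all
        belong to the questionnaire block.
    signal_effects
        Mapping feature name -> years of life per standard deviation of
        that feature's latent.  Negative = life-shortening when high.
    categorical_offsets
        Optional mapping ``feature -> {level: years}``; default none, so
        categoricals carry no survival signal (they are excluded from
        correlation partnering downstream anyway).
    baseline_life_expectancy
        Mean age at (natural) death in years for a person with all latents
        at zero.
    noise_sd
        SD in years of the Gaussian noise on the age at death.
    block_rho
        Equicorrelation of latents within each feature block
        (block-diagonal joint distribution; a free modelling choice).
    exam_age_range
        Uniform range of age at the first exam visit.
    exam_years
        Calendar window (inclusive) in which first visits are placed.
    missing_rates
        Block -> target missing fraction used by :func:`inject_missingness`.
    sparse_features
        Per-feature missing-rate overrides (used to emulate questionnaire
        items with >90% missingness that the cohort builder must drop).
    missing_mechanism
        ``"MCAR"`` or ``"MAR"`` (MAR ties laboratory missingness to age
        decile).
    frac_under20 / frac_medicated / frac_accidental_death
        Subpopulation fractions (first-exam age < 20; long-term-medication
        flag set; accidental cause of death with earlier death time).
    male_fraction
        Probability a person is male.
    visit_jitter_sd
        SD of per-visit measurement noise around the person latent.
    seed
        Generation with the same config and seed is bit-identical.
    """

    n_persons: int = 1000
    visits_mean: float = 1.0
    visits_max: int = 5
    n_continuous: int = 20
    n_categorical: int = 3
    signal_effects: dict[str, float] = field(default_factory=dict)
    categorical_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_life_expectancy: float = 80.0
    noise_sd: float = 2.0
    block_rho: float = 0.3
    exam_age_range: tuple[float, float] = (35.0, 85.0)
    exam_years: tuple[int, int] = (1998, 2012)
    missing_rates: dict[str, float] = field(default_factory=dict)
    sparse_features: dict[str, float] = field(default_factory=dict)
    missing_mechanism: str = "MCAR"
    frac_under20: float = 0.0
    frac_medicated: float = 0.0
    frac_accidental_death: float = 0.0
    male_fraction: float = 0.5
    visit_jitter_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ConfigurationError("n_persons must be positive")
        if not (1 <= self.visits_mean <= self.visits_max):
            raise ConfigurationError("visits_mean must lie in [1, visits_max]")
        if self.n_continuous < 0 or self.n_categorical < 0:
            raise ConfigurationError("feature counts must be non-negative")
        for name, frac in (
            ("frac_under20", self.frac_under20),
            ("frac_medicated", self.frac_medicated),
            ("frac_accidental_death", self.frac_accidental_death),
            ("male_fraction", self.male_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {frac}")
        for block, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missing_rates[{block!r}] must lie in [0, 1]")
        for feat, rate in self.sparse_features.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"sparse_features[{feat!r}] must lie in [0, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ConfigurationError("missing_mechanism must be 'MCAR' or 'MAR'")
        if len(self.signal_effects) > self.n_continuous:
            raise ConfigurationError("more signal effects than continuous features")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not -1.0 < self.block_rho < 1.0:
            raise ConfigurationError("block_rho must lie in (-1, 1)")
        unknown = set(self.signal_effects) - set(self.continuous_names())
        if unknown:
            raise ConfigurationError(
                f"signal_effects name(s) not among generated continuous features: {sorted(unknown)}"
            )

    # ---- feature naming -------------------------------------------------
    def _block_sizes(self) -> dict[str, int]:
        n = self.n_continuous
        n_lab = int(round(n * 0.6))
        n_an = int(round(n * 0.2))
        n_qn = n - n_lab - n_an
        return {"laboratory": n_lab, "anthropometry": n_an, "questionnaire": n_qn}

    def continuous_names(self) -> list[str]:
        sizes = self._block_sizes()
        names = [f"lab_{i + 1:02d}" for i in range(sizes["laboratory"])]
        names += [f"an_{i + 1:02d}" for i in range(sizes["anthropometry"])]
        names += [f"qn_{i + 1:02d}" for i in range(sizes["questionnaire"])]
        return names

    def categorical_names(self) -> list[str]:
        return [f"qc_{i + 1:02d}" for i in range(self.n_categorical)]

    def feature_block(self, name: str) -> str:
        if name.startswith("lab_"):
            return "laboratory"
        if name.startswith("an_"):
            return "anthropometry"
        return "questionnaire"  # qn_ and qc_


@dataclass
class GroundTruth:
    """What the generator knows and a fitted model should recover."""

    signal_features: list[str]
    signal_effects: dict[str, float]
    true_residual_life: dict[tuple[str, int], float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signal_features": self.signal_features,
            "signal_effects": self.signal_effects,
            "true_residual_life": {f"{pid}:{visit}": v for (pid, visit), v in self.true_residual_life.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _block_latents(rng: np.random.Generator, n: int, sizes: dict[str, int], rho: float) -> np.ndarray:
    """Draw person latents, equicorrelated within each block, independent across."""
    cols = []
    for size in sizes.values():
        if size == 0:
            continue
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, size))
        # z = sqrt(rho)*shared + sqrt(1-rho)*own gives corr rho within block
        cols.append(np.sqrt(abs(rho)) * np.sign(rho) * shared + np.sqrt(1 - abs(rho)) * own)
    if not cols:
        return np.empty((n, 0))
    return np.concatenate(cols, axis=1)


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (exam table, mortality table, ground truth).

    The exam table has one row per visit: ``pid``, ``exam_date``, ``sex``,
    ``chronological_age``, ``long_term_medication`` and the feature columns.
    The mortality table has one row per person: ``pid``, ``death_date``
    (NaT while alive at follow-up cutoff), ``cause_of_death`` (blank while
    alive) and ``n_visits``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    sizes = config._block_sizes()
    cont_names = config.continuous_names()
    cat_names = config.categorical_names()

    pids = np.array([f"p{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")

    z = _block_latents(rng, n, sizes, config.block_rho)  # (n, n_continuous)

    cat_levels = {name: [f"L{j}" for j in range(int(rng.integers(2, 6)))] for name in cat_names}
    cat_values = {
        name: rng.choice(levels, size=n) for name, levels in cat_levels.items()
    }

    # subpopulation flags (drawn independently)
    under20 = rng.random(n) < config.frac_under20
    medicated = rng.random(n) < config.frac_medicated
    accidental = rng.random(n) < config.frac_accidental_death

    # first-visit calendar date and age
    y0, y1 = config.exam_years
    start = pd.Timestamp(f"{y0}-01-01")
    span_days = (pd.Timestamp(f"{y1}-12-31") - start).days
    first_exam = start + pd.to_timedelta(rng.integers(0, span_days + 1, size=n), unit="D")
    a0, a1 = config.exam_age_range
    first_age = rng.uniform(a0, a1, size=n)
    first_age[under20] = rng.uniform(10.0, 19.5, size=int(under20.sum()))

    # visit counts: 1 + geometric-ish extra visits, capped
    extra_mean = max(config.visits_mean - 1.0, 0.0)
    if extra_mean > 0:
        extra = rng.geometric(1.0 / (1.0 + extra_mean), size=n) - 1
    else:
        extra = np.zeros(n, dtype=int)
    n_visits = np.clip(1 + extra, 1, config.visits_max)

    # age at death
    effect_vec = np.array([config.signal_effects.get(f, 0.0) for f in cont_names])
    signal = z @ effect_vec if len(cont_names) else np.zeros(n)
    for feat, offsets in config.categorical_offsets.items():
        vals = cat_values[feat]
        signal += np.array([offsets.get(v, 0.0) for v in vals])
    death_age = config.baseline_life_expectancy + signal + rng.normal(0.0, config.noise_sd, size=n)
    # under-20 participants: survival unrelated to the signal model
    death_age[under20] = first_age[under20] + rng.uniform(1.0, 30.0, size=int(under20.sum()))
    # accidental deaths occur earlier than the natural-course death
    death_age[accidental] -= rng.exponential(5.0, size=int(accidental.sum()))

    # per-visit offsets (years after first visit)
    visit_gap = rng.uniform(0.5, 2.0, size=(n, config.visits_max - 1)) if config.visits_max > 1 else np.empty((n, 0))

    rows: list[dict] = []
    truth: dict[tuple[str, int], float] = {}
    birth = first_exam - pd.to_timedelta((first_age * DAYS_PER_YEAR).round().astype(int), unit="D")

    # truncate death below at last exam date + epsilon
    last_offset = np.array(
        [visit_gap[i, : n_visits[i] - 1].sum() if n_visits[i] > 1 else 0.0 for i in range(n)]
    )
    eps = rng.uniform(0.1, 1.0, size=n)
    death_age = np.maximum(death_age, first_age + last_offset + eps)
    death_date = birth + pd.to_timedelta((death_age * DAYS_PER_YEAR).round().astype(int), unit="D")

    jitter = rng.normal(0.0, config.visit_jitter_sd, size=(n, config.visits_max, len(cont_names)))

    for i in range(n):
        for v in range(n_visits[i]):
            offset = visit_gap[i, :v].sum() if v else 0.0
            date_v = first_exam[i] + pd.to_timedelta(int(round(offset * DAYS_PER_YEAR)), unit="D")
            age_v = (date_v - birth[i]).days / DAYS_PER_YEAR
            row = {
                "pid": pids[i],
                "exam_date": date_v,
                "sex": sex[i],
                "chronological_age": age_v,
                "long_term_medication": int(medicated[i]),
            }
            for j, fname in enumerate(cont_names):
                row[fname] = z[i, j] + jitter[i, v, j]
            for cname in cat_names:
                row[cname] = cat_values[cname][i]
            rows.append(row)
            truth[(pids[i], v)] = (death_date[i] - date_v).days / DAYS_PER_YEAR

    exam = pd.DataFrame(rows)
    for cname in cat_names:
        exam[cname] = pd.Categorical(exam[cname], categories=cat_levels[cname])

    deceased = death_date <= FOLLOWUP_CUTOFF
    causes = rng.choice(NATURAL_CAUSES, size=n)
    causes = np.where(accidental, ACCIDENTAL_CAUSE, causes)
    mortality = pd.DataFrame(
        {
            "pid": pids,
            "death_date": pd.Series(death_date).where(deceased, pd.NaT),
            "cause_of_death": pd.Series(causes).where(deceased, None),
            "n_visits": n_visits,
        }
    )

    gt = GroundTruth(
        signal_features=sorted(config.signal_effects),
        signal_effects=dict(config.signal_effects),
        true_residual_life=truth,
    )
    return exam, mortality, gt


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def _exact_mask(rng: np.random.Generator, n: int, rate: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask with exactly round(rate*n) True entries.

    Exact-count masking keeps the realised missing fraction within rounding
    of the target (the Bernoulli alternative drifts by O(1/sqrt(n))).
    Optional ``weights`` bias which rows are selected (MAR mechanism)
    without changing the count.
    """
    k = int(round(rate * n))
    mask = np.zeros(n, dtype=bool)
    if k == 0:
        return mask
    if weights is None:
        idx = rng.permutation(n)[:k]
    else:
        p = weights / weights.sum()
        idx = rng.choice(n, size=k, replace=False, p=p)
    mask[idx] = True
    return mask


def inject_missingness(
    exam: pd.DataFrame,
    config: CohortSimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Return a copy of the exam table with cells blanked out.

    Per-feature target rates come from ``config.missing_rates`` (block
    level) overridden by ``config.sparse_features`` (per feature).  Under
    MAR, laboratory-feature missingness probability increases with age
    decile (older participants skip lab work more often), while the
    realised overall fraction still matches the target.  Identifier, date,
    sex, age and medication-flag columns are never masked.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    out = exam.copy()
    n = len(out)
    if n == 0:
        return out

    age = out["chronological_age"].to_numpy()
    # decile rank 1..10 -> linearly increasing MAR weight
    decile = np.clip(np.searchsorted(np.quantile(age, np.linspace(0.1, 0.9, 9)), age, side="right"), 0, 9) + 1

    feature_cols = [c for c in out.columns if c not in PROTECTED_COLUMNS]
    for col in feature_cols:
        block = config.feature_block(col)
        rate = config.sparse_features.get(col, config.missing_rates.get(block, 0.0))
        if rate <= 0.0:
            continue
        weights = None
        if config.missing_mechanism == "MAR" and block == "laboratory":
            weights = decile.astype(float)
        mask = _exact_mask(rng, n, rate, weights)
        if out[col].dtype.name == "category":
            out.loc[mask, col] = np.nan
        else:
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# canned configurations
# ---------------------------------------------------------------------------

#: Ten signal features of |effect| 1.5–3 years/SD among 50 continuous features.
STANDARD_SIGNAL_EFFECTS: dict[str, float] = {
    "lab_01": 3.0,
    "lab_02": -3.0,
    "lab_03": 2.5,
    "lab_04": -2.5,
    "lab_05": 2.0,
    "lab_06": -2.0,
    "lab_07": 1.5,
    "lab_08": -1.5,
    "an_01": 1.8,
    "an_02": -1.8,
}


def standard_cohort_config(seed: int = 0, n_persons: int = 7200) -> CohortSimConfig:
    """The package's standard validation cohort.

    Sized so that, after the exclusion rules and the deceased-only filter,
    roughly five thousand modeling records remain.  Single-sex
    (male-analogue): the generator attaches no sex-specific survival
    effect, and the downstream pipeline always models sexes separately, so
    a mixed cohort would only halve the per-model sample.

    The validation cohort is age-banded (exams at ages 66–74, early in the
    calendar window so follow-up covers most natural deaths).  Two
    selection effects motivate the band: (1) with late exam years most
    retained records are truncation-selected early deaths; (2) conditional
    on being alive at exam age a, expected death age increases with a
    (left truncation), so across a wide age range predicted death age
    tracks attained age and the Aging/Stable/Young partition degenerates
    into an age ranking.  An age-matched band isolates the feature-driven
    frailty signal the biological-age metric is meant to capture.
    """
    return CohortSimConfig(
        n_persons=n_persons,
        visits_mean=1.0,
        n_continuous=50,
        n_categorical=5,
        signal_effects=dict(STANDARD_SIGNAL_EFFECTS),
        baseline_life_expectancy=80.0,
        noise_sd=2.0,
        block_rho=0.3,
        exam_age_range=(66.0, 74.0),
        exam_years=(1998, 2005),
        missing_rates={"questionnaire": 0.40, "anthropometry": 0.05, "laboratory": 0.15},
        sparse_features={"qn_01": 0.95, "qn_02": 0.93, "qc_01": 0.96},
        missing_mechanism="MCAR",
        frac_under20=0.03,
        frac_medicated=0.05,
        frac_accidental_death=0.03,
        male_fraction=1.0,
        seed=seed,
    )


def config_to_dict(config: CohortSimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["exam_age_range"] = list(d["exam_age_range"])
    d["exam_years"] = list(d["exam_years"])
    return d


def config_from_dict(d: dict) -> CohortSimConfig:
    d = dict(d)
    if "exam_age_range" in d:
        d["exam_age_range"] = tuple(d["exam_age_range"])
    if "exam_years" in d:
        d["exam_years"] = tuple(d["exam_years"])
    return CohortSimConfig(**d)
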