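"""Model interpretation and the counterfactual intervention experiment.

Three layers:

* ranking — features ordered by the average split gain they contribute
  across the boosted trees (the biomarker nomination step);
* attribution — per-record additive (Shapley) contributions computed by
  the exact tree-path algorithm built into LightGBM, satisfying
  ``base_value + Σ φ_i = prediction``;
* intervention — for each record, the top three life-shortening features
  (most negative contributions) and, for each, its three most
  Pearson-correlated partners are reset to reference means (same-sex,
  same-10-year-age-bin training means by default) and the record is
  re-predicted.  A change in predicted residual life below 0.5 years in
  magnitude counts as unchanged; at or above the threshold the record is
  improved (positive delta) or worsened (negative).

Pearson correlation is restricted to continuous features; a categorical
feature nominated among the top-3 factors is reset to its modal level and
its partner search is skipped (flagged on the result).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bioagekit.model import ResidualLifeRegressor

ADDITIVITY_TOL = 1e-6


# ---------------------------------------------------------------------------
# gain ranking
# ---------------------------------------------------------------------------

def feature_gain_ranking(model: ResidualLifeRegressor, k: int = 10) -> pd.DataFrame:
    """Top-``k`` features by average split gain (gain per split).

    Features never used in a split rank last with zero gain.  ``k`` larger
    than the feature count returns the full list; ``k = 0`` an empty one.
    """
    booster = model.booster_
    names = booster.feature_name()
    gain = booster.feature_importance(importance_type="gain")
    splits = booster.feature_importance(importance_type="split")
    avg = np.divide(gain, splits, out=np.zeros_like(gain, dtype=float), where=splits > 0)
    out = (
        pd.DataFrame({"feature": names, "avg_gain": avg, "n_splits": splits})
        .sort_values(["avg_gain", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )
    if k < 0:
        raise ValueError("k must be non-negative")
    return out.head(k) if k <= len(out) else out


# ---------------------------------------------------------------------------
# additive attributions
# ---------------------------------------------------------------------------

@dataclass
class AttributionVector:
    """Additive decomposition of one prediction.

    ``base_value`` is the mean training prediction; ``contributions`` are
    per-feature years of residual life; their sum plus the base equals the
    prediction to within 1e-6.
    """

    base_value: float
    contributions: dict[str, float]
    prediction: float

    def check_additivity(self, tol: float = ADDITIVITY_TOL) -> bool:
        return abs(self.base_value + sum(self.contributions.values()) - self.prediction) <= tol


def attribute_table(model: ResidualLifeRegressor, table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Exact tree-path attributions for every row.

    Returns (contributions frame, base value); columns follow the model's
    feature order.
    """
    feats = model.feature_names_in_
    missing = [c for c in feats if c not in table.columns]
    if missing:
        raise ValueError(f"record schema mismatch: missing features {missing}")
    X = model.coerce(table)
    contrib = model._lgbm.predict(X, pred_contrib=True)
    base = float(contrib[0, -1]) if len(contrib) else 0.0
    return pd.DataFrame(contrib[:, :-1], columns=feats, index=table.index), base


def attribute(model: ResidualLifeRegressor, record: pd.Series | pd.DataFrame) -> AttributionVector:
    """Additive attribution of a single record's predicted residual life."""
    if isinstance(record, pd.Series):
        record = record.to_frame().T
    if len(record) != 1:
        raise ValueError("attribute() explains exactly one record")
    contribs, base = attribute_table(model, record)
    pred = float(model.predict(record[model.feature_names_in_])[0])
    vec = AttributionVector(
        base_value=base,
        contributions={c: float(contribs.iloc[0][c]) for c in contribs.columns},
        prediction=pred,
    )
    if not vec.check_additivity():
        raise AssertionError("attribution additivity violated beyond 1e-6")
    return vec


def top_life_shortening(attribution: AttributionVector, k: int = 3) -> list[str]:
    """The ``k`` features contributing most negatively to residual life.

    Only negative contributions qualify; if fewer than ``k`` exist the
    shorter list is returned with a warning.  Ties break by feature name.
    """
    negatives = sorted(
        ((v, f) for f, v in attribution.contributions.items() if v < 0),
        key=lambda t: (t[0], t[1]),
    )
    if len(negatives) < k:
        warnings.warn(
            f"only {len(negatives)} life-shortening feature(s) present (asked for {k})",
            stacklevel=2,
        )
    return [f for _, f in negatives[:k]]


# ---------------------------------------------------------------------------
# Pearson correlation partnering
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients over continuous features."""

    matrix: pd.DataFrame
    n: int

    def partners(self, feature: str, k: int = 3) -> list[str]:
        return correlated_partners(self, feature, k)


def pcc_matrix(table: pd.DataFrame, continuous_features: list[str]) -> CorrelationMatrix:
    """Pairwise Pearson correlation by the textbook formula.

    r_xy = Σ(xᵢ−x̄)(yᵢ−ȳ) / sqrt(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²), computed for every
    pair of the listed continuous features.  A zero-variance feature's
    coefficients are undefined and stored as NaN with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows")
    X = table[continuous_features].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("correlation requires a complete (imputed) table")
    Xc = X - X.mean(axis=0)
    ss = np.sqrt((Xc**2).sum(axis=0))
    zero_var = ss == 0.0
    if zero_var.any():
        bad = [f for f, z in zip(continuous_features, zero_var) if z]
        warnings.warn(f"zero-variance feature(s), correlation undefined: {bad}", stacklevel=2)
    denom = np.outer(ss, ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Xc) / denom
    r[zero_var, :] = np.nan
    r[:, zero_var] = np.nan
    np.fill_diagonal(r, np.where(zero_var, np.nan, 1.0))
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(
        matrix=pd.DataFrame(r, index=continuous_features, columns=continuous_features),
        n=len(table),
    )


def correlated_partners(matrix: CorrelationMatrix, feature: str, k: int = 3) -> list[str]:
    """``k`` features with the largest |r| to ``feature`` (self excluded)."""
    if feature not in matrix.matrix.index:
        raise KeyError(f"feature {feature!r} not in correlation matrix")
    row = matrix.matrix.loc[feature].drop(labels=[feature]).dropna()
    ranked = sorted(row.items(), key=lambda t: (-abs(t[1]), t[0]))
    return [f for f, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# reference means and intervention
# ---------------------------------------------------------------------------

class ReferenceMeans:
    """Training-set reference levels for the intervention.

    Default granularity is same-sex, same-10-year-age-bin means (modal
    level for categoricals); ``granularity="global"`` switches to the
    whole-training-set average.
    """

    def __init__(self, train: pd.DataFrame, feature_cols: list[str], granularity: str = "age-sex"):
        if granularity not in ("age-sex", "global"):
            raise ValueError("granularity must be 'age-sex' or 'global'")
        self.granularity = granularity
        self.feature_cols = feature_cols
        self._global = self._summarise(train)
        self._groups: dict[tuple[str, int], dict] = {}
        if granularity == "age-sex" and {"sex", "chronological_age"} <= set(train.columns):
            decade = (train["chronological_age"] // 10 * 10).astype(int)
            for (sex, dec), sub in train.groupby(["sex", decade], observed=True):
                self._groups[(sex, int(dec))] = self._summarise(sub)

    def _summarise(self, table: pd.DataFrame) -> dict:
        out = {}
        for col in self.feature_cols:
            s = table[col]
            if s.dtype.name == "category" or s.dtype == object:
                out[col] = s.mode(dropna=True).iloc[0] if s.notna().any() else None
            else:
                out[col] = float(pd.to_numeric(s, errors="coerce").mean())
        return out

    def value_for(self, record: pd.Series, feature: str):
        if feature not in self.feature_cols:
            raise KeyError(f"no reference mean available for feature {feature!r}")
        if self.granularity == "age-sex" and "sex" in record.index:
            key = (record["sex"], int(record["chronological_age"] // 10 * 10))
            if key in self._groups:
                return self._groups[key][feature]
        return self._global[feature]


#: features a counterfactual intervention may never modify: demographics are
#: not modifiable biomarkers, however negative their contribution.
IMMUTABLE_FEATURES = ("chronological_age", "sex")


def categorize_delta(delta: float, threshold: float = 0.5) -> str:
    """'unchanged' iff |delta| < threshold; else 'improved'/'worsened'."""
    if abs(delta) < threshold:
        return "unchanged"
    return "improved" if delta > 0 else "worsened"


@dataclass
class InterventionResult:
    """Outcome of the counterfactual reset for one record."""

    modified: dict[str, tuple] = field(default_factory=dict)  # feature -> (old, new)
    original_pred: float = 0.0
    new_pred: float = 0.0
    delta: float = 0.0
    category: str = "unchanged"
    factors: list[str] = field(default_factory=list)
    categorical_factors_reset: list[str] = field(default_factory=list)


def intervene(
    record: pd.Series,
    model: ResidualLifeRegressor,
    attribution: AttributionVector,
    matrix: CorrelationMatrix,
    reference_means: ReferenceMeans,
    threshold: float = 0.5,
    top_k: int = 3,
    partners_k: int = 3,
    immutable: tuple[str, ...] = IMMUTABLE_FEATURES,
) -> InterventionResult:
    """Reset the top life-shortening factors (and partners) to the mean.

    The union of the top-``top_k`` negative-contribution features and, for
    each continuous one, its ``partners_k`` most correlated continuous
    partners is set to the reference level; the record is re-predicted and
    the change categorised with the ``threshold``-year band.  Demographic
    columns (``immutable``) are never nominated or modified.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trimmed = AttributionVector(
            base_value=attribution.base_value,
            contributions={f: v for f, v in attribution.contributions.items() if f not in immutable},
            prediction=attribution.prediction,
        )
        factors = top_life_shortening(trimmed, k=top_k)
    to_modify: list[str] = []
    categorical_reset: list[str] = []
    for f in factors:
        to_modify.append(f)
        if f in matrix.matrix.index:
            to_modify.extend(
                p for p in correlated_partners(matrix, f, k=partners_k) if p not in immutable
            )
        else:
            categorical_reset.append(f)  # categorical factor: partners skipped
    # union semantics: each feature modified once
    seen: dict[str, None] = {}
    for f in to_modify:
        seen.setdefault(f)
    to_modify = list(seen)

    modified_record = record.copy()
    modified: dict[str, tuple] = {}
    for f in to_modify:
        ref = reference_means.value_for(record, f)
        modified[f] = (record[f], ref)
        modified_record[f] = ref

    frame = pd.DataFrame([record])
    new_frame = pd.DataFrame([modified_record])
    original = float(model.predict(frame)[0])
    new = float(model.predict(new_frame)[0])
    delta = new - original
    return InterventionResult(
        modified=modified,
        original_pred=original,
        new_pred=new,
        delta=delta,
        category=categorize_delta(delta, threshold),
        factors=factors,
        categorical_factors_reset=categorical_reset,
    )


def intervene_table(
    table: pd.DataFrame,
    model: ResidualLifeRegressor,
    matrix: CorrelationMatrix,
    reference_means: ReferenceMeans,
    threshold: float = 0.5,
    top_k: int = 3,
    partners_k: int = 3,
    immutable: tuple[str, ...] = IMMUTABLE_FEATURES,
) -> list[InterventionResult]:
    """Vectorised cohort intervention: one result per row.

    Attributions for all rows are computed in a single pass; the modified
    table is re-predicted in one call.
    """
    contribs, base = attribute_table(model, table)
    feats = model.feature_names_in_
    X = table[feats].copy()
    original = model.predict(X)
    modified_X = X.copy()
    per_row_meta: list[tuple[list[str], list[str], dict]] = []

    cont = [f for f in feats if f in matrix.matrix.index]
    partner_cache = {
        f: [p for p in correlated_partners(matrix, f, k=partners_k) if p not in immutable]
        for f in cont
    }

    for i, (idx, row) in enumerate(X.iterrows()):
        c = contribs.loc[idx]
        negatives = sorted(
            ((v, f) for f, v in c.items() if v < 0 and f not in immutable),
            key=lambda t: (t[0], t[1]),
        )
        factors = [f for _, f in negatives[:top_k]]
        to_modify: dict[str, None] = {}
        categorical_reset = []
        for f in factors:
            to_modify.setdefault(f)
            if f in partner_cache:
                for p in partner_cache[f]:
                    to_modify.setdefault(p)
            else:
                categorical_reset.append(f)
        rec = table.loc[idx]
        mods = {}
        for f in to_modify:
            ref = reference_means.value_for(rec, f)
            mods[f] = (rec[f], ref)
            modified_X.at[idx, f] = ref
        per_row_meta.append((factors, categorical_reset, mods))

    new = model.predict(modified_X)
    results = []
    for i, (factors, categorical_reset, mods) in enumerate(per_row_meta):
        delta = float(new[i] - original[i])
        results.append(
            InterventionResult(
                modified=mods,
                original_pred=float(original[i]),
                new_pred=float(new[i]),
                delta=delta,
                category=categorize_delta(delta, threshold),
                factors=factors,
                categorical_factors_reset=categorical_reset,
            )
        )
    return results


def cohort_intervention_summary(results: list[InterventionResult]) -> dict[str, float]:
    """Fractions of improved / unchanged / worsened records (sum to 1)."""
    if not results:
        raise ValueError("no intervention results to summarise")
    n = len(results)
    counts = {"improved": 0, "unchanged": 0, "worsened": 0}
    for r in results:
        counts[r.category] += 1
    return {k: v / n for k, v in counts.items()}
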