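"""Completion of feature tables with missing cells.

Two routes to a complete dataset:

* :class:`ChainedImputer` — a from-scratch chained-equations (MICE-style)
  imputer.  Missing cells are first filled with the training mean (mode for
  categoricals); then, for a fixed number of cycles, each incomplete
  feature in turn is reset to missing, a per-feature predictive model is
  fitted on the remaining features, and the missing cells are re-predicted.
  Fitting retains the final cycle's models so that validation/test tables
  are completed *from the training-set models* (two-phase protocol: a
  feature that is missing in new data but was never missing in training has
  no model, and a supplementary model is fitted on the training table on
  demand).

* :func:`filter_complete` — the rule-based alternative: drop features whose
  missing rate exceeds a small cutoff (default 2%), then drop every row
  that still contains a missing value.

Both routes preserve observed cells exactly and are deterministic under a
fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """New table's features do not match the training schema."""


@dataclass
class _FeatureModel:
    name: str
    kind: str  # "numeric" | "categorical"
    estimator: object
    predictors: list[str]


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype.name == "category" or s.dtype == object


class ChainedImputer(BaseEstimator, TransformerMixin):
    """Chained-equations imputer with train-model reuse on new tables.

    Parameters
    ----------
    n_iterations : int, default 5
        Number of full cycles over the incomplete features.
    model_family : {"forest", "tree", "linear"}, default "forest"
        Per-feature model family: random forests (the family the reference
        chained-equations implementations use), single CART trees (faster),
        or ridge / logistic regression.  Whatever the family, features
        observed on fewer than ``min_rows_for_model`` rows fall back to a
        linear model, and below 5 rows to a marginal (mean/mode) model.
    n_estimators, max_depth
        Forest/tree size controls.
    random_state : int, default 0
        Same state + same table -> identical completions.

    Attributes
    ----------
    feature_names_in_ : list of str
    initial_fill_ : dict
        Training mean (numeric) / mode (categorical) per feature.
    visit_order_ : list of str
        Incomplete training features in ascending missing-rate order.
    models_ : dict of str -> _FeatureModel
        One fitted model per training feature that had >= 1 missing value.
    train_completed_ : DataFrame
        The completed training table (needed for phase-two supplementary
        fits on new tables).
    supplementary_features_ : list of str
        Features that required a phase-two fit during the last transform.
    convergence_ : list of float
        Mean absolute change of imputed numeric cells per cycle.
    """

    def __init__(
        self,
        n_iterations: int = 5,
        model_family: str = "forest",
        n_estimators: int = 12,
        max_depth: int = 8,
        min_rows_for_model: int = 30,
        random_state: int = 0,
    ):
        self.n_iterations = n_iterations
        self.model_family = model_family
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_rows_for_model = min_rows_for_model
        self.random_state = random_state

    # ---- internals ------------------------------------------------------

    def _make_estimator(self, kind: str, n_obs: int):
        rs = self.random_state
        if n_obs < 5:
            return DummyRegressor() if kind == "numeric" else DummyClassifier(strategy="most_frequent")
        if n_obs < self.min_rows_for_model or self.model_family == "linear":
            return Ridge() if kind == "numeric" else LogisticRegression(max_iter=200)
        if self.model_family == "tree":
            cls = DecisionTreeRegressor if kind == "numeric" else DecisionTreeClassifier
            return cls(max_depth=self.max_depth, random_state=rs)
        if self.model_family == "forest":
            cls = RandomForestRegressor if kind == "numeric" else RandomForestClassifier
            # subsampled bootstrap: near-identical completions at ~half the cost
            return cls(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                max_samples=0.6 if n_obs >= 100 else None,
                n_jobs=1,
                random_state=rs,
            )
        raise ValueError(f"unknown model_family {self.model_family!r}")

    def _encode(self, table: pd.DataFrame) -> pd.DataFrame:
        """Numeric working copy: categoricals as float codes (NaN kept)."""
        work = pd.DataFrame(index=table.index)
        for col in table.columns:
            if col in self._cat_levels:
                codes = pd.Categorical(table[col], categories=self._cat_levels[col]).codes.astype(float)
                codes[codes < 0] = np.nan
                work[col] = codes
            else:
                work[col] = pd.to_numeric(table[col], errors="coerce")
        return work

    def _decode(self, work: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
        out = template.copy()
        for col in work.columns:
            if col in self._cat_levels:
                levels = self._cat_levels[col]
                codes = work[col].round().clip(0, len(levels) - 1).astype(int)
                filled = pd.Categorical.from_codes(codes, categories=levels)
                out[col] = pd.Series(filled, index=work.index).where(template[col].isna(), template[col])
                out[col] = out[col].astype(pd.CategoricalDtype(levels))
            else:
                out[col] = np.where(template[col].isna(), work[col], template[col])
        return out

    def _initial_fill_values(self, col: str) -> float:
        v = self.initial_fill_[col]
        if col in self._cat_levels:
            return float(self._cat_levels[col].index(v))
        return float(v)

    def _fit_feature_model(self, col: str, work: pd.DataFrame, observed: pd.Series) -> _FeatureModel:
        kind = "categorical" if col in self._cat_levels else "numeric"
        predictors = [c for c in work.columns if c != col]
        X = work.loc[observed, predictors].to_numpy()
        y = work.loc[observed, col].to_numpy()
        if kind == "categorical":
            y = y.astype(int)
            est = (
                DummyClassifier(strategy="most_frequent")
                if np.unique(y).size < 2
                else self._make_estimator(kind, int(observed.sum()))
            )
        else:
            est = self._make_estimator(kind, int(observed.sum()))
        est.fit(X, y)
        return _FeatureModel(col, kind, est, predictors)

    @staticmethod
    def _predict(model: _FeatureModel, work: pd.DataFrame, rows: pd.Series) -> np.ndarray:
        X = work.loc[rows, model.predictors].to_numpy()
        return model.estimator.predict(X).astype(float)

    # ---- sklearn API ----------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "ChainedImputer":
        X = self._validate_table(X, fitting=True)
        self.feature_names_in_ = list(X.columns)
        self._cat_levels = {
            c: list(X[c].astype("category").cat.categories) for c in X.columns if _is_categorical(X[c])
        }

        fully_missing = [c for c in X.columns if X[c].isna().all()]
        if fully_missing:
            raise ValueError(
                f"feature(s) 100% missing in training data: {fully_missing}; "
                "drop them upstream (sparse-feature filter) before imputation"
            )

        self.initial_fill_ = {}
        for col in X.columns:
            if col in self._cat_levels:
                self.initial_fill_[col] = X[col].mode(dropna=True).iloc[0]
            else:
                self.initial_fill_[col] = float(pd.to_numeric(X[col], errors="coerce").mean())

        miss_rate = X.isna().mean()
        incomplete = [c for c in X.columns if miss_rate[c] > 0]
        self.visit_order_ = sorted(incomplete, key=lambda c: (miss_rate[c], c))

        work = self._encode(X)
        missing_mask = {c: X[c].isna() for c in incomplete}
        for col in X.columns:
            if work[col].isna().any():
                work.loc[work[col].isna(), col] = self._initial_fill_values(col)

        self.models_ = {}
        self.convergence_ = []
        for it in range(self.n_iterations if incomplete else 0):
            deltas = []
            for col in self.visit_order_:
                mask = missing_mask[col]
                observed = ~mask
                model = self._fit_feature_model(col, work, observed)
                if mask.any():
                    new_vals = self._predict(model, work, mask)
                    old_vals = work.loc[mask, col].to_numpy()
                    if model.kind == "numeric":
                        deltas.append(float(np.mean(np.abs(new_vals - old_vals))))
                    work.loc[mask, col] = new_vals
                self.models_[col] = model
            self.convergence_.append(float(np.mean(deltas)) if deltas else 0.0)
            logger.info("chained imputation cycle %d: mean |change| = %.5f", it + 1, self.convergence_[-1])

        self.train_completed_ = self._decode(work, X)
        self.supplementary_features_ = []
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        X = self._validate_table(X, fitting=False)
        self.supplementary_features_ = []
        if len(X) == 0:
            return X.copy()

        incomplete = [c for c in X.columns if X[c].isna().any()]
        if not incomplete:
            return X.copy()

        # phase two: features missing here but never missing in training
        orphans = [c for c in incomplete if c not in self.models_]
        if orphans:
            train_work = self._encode(self.train_completed_)
            for col in sorted(orphans):
                logger.info("fitting supplementary model for feature %r (never missing in training)", col)
                model = self._fit_feature_model(col, train_work, pd.Series(True, index=train_work.index))
                self.models_[col] = model
                self.supplementary_features_.append(col)

        work = self._encode(X)
        missing_mask = {c: X[c].isna() for c in incomplete}
        for col in X.columns:
            if work[col].isna().any():
                work.loc[work[col].isna(), col] = self._initial_fill_values(col)

        order = [c for c in self.visit_order_ if c in incomplete]
        order += [c for c in sorted(incomplete) if c not in order]
        for _ in range(self.n_iterations):
            for col in order:
                mask = missing_mask[col]
                if mask.any():
                    work.loc[mask, col] = self._predict(self.models_[col], work, mask)
        return self._decode(work, X)

    # ---- plumbing -------------------------------------------------------

    def _validate_table(self, X, fitting: bool) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ChainedImputer operates on pandas DataFrames")
        if fitting:
            if len(X) == 0:
                raise ValueError("cannot fit on an empty table")
            return X
        unknown = [c for c in X.columns if c not in self.feature_names_in_]
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if unknown or missing:
            raise SchemaError(f"schema mismatch: unknown={unknown}, absent={missing}")
        return X[self.feature_names_in_]

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise RuntimeError("ChainedImputer is not fitted")

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        """Fit on ``X`` and return the completed training table."""
        return self.fit(X).train_completed_.copy()

    def save(self, path) -> None:
        """Serialise the fitted state (joblib bundle, versioned)."""
        self._check_fitted()
        joblib.dump({"format_version": 1, "imputer": self}, path)

    @classmethod
    def load(cls, path) -> "ChainedImputer":
        bundle = joblib.load(path)
        if bundle.get("format_version") != 1:
            raise ValueError("unrecognised imputer bundle version")
        return bundle["imputer"]


def mean_fill(table: pd.DataFrame) -> pd.DataFrame:
    """Marginal mean/mode fill (the baseline the chained imputer must beat)."""
    out = table.copy()
    for col in out.columns:
        if _is_categorical(out[col]):
            if out[col].isna().any():
                out[col] = out[col].fillna(out[col].mode(dropna=True).iloc[0])
        else:
            out[col] = out[col].fillna(pd.to_numeric(out[col], errors="coerce").mean())
    return out


def filter_complete(
    table: pd.DataFrame,
    feature_cutoff: float = 0.02,
    feature_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rule-based completion: drop sparse features, then incomplete rows.

    Features (restricted to ``feature_cols`` when given) with missing rate
    strictly greater than ``feature_cutoff`` are dropped; afterwards every
    row still containing a missing value in the remaining features is
    dropped.  Returns the complete table and a report with both counts.
    """
    if not 0.0 <= feature_cutoff <= 1.0:
        raise ValueError("feature_cutoff must lie in [0, 1]")
    cols = feature_cols if feature_cols is not None else list(table.columns)
    rates = table[cols].isna().mean()
    dropped_features = sorted(rates.index[rates > feature_cutoff])
    out = table.drop(columns=dropped_features)
    keep_cols = [c for c in cols if c not in dropped_features]
    row_mask = out[keep_cols].notna().all(axis=1)
    n_rows_dropped = int((~row_mask).sum())
    out = out.loc[row_mask].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("filtering removed every row; relax the cutoff or impute instead")
    report = {
        "n_features_dropped": len(dropped_features),
        "dropped_features": dropped_features,
        "n_rows_dropped": n_rows_dropped,
        "n_rows_out": len(out),
    }
    return out, report
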