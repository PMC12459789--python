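"""Age-stratified splitting, gradient-boosted residual-life regression, metrics.

The regressor is a thin sklearn-style estimator over LightGBM (leaf-wise
gradient-boosted trees).  Hyperparameter presets transcribe the published
per-sex settings for the imputed and filtered datasets verbatim; the
default parameters are lighter, sized for synthetic cohorts of a few
thousand rows.  Early stopping, when enabled, monitors R² on a validation
set through a custom evaluation hook.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split

TARGET = "residual_life"

AGE_BINS = ((20.0, 40.0), (41.0, 60.0), (61.0, 120.0))


@dataclass
class SplitSpec:
    """80/10/10 split stratified by coarse age bins (20–40, 41–60, 61–120)."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    age_bins: tuple[tuple[float, float], ...] = AGE_BINS
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        lo = min(b[0] for b in self.age_bins)
        hi = max(b[1] for b in self.age_bins)
        if lo > 20.0 or hi < 120.0:
            raise ValueError("age bins must cover [20, 120]")

    def bin_labels(self, ages: np.ndarray) -> np.ndarray:
        labels = np.full(len(ages), -1)
        for k, (lo, hi) in enumerate(self.age_bins):
            sel = (ages >= lo) & (ages <= hi) if k == 0 else (ages > self.age_bins[k - 1][1]) & (ages <= hi)
            labels[sel] = k
        return labels


def stratified_split(
    cohort: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/val/test split with consistent age mix.

    Every row's age must fall inside a bin; a bin with fewer than 3 rows
    triggers a warning and unstratified best-effort assignment for the
    whole split (scikit-learn cannot stratify singleton classes).
    """
    spec = spec or SplitSpec()
    spec.validate()
    ages = cohort["chronological_age"].to_numpy()
    labels = spec.bin_labels(ages)
    if (labels < 0).any():
        bad = ages[labels < 0]
        raise ValueError(f"age(s) outside every bin: {sorted(set(np.round(bad, 2)))[:5]}")

    strat: np.ndarray | None = labels
    counts = pd.Series(labels).value_counts()
    if (counts < 3).any():
        warnings.warn("an age bin has < 3 rows; falling back to unstratified split", stacklevel=2)
        strat = None

    r_train, r_val, r_test = spec.ratios
    idx = np.arange(len(cohort))
    idx_train, idx_rest = train_test_split(
        idx, train_size=r_train, random_state=spec.seed, stratify=strat
    )
    rest_strat = labels[idx_rest] if strat is not None else None
    if rest_strat is not None and pd.Series(rest_strat).value_counts().min() < 2:
        rest_strat = None
    idx_val, idx_test = train_test_split(
        idx_rest,
        train_size=r_val / (r_val + r_test),
        random_state=spec.seed + 1,
        stratify=rest_strat,
    )
    take = lambda ix: cohort.iloc[np.sort(ix)].reset_index(drop=True)
    return take(idx_train), take(idx_val), take(idx_test)


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Named LightGBM hyperparameters for residual-life regression."""

    lambda_l1: float = 0.0
    lambda_l2: float = 0.0
    learning_rate: float = 0.05
    max_depth: int = 8
    min_child_weight: float = 1e-3
    min_data_in_leaf: int = 20
    n_estimators: int = 500
    num_leaves: int = 63
    eval_metric: str = "r2_metric"
    early_stopping_rounds: int | None = 50

    def to_dict(self) -> dict:
        return asdict(self)


#: Published per-sex settings, transcribed verbatim.
PRESETS: dict[str, ModelParams] = {
    "paper-mice-male": ModelParams(
        lambda_l1=1, lambda_l2=92, learning_rate=0.1581, max_depth=6,
        min_child_weight=5, min_data_in_leaf=50, n_estimators=2825,
        num_leaves=640, eval_metric="r2_metric", early_stopping_rounds=100,
    ),
    "paper-mice-female": ModelParams(
        lambda_l1=10, lambda_l2=90, learning_rate=0.1011, max_depth=11,
        min_child_weight=1, min_data_in_leaf=130, n_estimators=3850,
        num_leaves=3130, eval_metric="r2_metric", early_stopping_rounds=200,
    ),
    "paper-filtered-male": ModelParams(
        lambda_l1=1, lambda_l2=56, learning_rate=0.0052, max_depth=5,
        min_child_weight=0, min_data_in_leaf=20, n_estimators=4075,
        num_leaves=2510, early_stopping_rounds=None,
    ),
    "paper-filtered-female": ModelParams(
        lambda_l1=55, lambda_l2=34, learning_rate=0.0427, max_depth=10,
        min_child_weight=8, min_data_in_leaf=30, n_estimators=1550,
        num_leaves=460, early_stopping_rounds=None,
    ),
    "synthetic-default": ModelParams(),
}


def _r2_eval(y_true: np.ndarray, y_pred: np.ndarray):
    """LightGBM feval: R² on the evaluation set (higher is better)."""
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return "r2", r2, True


class ResidualLifeRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regression of residual life on exam features.

    sklearn-compatible wrapper over ``lightgbm.LGBMRegressor`` that adds
    the R²-monitored early stopping, deterministic single-thread mode, and
    schema checking at predict time.  Pass ``params=<preset name>`` or a
    :class:`ModelParams`.
    """

    def __init__(
        self,
        params: ModelParams | str = "synthetic-default",
        seed: int = 0,
        deterministic: bool = True,
    ):
        self.params = params
        self.seed = seed
        self.deterministic = deterministic

    def _resolved(self) -> ModelParams:
        if isinstance(self.params, str):
            try:
                return PRESETS[self.params]
            except KeyError:
                raise ValueError(f"unknown preset {self.params!r}; choose from {sorted(PRESETS)}")
        return self.params

    def fit(
        self,
        X: pd.DataFrame,
        y: np.ndarray | pd.Series,
        eval_set: tuple[pd.DataFrame, np.ndarray] | None = None,
    ) -> "ResidualLifeRegressor":
        if TARGET in getattr(X, "columns", []):
            raise ValueError(f"feature table must not contain the target column {TARGET!r}")
        p = self._resolved()
        kwargs = dict(
            reg_alpha=p.lambda_l1,
            reg_lambda=p.lambda_l2,
            learning_rate=p.learning_rate,
            max_depth=p.max_depth,
            min_child_weight=p.min_child_weight,
            min_child_samples=p.min_data_in_leaf,
            n_estimators=p.n_estimators,
            num_leaves=p.num_leaves,
            random_state=self.seed,
            verbose=-1,
        )
        if self.deterministic:
            kwargs.update(deterministic=True, force_row_wise=True, n_jobs=1)
        self._lgbm = lgb.LGBMRegressor(**kwargs)
        fit_kwargs: dict = {}
        if eval_set is not None and p.early_stopping_rounds:
            fit_kwargs["eval_set"] = [eval_set]
            fit_kwargs["eval_metric"] = _r2_eval
            fit_kwargs["callbacks"] = [
                lgb.early_stopping(p.early_stopping_rounds, first_metric_only=True, verbose=False)
            ]
        self._lgbm.fit(X, y, **fit_kwargs)
        self.feature_names_in_ = list(X.columns)
        self.feature_dtypes_ = {c: X[c].dtype for c in X.columns}
        self.train_target_range_ = (float(np.min(y)), float(np.max(y)))
        return self

    def coerce(self, X: pd.DataFrame) -> pd.DataFrame:
        """Reorder and cast a feature table to the training schema."""
        self._check_fitted()
        missing = set(self.feature_names_in_) - set(X.columns)
        if missing:
            raise ValueError(f"schema mismatch: missing={sorted(missing)}")
        X = X[self.feature_names_in_].copy()
        for c, dt in self.feature_dtypes_.items():
            if isinstance(dt, pd.CategoricalDtype):
                X[c] = pd.Categorical(X[c], categories=dt.categories)
            else:
                X[c] = pd.to_numeric(X[c])
        return X

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        if len(X) == 0:
            return np.empty(0)
        X = self.coerce(X)
        preds = self._lgbm.predict(X)
        if not np.all(np.isfinite(preds)):
            raise RuntimeError("non-finite prediction produced")
        lo, hi = self.train_target_range_
        n_out = int(np.sum((preds < lo - 5) | (preds > hi + 5)))
        if n_out:
            warnings.warn(f"{n_out} prediction(s) far outside the training target range", stacklevel=2)
        return preds

    @property
    def booster_(self) -> lgb.Booster:
        self._check_fitted()
        return self._lgbm.booster_

    def _check_fitted(self) -> None:
        if not hasattr(self, "_lgbm"):
            raise RuntimeError("ResidualLifeRegressor is not fitted")

    def save(self, path) -> None:
        self.booster_.save_model(str(path))


def predict_residual_life(model: ResidualLifeRegressor, table: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`ResidualLifeRegressor.predict`."""
    return model.predict(table)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """R², MAE, MSE, RMSE and the SD of the actuals, plus the sample size."""

    r_squared: float
    mae: float
    mse: float
    rmse: float
    sd: float
    n: int
    degenerate: bool = False  # zero variance in actuals: R² undefined

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(predictions: np.ndarray, actuals: np.ndarray) -> MetricsReport:
    """Evaluation-metric suite on prediction/actual pairs.

    Implements the four regression formulas directly:
    R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)², MAE = Σ|yᵢ−ŷᵢ|/n, MSE = Σ(yᵢ−ŷᵢ)²/n,
    RMSE = √MSE, together with the population SD of the actuals.
    Zero variance in the actuals flags the report as degenerate (R² set to
    0.0 by convention) instead of propagating NaN.
    """
    y_hat = np.asarray(predictions, dtype=float)
    y = np.asarray(actuals, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("predictions and actuals must be equal-length nonempty 1-D arrays")
    n = len(y)
    err = y - y_hat
    mae = float(np.sum(np.abs(err)) / n)
    mse = float(np.sum(err**2) / n)
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    degenerate = ss_tot == 0.0
    r2 = 0.0 if degenerate else 1.0 - float(np.sum(err**2)) / ss_tot
    sd = float(np.sqrt(np.sum((y - y.mean()) ** 2) / n))
    return MetricsReport(r2, mae, mse, rmse, sd, n, degenerate)


def compare_regressors(
    train: pd.DataFrame,
    val: pd.DataFrame,
    test: pd.DataFrame,
    model_specs: dict[str, object],
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Fit each spec on the same split; report test metrics sorted by R².

    ``model_specs`` maps a display name to any sklearn-style regressor
    (fit(X, y)/predict(X)).  :class:`ResidualLifeRegressor` entries get the
    validation set for early stopping.
    """
    if len(model_specs) < 2:
        raise ValueError("need at least two model specs to compare")
    cols = feature_cols or [c for c in train.columns if c != TARGET]
    rows = []
    for name, est in model_specs.items():
        if isinstance(est, ResidualLifeRegressor):
            est.fit(train[cols], train[TARGET].to_numpy(), eval_set=(val[cols], val[TARGET].to_numpy()))
        else:
            Xtr = pd.get_dummies(train[cols])
            est.fit(Xtr, train[TARGET].to_numpy())
        Xte = test[cols] if isinstance(est, ResidualLifeRegressor) else pd.get_dummies(test[cols]).reindex(
            columns=pd.get_dummies(train[cols]).columns, fill_value=0
        )
        report = evaluate(est.predict(Xte), test[TARGET].to_numpy())
        rows.append({"model": name, **report.to_dict()})
    out = pd.DataFrame(rows).sort_values("r_squared", ascending=False).reset_index(drop=True)
    return out
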