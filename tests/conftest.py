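import warnings

import pytest

import bioagekit as bk
from bioagekit.cohort import feature_columns

warnings.filterwarnings("ignore", category=UserWarning, module="lightgbm")


@pytest.fixture(scope="session")
def trained_setup():
    """A complete (no-missing) two-signal cohort with a fitted regressor.

    Age-banded exams keep the deceased-only selection mild, so the
    feature signal (lab_01 protective, lab_02 harmful, 2.5 y/SD each)
    dominates residual life and the model is strongly predictive.
    """
    cfg = bk.CohortSimConfig(
        n_persons=3000,
        n_continuous=10,
        n_categorical=2,
        signal_effects={"lab_01": 2.5, "lab_02": -2.5},
        noise_sd=2.0,
        exam_age_range=(66.0, 74.0),
        exam_years=(1998, 2005),
        frac_accidental_death=0.02,
        frac_medicated=0.03,
        seed=42,
    )
    exam, mortality, gt = bk.simulate_cohort(cfg)
    cohort, report = bk.build_cohort(exam, mortality)
    feats = feature_columns(cohort) + ["chronological_age"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train, val, test = bk.stratified_split(cohort, bk.SplitSpec(seed=0))
    model = bk.ResidualLifeRegressor(seed=0)
    model.fit(
        train[feats],
        train["residual_life"].to_numpy(),
        eval_set=(val[feats], val["residual_life"].to_numpy()),
    )
    return {
        "config": cfg,
        "ground_truth": gt,
        "cohort": cohort,
        "report": report,
        "features": feats,
        "train": train,
        "val": val,
        "test": test,
        "model": model,
    }
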