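"""Attributions, gain ranking, correlation partnering and interventions."""

import numpy as np
import pandas as pd
import pytest

import bioagekit as bk
from bioagekit.interpret import (
    AttributionVector,
    ReferenceMeans,
    attribute,
    attribute_table,
    categorize_delta,
    cohort_intervention_summary,
    correlated_partners,
    feature_gain_ranking,
    intervene,
    intervene_table,
    pcc_matrix,
    top_life_shortening,
)
from bioagekit.model import ModelParams


@pytest.fixture(scope="module")
def one_feature_model():
    """Monotone-increasing relationship: higher x -> longer residual life."""
    # noiseless response: the fitted ensemble is then empirically monotone,
    # which is the premise of the intervention-coherence property
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"x": rng.standard_normal(2000)})
    y = 10 + 3 * X["x"].to_numpy()
    params = ModelParams(n_estimators=200, early_stopping_rounds=None)
    return bk.ResidualLifeRegressor(params=params, seed=0).fit(X, y)


class TestGainRanking:
    def test_signal_features_dominate_ranking(self, trained_setup):
        top = feature_gain_ranking(trained_setup["model"], k=5)["feature"].tolist()
        assert "lab_01" in top and "lab_02" in top

    def test_single_feature_model_ranks_it_first(self, one_feature_model):
        assert feature_gain_ranking(one_feature_model, k=1)["feature"].tolist() == ["x"]

    def test_k_zero_gives_empty_list(self, trained_setup):
        assert len(feature_gain_ranking(trained_setup["model"], k=0)) == 0

    def test_k_beyond_feature_count_returns_full_list(self, one_feature_model):
        assert len(feature_gain_ranking(one_feature_model, k=99)) == 1


class TestAttribution:
    def test_additivity_on_every_test_record(self, trained_setup):
        model, test = trained_setup["model"], trained_setup["test"]
        contribs, base = attribute_table(model, test)
        preds = model.predict(test[trained_setup["features"]])
        gap = np.abs(base + contribs.sum(axis=1).to_numpy() - preds)
        assert gap.max() <= 1e-6

    def test_base_value_is_mean_training_prediction(self, trained_setup):
        model, train, feats = trained_setup["model"], trained_setup["train"], trained_setup["features"]
        _, base = attribute_table(model, train)
        assert base == pytest.approx(model.predict(train[feats]).mean(), rel=1e-6)

    def test_duplicated_record_attributes_identically(self, trained_setup):
        model, test = trained_setup["model"], trained_setup["test"]
        a = attribute(model, test.iloc[0])
        b = attribute(model, test.iloc[0])
        assert a == b

    def test_schema_mismatch_rejected(self, trained_setup):
        with pytest.raises(ValueError, match="missing"):
            attribute_table(trained_setup["model"], pd.DataFrame({"bogus": [1.0]}))

    def test_three_sd_adverse_feature_ranks_in_top_shortening(self, trained_setup):
        model, test = trained_setup["model"], trained_setup["test"]
        record = test.iloc[[0]].copy()
        record["lab_02"] = 3.0  # lab_02 costs 2.5 y/SD: 3 SD adverse
        vec = attribute(model, record)
        assert "lab_02" in top_life_shortening(vec, k=3)


class TestTopLifeShortening:
    def test_only_negative_contributions_qualify(self):
        vec = AttributionVector(0.0, {"a": -2.0, "b": -1.0, "c": 3.0}, 0.0)
        with pytest.warns(UserWarning, match="2"):
            assert top_life_shortening(vec, k=3) == ["a", "b"]

    def test_all_positive_gives_empty_with_warning(self):
        vec = AttributionVector(0.0, {"a": 1.0, "b": 2.0}, 3.0)
        with pytest.warns(UserWarning):
            assert top_life_shortening(vec, k=3) == []

    def test_ties_break_by_feature_name(self):
        vec = AttributionVector(0.0, {"b": -1.0, "a": -1.0, "c": -2.0}, -4.0)
        assert top_life_shortening(vec, k=2) == ["c", "a"]


class TestPccMatrix:
    def test_perfect_linear_relationships(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2 * df["x"]
        df["z"] = -df["x"]
        m = pcc_matrix(df, ["x", "y", "z"]).matrix
        assert m.loc["x", "y"] == pytest.approx(1.0)
        assert m.loc["x", "z"] == pytest.approx(-1.0)

    def test_hand_computed_half_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 3.0, 2.0]})
        assert pcc_matrix(df, ["x", "y"]).matrix.loc["x", "y"] == pytest.approx(0.5)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((50, 10)), columns=[f"f{i}" for i in range(10)])
        got = pcc_matrix(df, list(df.columns)).matrix.to_numpy()
        for i, a in enumerate(df.columns):
            x = df[a].to_numpy()
            for j, b in enumerate(df.columns):
                y = df[b].to_numpy()
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                assert got[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_feature_stored_as_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            m = pcc_matrix(df, ["x", "c"]).matrix
        assert np.isnan(m.loc["x", "c"]) and np.isnan(m.loc["c", "c"])

    def test_symmetry_and_unit_diagonal(self, trained_setup):
        train, feats = trained_setup["train"], trained_setup["features"]
        cont = [f for f in feats if train[f].dtype.name != "category"]
        m = pcc_matrix(train, cont).matrix.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)


class TestCorrelatedPartners:
    @pytest.fixture()
    def matrix(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(500)
        df = pd.DataFrame(
            {
                "hub": base,
                "near": base + rng.standard_normal(500) * 0.2,
                "anti": -base + rng.standard_normal(500) * 0.2,
                "far": rng.standard_normal(500),
                "mid": base + rng.standard_normal(500),
            }
        )
        return pcc_matrix(df, list(df.columns))

    def test_ranked_by_absolute_correlation_self_excluded(self, matrix):
        partners = correlated_partners(matrix, "hub", k=3)
        assert "hub" not in partners
        assert set(partners[:2]) == {"near", "anti"}

    def test_k_beyond_available_returns_all_others(self, matrix):
        assert len(correlated_partners(matrix, "hub", k=99)) == 4

    def test_unknown_feature_rejected(self, matrix):
        with pytest.raises(KeyError):
            correlated_partners(matrix, "nope")


class TestIntervention:
    def test_boundary_follows_strict_less_than_rule(self):
        assert categorize_delta(0.49) == "unchanged"
        assert categorize_delta(0.5) == "improved"
        assert categorize_delta(-0.5) == "worsened"
        assert categorize_delta(-0.49) == "unchanged"

    def test_record_already_at_reference_means_is_unchanged(self, trained_setup):
        model, train, feats = trained_setup["model"], trained_setup["train"], trained_setup["features"]
        cont = [f for f in feats if train[f].dtype.name != "category"]
        matrix = pcc_matrix(train, cont)
        refs = ReferenceMeans(train, feats, granularity="global")
        record = train.iloc[0].copy()
        for f in feats:
            record[f] = refs.value_for(record, f)
        vec = attribute(model, pd.DataFrame([record]))
        res = intervene(record, model, vec, matrix, refs)
        assert res.delta == pytest.approx(0.0, abs=1e-9)
        assert res.category == "unchanged"

    def test_adverse_record_improves(self, trained_setup):
        model, train, test, feats = (
            trained_setup["model"], trained_setup["train"], trained_setup["test"], trained_setup["features"],
        )
        cont = [f for f in feats if train[f].dtype.name != "category"]
        matrix = pcc_matrix(train, cont)
        refs = ReferenceMeans(train, feats, granularity="global")
        record = test.iloc[0].copy()
        record["lab_02"] = 3.0  # strongly adverse on the harmful signal feature
        vec = attribute(model, pd.DataFrame([record]))
        res = intervene(record, model, vec, matrix, refs)
        assert "lab_02" in res.factors
        assert res.delta > 0

    def test_missing_reference_mean_raises_naming_feature(self, trained_setup):
        model, train, test, feats = (
            trained_setup["model"], trained_setup["train"], trained_setup["test"], trained_setup["features"],
        )
        cont = [f for f in feats if train[f].dtype.name != "category"]
        matrix = pcc_matrix(train, cont)
        refs = ReferenceMeans(train, ["lab_01"], granularity="global")
        record = test.iloc[0].copy()
        record["lab_02"] = 3.0
        vec = attribute(model, pd.DataFrame([record]))
        with pytest.raises(KeyError):
            intervene(record, model, vec, matrix, refs)

    def test_monotone_model_never_worsens_when_moving_toward_mean(self, one_feature_model):
        """With residual life increasing in x, raising an adverse (low) x
        toward the mean must never lower the prediction."""
        model = one_feature_model
        grid = pd.DataFrame({"x": np.linspace(-3, 0, 40)})
        preds = model.predict(grid)
        assert np.all(np.diff(preds) >= -1e-9)

    def test_cohort_summary_fractions_sum_to_one(self, trained_setup):
        model, train, test, feats = (
            trained_setup["model"], trained_setup["train"], trained_setup["test"], trained_setup["features"],
        )
        cont = [f for f in feats if train[f].dtype.name != "category"]
        matrix = pcc_matrix(train, cont)
        refs = ReferenceMeans(train.assign(sex="male"), feats)
        results = intervene_table(test.head(200), model, matrix, refs)
        summary = cohort_intervention_summary(results)
        assert sum(summary.values()) == pytest.approx(1.0)
        assert set(summary) == {"improved", "unchanged", "worsened"}

    def test_full_explain_intervene_pass_is_reproducible(self, trained_setup):
        model, train, test, feats = (
            trained_setup["model"], trained_setup["train"], trained_setup["test"], trained_setup["features"],
        )
        cont = [f for f in feats if train[f].dtype.name != "category"]
        matrix = pcc_matrix(train, cont)
        refs = ReferenceMeans(train, feats, granularity="global")
        r1 = intervene_table(test.head(50), model, matrix, refs)
        r2 = intervene_table(test.head(50), model, matrix, refs)
        assert [(r.delta, r.category, r.factors) for r in r1] == [
            (r.delta, r.category, r.factors) for r in r2
        ]

    def test_all_improved_fixture_summarises_to_unity(self):
        from bioagekit.interpret import InterventionResult

        results = [InterventionResult(delta=1.0, category="improved") for _ in range(5)]
        assert cohort_intervention_summary(results) == {"improved": 1.0, "unchanged": 0.0, "worsened": 0.0}
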