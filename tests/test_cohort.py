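"""Cohort construction: merging, exclusion rules, residual-life target."""

import numpy as np
import pandas as pd
import pytest

import bioagekit as bk
from bioagekit.cohort import (
    CohortConfig,
    EmptyCohortError,
    IntegrityError,
    apply_exclusions,
    build_cohort,
    compute_residual_life,
    drop_sparse_features,
    merge_records,
    retain_deceased,
)


def exam_row(pid="c19b000001", date="2010-12-01", age=50.0, med=0, **feats):
    row = {
        "pid": pid,
        "exam_date": pd.Timestamp(date),
        "sex": "male",
        "chronological_age": age,
        "long_term_medication": med,
    }
    row.update(feats)
    return row


def mortality_row(pid="c19b000001", death="2018-05-01", cause="malignant tumor"):
    return {"pid": pid, "death_date": pd.Timestamp(death) if death else pd.NaT, "cause_of_death": cause}


class TestMergeRecords:
    def test_exam_row_joined_with_death_information(self):
        exam = pd.DataFrame([exam_row(lab_01=1.2)])
        mort = pd.DataFrame([mortality_row()])
        merged = merge_records(exam, mort)
        assert len(merged) == 1
        assert merged.loc[0, "death_date"] == pd.Timestamp("2018-05-01")
        assert merged.loc[0, "cause_of_death"] == "malignant tumor"
        assert merged.loc[0, "lab_01"] == 1.2

    def test_empty_exam_table_gives_empty_merge(self):
        exam = pd.DataFrame(columns=["pid", "exam_date", "chronological_age"])
        mort = pd.DataFrame([mortality_row()])
        assert len(merge_records(exam, mort)) == 0

    def test_three_visits_share_one_death_date(self):
        exam = pd.DataFrame([exam_row(date=d) for d in ("2005-01-01", "2007-06-01", "2010-12-01")])
        merged = merge_records(exam, pd.DataFrame([mortality_row()]))
        assert len(merged) == 3
        assert merged["death_date"].nunique() == 1

    def test_unmatched_pid_is_an_integrity_error(self):
        exam = pd.DataFrame([exam_row(pid="ghost")])
        with pytest.raises(IntegrityError, match="ghost"):
            merge_records(exam, pd.DataFrame([mortality_row()]))

    def test_duplicate_mortality_pid_rejected(self):
        exam = pd.DataFrame([exam_row()])
        mort = pd.DataFrame([mortality_row(), mortality_row()])
        with pytest.raises(IntegrityError, match="duplicate"):
            merge_records(exam, mort)


class TestApplyExclusions:
    def fixture_table(self):
        rows = (
            [exam_row(pid=f"a{i}") | {"cause_of_death": "accidental injury"} for i in range(2)]
            + [exam_row(pid="u0", age=19.9) | {"cause_of_death": "pneumonia"}]
            + [exam_row(pid=f"m{i}", med=1) | {"cause_of_death": "pneumonia"} for i in range(3)]
            + [exam_row(pid=f"k{i}") | {"cause_of_death": "pneumonia"} for i in range(4)]
        )
        df = pd.DataFrame(rows)
        df["death_date"] = pd.Timestamp("2015-01-01")
        return df

    def test_disjoint_rule_counts_and_survivors(self):
        out, report = apply_exclusions(self.fixture_table())
        assert len(out) == 4
        assert report.removed == {"accidental_death": 2, "under_20": 1, "long_term_medication": 3}
        assert report.consistent()

    def test_age_boundary_twenty_is_retained(self):
        df = pd.DataFrame([exam_row(pid="x", age=19.9), exam_row(pid="y", age=20.0)])
        df["cause_of_death"] = "pneumonia"
        df["death_date"] = pd.Timestamp("2015-01-01")
        out, report = apply_exclusions(df)
        assert list(out["pid"]) == ["y"]
        assert report.removed["under_20"] == 1

    def test_missing_flag_column_is_configuration_error(self):
        df = self.fixture_table().drop(columns="long_term_medication")
        with pytest.raises(Exception, match="long_term_medication"):
            apply_exclusions(df)


class TestDropSparseFeatures:
    def make(self, rates):
        n = 100
        rng = np.random.default_rng(0)
        df = pd.DataFrame([exam_row(pid=f"p{i}") for i in range(n)])
        for j, rate in enumerate(rates):
            col = rng.standard_normal(n)
            vals = pd.Series(col)
            k = int(round(rate * n))
            vals.iloc[:k] = np.nan
            df[f"f{j}"] = vals
        return df

    def test_strictly_greater_than_cutoff_dropped(self):
        df = self.make([0.0, 0.5, 0.91, 0.99, 1.0])
        out, dropped = drop_sparse_features(df, cutoff=0.90)
        assert dropped == ["f2", "f3", "f4"]
        assert {"f0", "f1"} <= set(out.columns)

    def test_exactly_at_cutoff_retained(self):
        df = self.make([0.90])
        out, dropped = drop_sparse_features(df, cutoff=0.90)
        assert dropped == []
        assert "f0" in out.columns


class TestRetainDeceased:
    def test_mixed_cohort_keeps_only_deceased(self):
        df = pd.DataFrame([exam_row(pid=f"p{i}") for i in range(10)])
        df["death_date"] = [pd.Timestamp("2015-01-01")] * 6 + [pd.NaT] * 4
        assert len(retain_deceased(df)) == 6

    def test_all_deceased_is_identity(self):
        df = pd.DataFrame([exam_row(pid=f"p{i}") for i in range(3)])
        df["death_date"] = pd.Timestamp("2015-01-01")
        pd.testing.assert_frame_equal(retain_deceased(df), df)

    def test_all_censored_raises_empty_cohort(self):
        df = pd.DataFrame([exam_row()])
        df["death_date"] = pd.NaT
        with pytest.raises(EmptyCohortError):
            retain_deceased(df)


class TestComputeResidualLife:
    def test_published_example_dates(self):
        # 2010-12-01 to 2018-05-01 is 2708 calendar days
        got = compute_residual_life(pd.Timestamp("2010-12-01"), pd.Timestamp("2018-05-01"))
        assert got == pytest.approx(2708 / 365.25, abs=1e-12)

    def test_same_day_death_is_zero(self):
        assert compute_residual_life(pd.Timestamp("2010-12-01"), pd.Timestamp("2010-12-01")) == 0.0

    def test_leap_year_span(self):
        got = compute_residual_life(pd.Timestamp("2000-01-01"), pd.Timestamp("2001-01-01"))
        assert got == pytest.approx(366 / 365.25, abs=1e-12)

    def test_death_before_exam_rejected(self):
        with pytest.raises(IntegrityError):
            compute_residual_life(pd.Timestamp("2010-01-02"), pd.Timestamp("2010-01-01"))


class TestBuildCohortPipeline:
    def test_row_conservation_and_report_consistency(self, trained_setup):
        report = trained_setup["report"]
        assert report.consistent()
        assert report.n_input == report.n_output + sum(report.removed.values())

    def test_residual_life_positive_and_under20_absent(self, trained_setup):
        cohort = trained_setup["cohort"]
        assert (cohort["residual_life"] > 0).all()
        assert (cohort["chronological_age"] >= 20).all()

    def test_sparse_features_absent_from_cohort(self):
        cfg = bk.CohortSimConfig(
            n_persons=400, n_continuous=6, n_categorical=1,
            sparse_features={"qn_01": 0.97}, exam_age_range=(66.0, 74.0),
            exam_years=(1998, 2005), seed=2,
        )
        exam, mort, _ = bk.simulate_cohort(cfg)
        exam = bk.inject_missingness(exam, cfg)
        cohort, report = build_cohort(exam, mort)
        assert "qn_01" in report.dropped_features
        assert "qn_01" not in cohort.columns

    def test_pipeline_is_idempotent_on_its_own_output(self, trained_setup):
        cohort = trained_setup["cohort"]
        again, report = apply_exclusions(cohort)
        pd.testing.assert_frame_equal(again, cohort)
        out, dropped = drop_sparse_features(again)
        assert dropped == []
        pd.testing.assert_frame_equal(retain_deceased(out), cohort)

    def test_excluding_accidental_deaths_improves_fit(self):
        """Accidental deaths carry artificially shortened lifetimes, so a
        model trained with them included fits held-out natural deaths worse."""
        from bioagekit.cohort import feature_columns

        deltas = []
        for seed in (0, 1, 2):
            cfg = bk.CohortSimConfig(
                n_persons=2500, n_continuous=8, n_categorical=0,
                signal_effects={"lab_01": 2.5, "lab_02": -2.5}, noise_sd=2.0,
                exam_age_range=(66.0, 74.0), exam_years=(1998, 2005),
                frac_accidental_death=0.25, seed=seed,
            )
            exam, mort, _ = bk.simulate_cohort(cfg)
            with_acc = CohortConfig(accidental_causes=())
            cohort_in, _ = build_cohort(exam, mort, with_acc)
            cohort_ex, _ = build_cohort(exam, mort)
            feats = feature_columns(cohort_in) + ["chronological_age"]
            r2 = {}
            for name, cohort in (("incl", cohort_in), ("excl", cohort_ex)):
                tr, va, te = bk.stratified_split(cohort, bk.SplitSpec(seed=seed))
                # evaluate on natural-cause deaths only, the population of interest
                te = te[te["cause_of_death"] != "accidental injury"]
                m = bk.ResidualLifeRegressor(seed=seed)
                m.fit(tr[feats], tr["residual_life"].to_numpy(),
                      eval_set=(va[feats], va["residual_life"].to_numpy()))
                r2[name] = bk.evaluate(m.predict(te[feats]), te["residual_life"].to_numpy()).r_squared
            deltas.append(r2["excl"] - r2["incl"])
        assert sum(d > 0 for d in deltas) >= 2
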