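"""Pipeline stages: validation, outlier screen, split, evaluation, stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle_exact_tests as enum_oracle
from iolopt import (InvalidInputError, LensConstants, PipelineAbortError,
                    SchemaError, StratumEmptyError, evaluate_formulas,
                    exclude_outliers, one_eye_per_patient, pe_regression,
                    run_study, split_train_test, validate_cohort, welch_t,
                    wilcoxon_rank_sum, wilcoxon_signed_rank)
from iolopt.cohort import (biometry_summary_table, cohort_spe,
                           record_from_row)


def _well_formed_rows(n=10):
    rng = np.random.default_rng(5)
    sph = rng.uniform(-1.5, 0.5, n).round(2)
    cyl = rng.uniform(0.0, 1.5, n).round(2)
    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "eye": (["OD", "OS"] * n)[:n],
        "gender": (["female", "male"] * n)[:n],
        "age_years": rng.uniform(55, 85, n),
        "al_mm": rng.uniform(22, 26, n),
        "cct_um": rng.uniform(500, 600, n),
        "ad_mm": rng.uniform(2.2, 3.2, n),
        "acd_mm": rng.uniform(2.8, 3.8, n),
        "lt_mm": rng.uniform(4.0, 5.0, n),
        "km_d": rng.uniform(41, 46, n),
        "ast_d": rng.uniform(0, 2, n),
        "wtw_mm": rng.uniform(11.2, 12.8, n),
        "iol_power_d": rng.integers(20, 50, n) / 2.0,
        "postop_sphere_d": sph,
        "postop_cyl_d": cyl,
        "postop_se_d": sph + cyl / 2.0,
    })


class TestValidation:
    def test_clean_fixture_passes(self):
        valid, report = validate_cohort(_well_formed_rows())
        assert len(valid) == 10
        assert report["reasons"] == {}
        # every surviving row materializes as a validated record
        for row in valid.itertuples():
            record_from_row(row)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="al_mm"):
            validate_cohort(_well_formed_rows().drop(columns=["al_mm"]))

    def test_empty_table_is_schema_error(self):
        with pytest.raises(SchemaError):
            validate_cohort(_well_formed_rows().iloc[:0])

    @pytest.mark.parametrize("mutate, reason", [
        (lambda df: df.assign(
            postop_cyl_d=[np.nan] + df["postop_cyl_d"].tolist()[1:]),
         "incomplete refraction"),
        (lambda df: df.assign(prior_refractive_surgery=[True] + [False] * 9),
         "prior refractive surgery"),
        (lambda df: df.assign(gender=["unknown"] + ["male"] * 9),
         "unknown gender code"),
        (lambda df: df.assign(iol_power_d=[20.3] + [21.0] * 9),
         "iol power missing, out of range or off the 0.5 D grid"),
        (lambda df: df.assign(al_mm=[41.0] + [24.0] * 9),
         "biometry out of range"),
    ])
    def test_single_bad_row_rejected_with_reason(self, mutate, reason):
        df = mutate(_well_formed_rows())
        if "postop_cyl_d" in reason or "incomplete" in reason:
            pass
        valid, report = validate_cohort(df)
        assert report["reasons"].get(reason) == 1
        assert len(valid) == 9

    def test_duplicate_patient_eye_rejected(self):
        df = _well_formed_rows()
        df.loc[1, ["patient_id", "eye"]] = df.loc[0, ["patient_id", "eye"]]
        valid, report = validate_cohort(df)
        assert report["reasons"]["duplicate patient-eye record"] == 1
        assert len(valid) == 9

    def test_gender_codes_normalized(self):
        df = _well_formed_rows()
        df["gender"] = ["F", "M"] * 5
        valid, report = validate_cohort(df)
        assert set(valid["gender"]) == {"female", "male"}


class TestOutlierScreen:
    def test_borderline_point_kept(self):
        df = _well_formed_rows(5)
        spe = np.array([0.0, 0.0, 0.0, 0.0, 10.0])
        # z of the extreme point: (10 - 2)/sqrt(20) = 1.789 < 1.96
        kept, removed = exclude_outliers(df, spe)
        assert removed == 0 and len(kept) == 5

    def test_extreme_point_removed(self):
        df = _well_formed_rows(6)
        spe = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 100.0])
        # z = (100 - 16.67)/40.82 = 2.04 > 1.96
        kept, removed = exclude_outliers(df, spe)
        assert removed == 1 and len(kept) == 5
        assert kept["patient_id"].tolist() == df["patient_id"].tolist()[:5]

    def test_constant_spe_removes_nothing(self):
        df = _well_formed_rows(6)
        kept, removed = exclude_outliers(df, np.full(6, 0.25))
        assert removed == 0 and len(kept) == 6

    def test_all_removed_aborts(self):
        df = _well_formed_rows(4)
        with pytest.raises(PipelineAbortError):
            exclude_outliers(df, np.array([-1.0, -0.5, 0.5, 1.0]),
                             z_threshold=0.3)


class TestSplit:
    def test_deterministic_for_seed(self, small_cohort):
        cohort, _, _ = small_cohort
        a = split_train_test(cohort, seed=3)
        b = split_train_test(cohort, seed=3)
        assert a.side == b.side and a.test_eye == b.test_eye

    def test_bilateral_patients_not_torn_apart(self, small_cohort):
        cohort, _, _ = small_cohort
        split = split_train_test(cohort, seed=3)
        sides = cohort["patient_id"].map(split.side)
        assert (sides.groupby(cohort["patient_id"]).nunique() == 1).all()
        train = split.training_frame(cohort)
        test = split.testing_frame(cohort)
        assert set(train["patient_id"]).isdisjoint(test["patient_id"])
        assert (test.groupby("patient_id").size() == 1).all()

    def test_split_fraction_concentrates(self):
        patients = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(10_000)],
            "eye": "OD"})
        split = split_train_test(patients, seed=1)
        frac = np.mean([v == "train" for v in split.side.values()])
        assert 0.48 <= frac <= 0.52

    def test_one_eye_per_patient_weighting(self, small_cohort):
        cohort, _, _ = small_cohort
        single = one_eye_per_patient(cohort, seed=9)
        assert single["patient_id"].is_unique
        assert len(single) == cohort["patient_id"].nunique()


class TestEvaluation:
    def test_perfect_constants_zero_error(self, unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(200, seed=31, noise_sd=0.0)
        constants = {"srkt": {"all": LensConstants.srkt(119.0)}}
        pred, summary = evaluate_formulas(cohort, constants, "pooled",
                                          formulas=("srkt",))
        assert np.max(pred["ape_d"]) < 1e-9
        assert summary.loc[summary["group"] == "overall",
                           "mean_ape_d"].iloc[0] < 1e-9

    def test_ape_is_absolute_spe(self, unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(200, seed=32, noise_sd=0.4)
        constants = {"srkt": {"all": LensConstants.srkt(119.0)}}
        pred, _ = evaluate_formulas(cohort, constants, "pooled",
                                    formulas=("srkt",))
        assert np.allclose(pred["ape_d"], np.abs(pred["spe_d"]))

    def test_missing_stratum_constant_rejected(self,
                                               unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(100, seed=33, noise_sd=0.0)
        constants = {"srkt": {"female": LensConstants.srkt(119.0)}}
        with pytest.raises(InvalidInputError, match="male"):
            evaluate_formulas(cohort, constants, "by_gender",
                              formulas=("srkt",))

    def test_gender_offsets_produce_opposite_sign_spe(
            self, unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(4000, seed=34, noise_sd=0.4,
                                              offset_f=0.07, offset_m=-0.10)
        constants = {"srkt": {"all": LensConstants.srkt(119.0)}}
        pred, summary = evaluate_formulas(cohort, constants, "pooled",
                                          formulas=("srkt",))
        f = summary.loc[summary["group"] == "female", "mean_spe_d"].iloc[0]
        m = summary.loc[summary["group"] == "male", "mean_spe_d"].iloc[0]
        assert f > 0 > m


class TestStatistics:
    def test_rank_sum_worked_example(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]).p_value == pytest.approx(
            1.0 / 3.0, abs=1e-12)

    def test_rank_sum_identical_samples(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_rank_sum_matches_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(1, 9))
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = vals[:n], vals[n:]
            assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
                enum_oracle.rank_sum_exact_p(x, y), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=2, max_size=8, unique=True),
           st.lists(st.integers(41, 80), min_size=2, max_size=8, unique=True))
    def test_rank_sum_invariant_under_monotone_transform(self, x, y):
        direct = wilcoxon_rank_sum(x, y).p_value
        transformed = wilcoxon_rank_sum(np.exp(np.asarray(x) / 10.0),
                                        np.exp(np.asarray(y) / 10.0)).p_value
        assert direct == pytest.approx(transformed, abs=1e-12)

    def test_welch_worked_example(self):
        res = welch_t([0.0, 1.0], [10.0, 11.0])
        assert res.statistic == pytest.approx(-14.1421356, abs=1e-6)
        flipped = welch_t([10.0, 11.0], [0.0, 1.0])
        assert flipped.statistic == pytest.approx(-res.statistic, abs=1e-12)
        assert flipped.p_value == pytest.approx(res.p_value, abs=1e-12)

    def test_welch_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_welch_degenerate_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_signed_rank_worked_examples(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0]).p_value == pytest.approx(
            0.25, abs=1e-12)
        res = wilcoxon_signed_rank(np.zeros(5))
        assert res.p_value == 1.0

    def test_signed_rank_sign_flip_invariance(self):
        d = np.array([0.3, -1.2, 0.7, 2.0, -0.4])
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_signed_rank(-d).p_value, abs=1e-12)

    def test_signed_rank_matches_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            n = int(rng.integers(1, 9))
            d = rng.permutation(np.arange(1.0, n + 1)) * rng.choice([-1, 1], n)
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                enum_oracle.signed_rank_exact_p(d), abs=1e-12)


class TestRegression:
    def test_null_gender_effect(self, unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(2000, seed=41, noise_sd=0.4)
        constants = {"srkt": {"all": LensConstants.srkt(119.0)}}
        pred, _ = evaluate_formulas(cohort, constants, "pooled",
                                    formulas=("srkt",))
        coefs, tests = pe_regression(cohort, pred, formulas=("srkt",))
        male = coefs[(coefs["formula_id"] == "srkt")
                     & (coefs["term"] == "male")].iloc[0]
        assert abs(male["coef"]) < 2 * male["se"] + 1e-12

    def test_injected_gender_shift_recovered(self,
                                             unilateral_cohort_factory):
        """Shifting male observed SE by -0.08 D shifts male SPE by +0.08 and
        the regression recovers that coefficient within 0.02."""
        cohort, _ = unilateral_cohort_factory(8000, seed=42, noise_sd=0.4,
                                              offset_m=0.08)
        constants = {"srkt": {"all": LensConstants.srkt(119.0)}}
        pred, _ = evaluate_formulas(cohort, constants, "pooled",
                                    formulas=("srkt",))
        coefs, tests = pe_regression(cohort, pred, formulas=("srkt",))
        male = coefs[(coefs["formula_id"] == "srkt")
                     & (coefs["term"] == "male")].iloc[0]
        assert male["coef"] == pytest.approx(0.08, abs=0.02)
        assert tests["srkt"]["p_value"] < 0.001

    def test_duplication_leaves_coefficients_unchanged(
            self, unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(500, seed=43, noise_sd=0.4)
        constants = {"srkt": {"all": LensConstants.srkt(119.0)}}
        pred, _ = evaluate_formulas(cohort, constants, "pooled",
                                    formulas=("srkt",))
        coefs1, _ = pe_regression(cohort, pred, formulas=("srkt",))
        doubled = pd.concat([cohort, cohort.assign(
            patient_id=cohort["patient_id"] + "b")], ignore_index=True)
        pred2, _ = evaluate_formulas(doubled, constants, "pooled",
                                     formulas=("srkt",))
        coefs2, _ = pe_regression(doubled, pred2, formulas=("srkt",))
        merged = coefs1.merge(coefs2, on=["formula_id", "term"],
                              suffixes=("_1", "_2"))
        assert np.allclose(merged["coef_1"], merged["coef_2"], atol=1e-9)
        assert (merged["se_2"] < merged["se_1"]).all()

    def test_collinear_design_rejected(self, unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(200, seed=44, noise_sd=0.4)
        cohort = cohort.copy()
        cohort["cct_um"] = 2.0 * cohort["al_mm"]   # force exact collinearity
        constants = {"srkt": {"all": LensConstants.srkt(119.0)}}
        pred, _ = evaluate_formulas(cohort, constants, "pooled",
                                    formulas=("srkt",))
        with pytest.raises(InvalidInputError, match="collinear"):
            pe_regression(cohort, pred, formulas=("srkt",))


class TestStudy:
    def test_full_study_tables_and_determinism(self, small_cohort):
        cohort, _, _ = small_cohort
        res1 = run_study(cohort, seed=2)
        res2 = run_study(cohort, seed=2)
        assert set(res1.tables) == {
            "table1_biometry", "table2_prediction_error", "table3_regression",
            "table4_constants", "table5_mae"}
        for name in res1.tables:
            pd.testing.assert_frame_equal(res1.tables[name],
                                          res2.tables[name])
        for fid, strata in res1.constants.items():
            assert all(r.converged for r in strata.values())

    def test_summary_ci_half_width(self, small_cohort):
        cohort, _, _ = small_cohort
        table = biometry_summary_table(cohort, seed=2)
        row = table[table["variable"] == "AL (mm)"].iloc[0]
        al = cohort["al_mm"].to_numpy()
        half = 1.96 * al.std(ddof=1) / np.sqrt(al.size)
        assert row["overall_ci_hi"] - row["overall_mean"] == pytest.approx(
            half, abs=1e-9)
        assert row["overall_median"] == pytest.approx(np.median(al), abs=1e-12)

    def test_single_gender_cohort_fails_reporting(
            self, unilateral_cohort_factory):
        cohort, _ = unilateral_cohort_factory(120, seed=45, noise_sd=0.4)
        with pytest.raises(StratumEmptyError):
            biometry_summary_table(cohort[cohort["gender"] == "female"],
                                   seed=1)

    def test_mae_never_below_absolute_mean_spe(self, small_cohort):
        cohort, _, _ = small_cohort
        res = run_study(cohort, seed=2)
        for fid in ("srkt", "haigis"):
            sub = res.summary_pooled
            row = sub[(sub["formula_id"] == fid)
                      & (sub["group"] == "overall")].iloc[0]
            assert row["mean_ape_d"] >= abs(row["mean_spe_d"]) - 1e-12

    def test_outlier_screen_uses_reference_formula(self, small_cohort):
        cohort, _, _ = small_cohort
        spe = cohort_spe(cohort, "srkt", LensConstants.srkt(119.0))
        _, n_direct = exclude_outliers(cohort, spe)
        res = run_study(cohort, seed=2)
        assert res.n_outliers_removed == n_direct
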