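"""The study pipeline on a per-eye cohort table.

Stages, in the order a constant-personalization study runs them:

1. :func:`validate_cohort` — schema and invariant checks with a per-reason
   rejection report (nothing is dropped silently).
2. :func:`exclude_outliers` — single-pass removal of eyes whose signed
   prediction error under a reference formula lies more than z standard
   deviations from the cohort mean (unreliable refractions).
3. :func:`split_train_test` — patient-level 1:1 split; one randomly chosen
   eye per test patient so every patient carries the same weight in
   evaluation.
4. :func:`evaluate_formulas` — per-eye predictions, signed and absolute
   prediction errors, gender-stratified summaries, MAE.
5. Statistics: Wilcoxon rank-sum (biometry and SPE gender contrasts), Welch
   t (SPE/APE gender contrasts), paired Wilcoxon signed-rank (pooled vs
   gender-stratified constants on the same eyes), and an OLS regression of
   SPE on biometry + gender with a likelihood-ratio test for the gender
   term.
6. :func:`run_study` / :func:`make_report` — the whole pipeline and its
   summary tables.

The cohort container is a pandas DataFrame with one row per operated eye
(columns documented in ``REQUIRED_COLUMNS``); :class:`EyeRecord` gives the
validated scalar view of one row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import (InvalidInputError, PipelineAbortError, SchemaError,
                     StratumEmptyError)
from .formulas import (DEFAULT_PARAMS, FORMULAS, EyeBiometry, LensConstants,
                       OpticalModelParams, predict_refraction_arrays)
from .optimize import (DEFAULT_START_CONSTANTS, DEFAULT_TOL_D,
                       optimize_by_gender)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "patient_id", "eye", "gender", "age_years", "al_mm", "cct_um", "ad_mm",
    "acd_mm", "lt_mm", "km_d", "ast_d", "wtw_mm", "iol_power_d",
    "postop_sphere_d", "postop_cyl_d", "postop_se_d",
)

GENDERS = ("female", "male")
_GENDER_ALIASES = {"female": "female", "f": "female", "male": "male",
                   "m": "male"}


@dataclass(frozen=True)
class EyeRecord:
    """One operated eye: demographics, biometry, implant, outcome."""

    patient_id: str
    eye: str                    # "OD" or "OS"
    gender: str                 # "female" or "male"
    age_years: float
    biometry: EyeBiometry
    iol_power_d: float
    postop_sphere_d: float
    postop_cyl_d: float
    postop_se_d: float

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise InvalidInputError(f"eye must be OD or OS: {self.eye!r}")
        if self.gender not in GENDERS:
            raise InvalidInputError(f"unknown gender {self.gender!r}")
        se = self.postop_sphere_d + self.postop_cyl_d / 2.0
        if abs(se - self.postop_se_d) > 1e-9:
            raise InvalidInputError("postop_se_d inconsistent with "
                                    "sphere + cyl/2")


@dataclass(frozen=True)
class PredictionResult:
    """Predicted refraction and its errors for one eye under one formula."""

    patient_id: str
    eye: str
    formula_id: str
    predicted_se_d: float
    spe_d: float   # predicted - observed
    ape_d: float   # |spe_d|


@dataclass(frozen=True)
class SplitAssignment:
    """Patient-level train/test assignment plus the chosen test eye."""

    side: dict          # patient_id -> "train" | "test"
    test_eye: dict      # test patient_id -> "OD" | "OS"
    seed: int

    def training_frame(self, cohort: pd.DataFrame) -> pd.DataFrame:
        mask = cohort["patient_id"].map(self.side) == "train"
        return cohort[mask].reset_index(drop=True)

    def testing_frame(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """One chosen eye per test patient."""
        chosen = cohort["patient_id"].map(self.test_eye)
        mask = chosen.notna() & (cohort["eye"] == chosen)
        return cohort[mask].reset_index(drop=True)


@dataclass(frozen=True)
class StatTestResult:
    name: str
    statistic: float
    p_value: float
    n: tuple
    group_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidInputError(f"p-value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# validation


def validate_cohort(raw: pd.DataFrame) -> tuple:
    """Check schema and row invariants; return (valid frame, report).

    The report maps each rejection reason to the count of offending rows (a
    row violating several invariants is counted under each reason but
    rejected once). Unknown gender codes, incomplete refractions and rows
    flagged ``prior_refractive_surgery`` are rejected, never silently
    dropped.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    if len(raw) == 0:
        raise SchemaError("cohort table has no rows")

    df = raw.copy().reset_index(drop=True)
    reasons: dict = {}
    rejected = np.zeros(len(df), dtype=bool)

    def flag(mask: np.ndarray, reason: str) -> None:
        nonlocal rejected
        mask = np.asarray(mask, dtype=bool)
        if mask.any():
            reasons[reason] = int(mask.sum())
            rejected |= mask

    if "prior_refractive_surgery" in df.columns:
        prior = df["prior_refractive_surgery"].fillna(False).astype(bool)
        flag(prior.to_numpy(), "prior refractive surgery")

    gender_norm = df["gender"].astype(str).str.strip().str.lower()
    df["gender"] = gender_norm.map(_GENDER_ALIASES)
    flag(df["gender"].isna().to_numpy(), "unknown gender code")

    flag(~df["eye"].isin(["OD", "OS"]).to_numpy(), "invalid eye code")

    refr = df[["postop_sphere_d", "postop_cyl_d", "postop_se_d"]].apply(
        pd.to_numeric, errors="coerce")
    incomplete = refr.isna().any(axis=1).to_numpy()
    flag(incomplete, "incomplete refraction")
    se_calc = refr["postop_sphere_d"] + refr["postop_cyl_d"] / 2.0
    inconsistent = (~incomplete
                    & ((se_calc - refr["postop_se_d"]).abs() > 1e-9).to_numpy())
    flag(inconsistent, "spherical equivalent inconsistent with sphere+cyl/2")

    bio = df[["al_mm", "acd_mm", "km_d", "ast_d"]].apply(pd.to_numeric,
                                                         errors="coerce")
    missing_bio = bio.isna().any(axis=1).to_numpy()
    flag(missing_bio, "missing biometry")
    out_of_range = (~missing_bio & (
        ~bio["al_mm"].between(15, 40, inclusive="neither")
        | ~bio["km_d"].between(30, 60, inclusive="neither")
        | ~bio["acd_mm"].between(1.5, 6, inclusive="neither")
        | (bio["ast_d"] < 0)).to_numpy())
    flag(out_of_range, "biometry out of range")

    power = pd.to_numeric(df["iol_power_d"], errors="coerce")
    bad_power = (power.isna() | (power < -10) | (power > 40)
                 | ((power * 2 - (power * 2).round()).abs() > 1e-6)).to_numpy()
    flag(bad_power, "iol power missing, out of range or off the 0.5 D grid")

    dup = df.duplicated(subset=["patient_id", "eye"], keep="first").to_numpy()
    flag(dup, "duplicate patient-eye record")

    valid = df[~rejected].reset_index(drop=True)
    report = {"n_input": int(len(df)), "n_valid": int(len(valid)),
              "n_rejected": int(rejected.sum()), "reasons": reasons}
    logger.info("validate_cohort: %d/%d rows accepted; rejections: %s",
                report["n_valid"], report["n_input"], reasons or "none")
    return valid, report


def record_from_row(row) -> EyeRecord:
    """Validated scalar view of one cohort row (pandas Series/namedtuple)."""
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    biometry = EyeBiometry(al_mm=float(get("al_mm")),
                           acd_mm=float(get("acd_mm")),
                           km_d=float(get("km_d")),
                           ad_mm=float(get("ad_mm")),
                           cct_um=float(get("cct_um")),
                           lt_mm=float(get("lt_mm")),
                           ast_d=float(get("ast_d")),
                           wtw_mm=float(get("wtw_mm")))
    return EyeRecord(patient_id=str(get("patient_id")), eye=str(get("eye")),
                     gender=str(get("gender")),
                     age_years=float(get("age_years")), biometry=biometry,
                     iol_power_d=float(get("iol_power_d")),
                     postop_sphere_d=float(get("postop_sphere_d")),
                     postop_cyl_d=float(get("postop_cyl_d")),
                     postop_se_d=float(get("postop_se_d")))


# ---------------------------------------------------------------------------
# filtering and splitting


def cohort_spe(cohort: pd.DataFrame, formula_id: str,
               constants: LensConstants,
               params: OpticalModelParams = DEFAULT_PARAMS) -> np.ndarray:
    """Signed prediction error of every row under one formula/constant."""
    predicted = predict_refraction_arrays(
        formula_id, constants,
        al_mm=cohort["al_mm"].to_numpy(float),
        km_d=cohort["km_d"].to_numpy(float),
        iol_power_d=cohort["iol_power_d"].to_numpy(float),
        acd_mm=cohort["acd_mm"].to_numpy(float),
        ad_mm=cohort["ad_mm"].to_numpy(float) if "ad_mm" in cohort else None,
        params=params)
    return predicted - cohort["postop_se_d"].to_numpy(float)


def exclude_outliers(cohort: pd.DataFrame, spe: np.ndarray,
                     z_threshold: float = 1.96) -> tuple:
    """Single-pass removal of eyes whose SPE is > z sample SDs from the mean.

    A zero-variance SPE vector yields no outliers. Returns
    ``(filtered frame, n_removed)``; aborts if nothing would survive.
    """
    spe = np.asarray(spe, dtype=float)
    if len(cohort) < 3:
        raise InvalidInputError("outlier exclusion needs >= 3 records")
    if len(spe) != len(cohort):
        raise InvalidInputError("spe vector does not match the cohort")
    sd = float(np.std(spe, ddof=1))
    if sd == 0.0:
        return cohort.reset_index(drop=True), 0
    z = np.abs(spe - spe.mean()) / sd
    keep = z <= z_threshold
    if not keep.any():
        raise PipelineAbortError(
            f"outlier screen at z = {z_threshold} removed all "
            f"{len(cohort)} records (mean SPE {spe.mean():.3f}, SD {sd:.3f})")
    n_removed = int((~keep).sum())
    logger.info("exclude_outliers: removed %d of %d eyes at z > %.2f",
                n_removed, len(cohort), z_threshold)
    return cohort[keep].reset_index(drop=True), n_removed


def split_train_test(cohort: pd.DataFrame, seed: int) -> SplitAssignment:
    """Patient-level Bernoulli(1/2) train/test split, reproducible by seed.

    Both eyes of a patient land on the same side; each test patient gets
    exactly one (uniformly chosen) test eye.
    """
    patients = np.sort(cohort["patient_id"].unique())
    if patients.size < 2:
        raise InvalidInputError("split needs at least two patients")
    rng = np.random.default_rng(seed)
    to_train = rng.random(patients.size) < 0.5
    side = {p: ("train" if t else "test")
            for p, t in zip(patients, to_train)}
    eyes_by_patient = cohort.groupby("patient_id")["eye"].apply(
        lambda s: sorted(s.unique()))
    test_eye = {}
    for p in patients[~to_train]:
        eyes = eyes_by_patient[p]
        test_eye[p] = eyes[int(rng.integers(len(eyes)))]
    return SplitAssignment(side=side, test_eye=test_eye, seed=seed)


def one_eye_per_patient(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Uniformly keep one eye per patient (for patient-weighted statistics)."""
    rng = np.random.default_rng(seed)
    keep_rows = []
    for _, group in cohort.groupby("patient_id", sort=True):
        idx = group.index.to_numpy()
        keep_rows.append(idx[int(rng.integers(idx.size))])
    return cohort.loc[sorted(keep_rows)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_formulas(test: pd.DataFrame, constants_map: dict,
                      mode: str = "pooled",
                      params: OpticalModelParams = DEFAULT_PARAMS,
                      formulas: tuple = FORMULAS) -> tuple:
    """Per-eye predictions and gender-stratified summaries on the test set.

    ``constants_map`` is ``{formula_id: {stratum: LensConstants}}`` with
    stratum keys ``"all"`` (pooled mode) and/or ``"female"``/``"male"``
    (by-gender mode). Returns ``(predictions, summary)`` where predictions
    is a long frame (one row per eye x formula) and summary holds mean/SD of
    SPE and APE per gender plus the overall MAE per formula.
    """
    if mode not in ("pooled", "by_gender"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    pred_frames = []
    for fid in formulas:
        strata = constants_map.get(fid)
        if strata is None:
            raise InvalidInputError(f"no constants for formula {fid!r}")
        spe = np.empty(len(test))
        if mode == "pooled":
            if "all" not in strata:
                raise InvalidInputError(f"missing pooled constant for {fid!r}")
            spe[:] = cohort_spe(test, fid, strata["all"], params)
        else:
            for gender in GENDERS:
                if gender not in strata:
                    raise InvalidInputError(
                        f"missing {gender} constant for {fid!r}")
                mask = (test["gender"] == gender).to_numpy()
                if mask.any():
                    spe[mask] = cohort_spe(test[mask], fid, strata[gender],
                                           params)
        frame = test[["patient_id", "eye", "gender"]].copy()
        frame["formula_id"] = fid
        frame["predicted_se_d"] = spe + test["postop_se_d"].to_numpy(float)
        frame["spe_d"] = spe
        frame["ape_d"] = np.abs(spe)
        pred_frames.append(frame)
    predictions = pd.concat(pred_frames, ignore_index=True)

    rows = []
    for fid in formulas:
        sub = predictions[predictions["formula_id"] == fid]
        for group, gsub in (("overall", sub),
                            ("female", sub[sub["gender"] == "female"]),
                            ("male", sub[sub["gender"] == "male"])):
            rows.append({
                "formula_id": fid, "group": group, "n": int(len(gsub)),
                "mean_spe_d": float(gsub["spe_d"].mean()) if len(gsub) else np.nan,
                "sd_spe_d": float(gsub["spe_d"].std(ddof=1)) if len(gsub) > 1 else np.nan,
                "mean_ape_d": float(gsub["ape_d"].mean()) if len(gsub) else np.nan,
                "sd_ape_d": float(gsub["ape_d"].std(ddof=1)) if len(gsub) > 1 else np.nan,
            })
    summary = pd.DataFrame(rows)
    return predictions, summary


# ---------------------------------------------------------------------------
# statistical tests


def _check_sample(x, name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size < min_n or np.any(~np.isfinite(arr)):
        raise InvalidInputError(
            f"sample {name!r} needs >= {min_n} finite values")
    return arr


def wilcoxon_rank_sum(x, y) -> StatTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the smaller sample has <= 25 observations
    and there are no ties; normal approximation with continuity and tie
    correction otherwise.
    """
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (min(x.size, y.size) <= 25) and not has_ties
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic")
    return StatTestResult(
        name="wilcoxon_rank_sum", statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)), n=(int(x.size), int(y.size)),
        group_stats={"mean_x": float(x.mean()), "mean_y": float(y.mean()),
                     "exact": exact})


def welch_t(x, y) -> StatTestResult:
    """Two-sided unequal-variance t-test with Welch-Satterthwaite df."""
    x = _check_sample(x, "x", min_n=2)
    y = _check_sample(y, "y", min_n=2)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise InvalidInputError("both samples have zero variance")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return StatTestResult(
        name="welch_t", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(int(x.size), int(y.size)),
        group_stats={"mean_x": float(x.mean()), "sd_x": float(np.std(x, ddof=1)),
                     "mean_y": float(y.mean()), "sd_y": float(np.std(y, ddof=1)),
                     "df": float(res.df)})


def wilcoxon_signed_rank(d) -> StatTestResult:
    """Two-sided paired Wilcoxon signed-rank test on differences ``d``.

    Zero differences are dropped; exact distribution for <= 25 nonzero
    untied pairs, normal approximation otherwise. An all-zero vector yields
    p = 1 with a warning (no evidence of any difference).
    """
    d = _check_sample(d, "d")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        logger.warning("wilcoxon_signed_rank: all differences are zero")
        return StatTestResult(name="wilcoxon_signed_rank", statistic=0.0,
                              p_value=1.0, n=(int(d.size),),
                              group_stats={"n_nonzero": 0})
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    exact = nonzero.size <= 25 and not has_ties
    res = scipy.stats.wilcoxon(nonzero,
                               method="exact" if exact else "approx",
                               correction=not exact)
    return StatTestResult(
        name="wilcoxon_signed_rank", statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)), n=(int(d.size),),
        group_stats={"n_nonzero": int(nonzero.size), "exact": exact,
                     "mean_d": float(d.mean())})


# ---------------------------------------------------------------------------
# regression


REGRESSION_COVARIATES = ("al_mm", "cct_um", "acd_mm", "lt_mm", "km_d",
                         "ast_d", "wtw_mm", "age_years")


def pe_regression(test: pd.DataFrame, predictions: pd.DataFrame,
                  acd_source: str = "acd",
                  formulas: tuple = FORMULAS) -> tuple:
    """OLS of signed prediction error on biometry, age and gender.

    For each formula, regresses per-eye SPE on AL, CCT, ACD (or AD), LT, Km,
    AST, WTW, age and a male indicator (male = 1, female = 0), and tests the
    gender term with a likelihood-ratio test against the nested model
    without it. Returns ``(coefficient table, gender tests)``.
    """
    if len(test) < 50:
        raise InvalidInputError("regression needs >= 50 test records")
    covars = list(REGRESSION_COVARIATES)
    if acd_source == "ad":
        covars[covars.index("acd_mm")] = "ad_mm"
    elif acd_source != "acd":
        raise InvalidInputError("acd_source must be 'acd' or 'ad'")

    coef_rows = []
    gender_tests = {}
    base = test.reset_index(drop=True)
    male = (base["gender"] == "male").astype(float).rename("male")
    for fid in formulas:
        sub = predictions[predictions["formula_id"] == fid]
        merged = base.merge(sub[["patient_id", "eye", "spe_d"]],
                            on=["patient_id", "eye"], how="inner")
        if len(merged) != len(base):
            raise InvalidInputError(
                f"predictions for {fid!r} do not cover the test set")
        X = pd.concat([merged[covars], male], axis=1).astype(float)
        Xc = sm.add_constant(X)
        rank = np.linalg.matrix_rank(Xc.to_numpy())
        if rank < Xc.shape[1]:
            collinear = [c for c in X.columns
                         if np.linalg.matrix_rank(
                             Xc.drop(columns=[c]).to_numpy()) == rank]
            raise InvalidInputError(
                f"rank-deficient design for {fid!r}; collinear columns: "
                f"{collinear}")
        y = merged["spe_d"].astype(float)
        full = sm.OLS(y, Xc).fit()
        restricted = sm.OLS(y, Xc.drop(columns=["male"])).fit()
        lr_stat = 2.0 * (full.llf - restricted.llf)
        lr_p = float(scipy.stats.chi2.sf(lr_stat, df=1))
        gender_tests[fid] = {"lr_stat": float(lr_stat), "p_value": lr_p}
        for term in Xc.columns:
            coef_rows.append({"formula_id": fid, "term": term,
                              "coef": float(full.params[term]),
                              "se": float(full.bse[term]),
                              "p_value": float(full.pvalues[term])})
    return pd.DataFrame(coef_rows), gender_tests


# ---------------------------------------------------------------------------
# full study and report tables


@dataclass
class StudyResult:
    """Everything a study run produces, ready for reporting/serialization."""

    validation_report: dict
    n_outliers_removed: int
    split: SplitAssignment
    constants: dict                      # {formula: {stratum: OptimizationResult}}
    predictions_pooled: pd.DataFrame
    predictions_gender: pd.DataFrame
    summary_pooled: pd.DataFrame
    summary_gender: pd.DataFrame
    regression_coefficients: pd.DataFrame
    gender_lr_tests: dict
    tables: dict                         # name -> DataFrame

    def constants_jsonable(self) -> dict:
        out = {}
        for fid, strata in self.constants.items():
            out[fid] = {s: {"constant_value": r.constant_value,
                            "mean_spe_at_optimum": r.mean_spe_at_optimum,
                            "n_train": r.n_train, "converged": r.converged}
                        for s, r in strata.items()}
        return out


def _summary_block(values: np.ndarray) -> dict:
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else np.nan
    half = 1.96 * sd / np.sqrt(n) if n > 1 else np.nan
    return {"mean": mean, "sd": sd, "median": float(np.median(values)),
            "ci_lo": mean - half, "ci_hi": mean + half, "n": int(n)}


_TABLE1_ROWS = (
    ("Age at surgery (years)", "age_years"),
    ("AL (mm)", "al_mm"), ("CCT (um)", "cct_um"), ("AD (mm)", "ad_mm"),
    ("ACD (mm)", "acd_mm"), ("LT (mm)", "lt_mm"), ("Km (D)", "km_d"),
    ("AST (D)", "ast_d"), ("WTW (mm)", "wtw_mm"),
    ("Postop sphere (D)", "postop_sphere_d"),
    ("Postop cylinder (D)", "postop_cyl_d"),
    ("Postop refraction SE (D)", "postop_se_d"),
)


def biometry_summary_table(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Per-gender demographics/biometry summary with rank-sum p-values.

    Means, SDs, medians and normal-approximation 95% CIs are computed on all
    eyes; the gender contrast p-value uses one randomly chosen eye per
    patient so each patient carries equal weight.
    """
    for gender in GENDERS:
        if not (cohort["gender"] == gender).any():
            raise StratumEmptyError(f"no {gender} records in the cohort")
    single = one_eye_per_patient(cohort, seed)
    rows = []
    for label, col in _TABLE1_ROWS:
        row = {"variable": label}
        for group, sub in (("overall", cohort),
                           ("female", cohort[cohort["gender"] == "female"]),
                           ("male", cohort[cohort["gender"] == "male"])):
            stats = _summary_block(sub[col].to_numpy(float))
            for k, v in stats.items():
                row[f"{group}_{k}"] = v
        test = wilcoxon_rank_sum(
            single.loc[single["gender"] == "female", col].to_numpy(float),
            single.loc[single["gender"] == "male", col].to_numpy(float))
        row["p_value"] = test.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def prediction_error_table(predictions: pd.DataFrame,
                           formulas: tuple = FORMULAS) -> pd.DataFrame:
    """Gender contrast of SPE and APE per formula (Welch t per contrast)."""
    rows = []
    for metric in ("spe_d", "ape_d"):
        for fid in formulas:
            sub = predictions[predictions["formula_id"] == fid]
            f = sub.loc[sub["gender"] == "female", metric].to_numpy(float)
            m = sub.loc[sub["gender"] == "male", metric].to_numpy(float)
            if f.size < 2 or m.size < 2:
                raise StratumEmptyError(
                    f"gender stratum too small for {fid!r}")
            test = welch_t(f, m)
            rows.append({
                "metric": "SPE" if metric == "spe_d" else "APE",
                "formula_id": fid,
                "overall_mean": float(sub[metric].mean()),
                "overall_sd": float(sub[metric].std(ddof=1)),
                "female_mean": float(f.mean()), "female_sd": float(f.std(ddof=1)),
                "male_mean": float(m.mean()), "male_sd": float(m.std(ddof=1)),
                "p_value": test.p_value})
    return pd.DataFrame(rows)


def constants_table(constants: dict) -> pd.DataFrame:
    rows = []
    for fid, strata in constants.items():
        rows.append({"formula_id": fid,
                     "standard": strata["all"].constant_value,
                     "male": strata["male"].constant_value,
                     "female": strata["female"].constant_value})
    return pd.DataFrame(rows)


def mae_comparison_table(pred_pooled: pd.DataFrame,
                         pred_gender: pd.DataFrame,
                         formulas: tuple = FORMULAS) -> pd.DataFrame:
    """MAE under pooled vs gender-stratified constants on the same eyes.

    The significance of the improvement is a paired Wilcoxon signed-rank
    test on per-eye APE differences (pooled minus stratified).
    """
    rows = []
    for fid in formulas:
        pooled = pred_pooled[pred_pooled["formula_id"] == fid]
        strat = pred_gender[pred_gender["formula_id"] == fid]
        merged = pooled.merge(strat, on=["patient_id", "eye", "formula_id"],
                              suffixes=("_pooled", "_gender"))
        if len(merged) != len(pooled):
            raise InvalidInputError(
                f"prediction tables for {fid!r} do not align")
        diff = (merged["ape_d_pooled"] - merged["ape_d_gender"]).to_numpy()
        mae_pooled = float(merged["ape_d_pooled"].mean())
        mae_gender = float(merged["ape_d_gender"].mean())
        test = wilcoxon_signed_rank(diff)
        rows.append({
            "formula_id": fid, "mae_standard": mae_pooled,
            "mae_by_gender": mae_gender,
            "pct_reduction": 100.0 * (mae_pooled - mae_gender) / mae_pooled
            if mae_pooled > 0 else 0.0,
            "p_value": test.p_value})
    return pd.DataFrame(rows)


def run_study(raw: pd.DataFrame, seed: int,
              params: OpticalModelParams = DEFAULT_PARAMS,
              start_constants: Optional[dict] = None,
              tol: float = DEFAULT_TOL_D,
              outlier_z: float = 1.96,
              reference_formula: str = "srkt",
              formulas: tuple = FORMULAS) -> StudyResult:
    """Run the whole pipeline on a raw cohort table.

    validation -> outlier screen (reference formula at its starting
    constant) -> patient-level split -> pooled and by-gender constant
    optimization on the training eyes -> evaluation on one eye per test
    patient -> summary tables (biometry, SPE/APE gender contrasts,
    regression, constants, MAE comparison).
    """
    starts = dict(DEFAULT_START_CONSTANTS)
    if start_constants:
        starts.update(start_constants)

    cohort, report = validate_cohort(raw)
    ref_const = LensConstants.for_formula(reference_formula,
                                          starts[reference_formula])
    spe_ref = cohort_spe(cohort, reference_formula, ref_const, params)
    cohort, n_removed = exclude_outliers(cohort, spe_ref, outlier_z)

    split = split_train_test(cohort, seed)
    train = split.training_frame(cohort)
    test = split.testing_frame(cohort)

    constants = {}
    for fid in formulas:
        constants[fid] = optimize_by_gender(train, fid,
                                            start_constant=starts[fid],
                                            tol=tol, params=params)

    pooled_map = {fid: {"all": LensConstants.for_formula(
        fid, res["all"].constant_value)} for fid, res in constants.items()}
    gender_map = {fid: {g: LensConstants.for_formula(
        fid, res[g].constant_value) for g in GENDERS}
        for fid, res in constants.items()}

    pred_pooled, summary_pooled = evaluate_formulas(test, pooled_map,
                                                    "pooled", params, formulas)
    pred_gender, summary_gender = evaluate_formulas(test, gender_map,
                                                    "by_gender", params,
                                                    formulas)
    coef_table, gender_lr = pe_regression(test, pred_pooled,
                                          formulas=formulas)

    tables = {
        "table1_biometry": biometry_summary_table(cohort, seed),
        "table2_prediction_error": prediction_error_table(pred_pooled,
                                                          formulas),
        "table3_regression": coef_table,
        "table4_constants": constants_table(constants),
        "table5_mae": mae_comparison_table(pred_pooled, pred_gender,
                                           formulas),
    }
    return StudyResult(
        validation_report=report, n_outliers_removed=n_removed, split=split,
        constants=constants, predictions_pooled=pred_pooled,
        predictions_gender=pred_gender, summary_pooled=summary_pooled,
        summary_gender=summary_gender, regression_coefficients=coef_table,
        gender_lr_tests=gender_lr, tables=tables)


def make_report(result: StudyResult) -> dict:
    """The study's summary tables keyed by name (deterministic contents)."""
    return dict(result.tables)
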