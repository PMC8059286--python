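"""Synthetic cataract-surgery cohort generator with known ground truth.

The generator emulates the statistical structure of a large single-IOL
biometry cohort: gender-stratified Gaussian biometry marginals (axial
length, chamber depth, keratometry, lens thickness, corneal diameter,
corneal thickness, astigmatism, age), a configurable correlation structure
on the (AL, ACD, Km, LT, WTW) block, bilateral patients with highly
correlated fellow eyes, an IOL-power selection policy (emmetropia-targeted
power from a "world" formula with known true constants, rounded to the
half-diopter grid with a myopic tie bias), and a postoperative-refraction
model

    observed SE = world prediction - delta_gender + N(0, noise_sd)

so that the pipeline's signed prediction error at the true constant equals
+delta_gender in expectation. Every cohort carries a ground-truth sidecar
(true constants, per-eye offsets and noise draws) so each pipeline stage can
be tested against a known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .formulas import (DEFAULT_PARAMS, FORMULAS, IOL_POWER_RANGE,
                       LensConstants, OpticalModelParams, _power_for_target,
                       elp_arrays, predict_refraction_arrays)

#: The correlated biometry block; everything else is drawn independently.
CORR_VARS = ("al_mm", "acd_mm", "km_d", "lt_mm", "wtw_mm")


def _default_marginals() -> dict:
    # Per-gender (mean, SD) of the biometry marginals of a large cataract
    # cohort measured on an optical biometer.
    return {
        "female": {"al_mm": (23.90, 1.35), "acd_mm": (3.19, 0.40),
                   "km_d": (44.17, 1.58), "lt_mm": (4.53, 0.44),
                   "wtw_mm": (12.04, 0.50), "cct_um": (549.34, 36.29),
                   "ast_d": (0.91, 0.77), "age_years": (71.16, 9.38)},
        "male": {"al_mm": (24.49, 1.32), "acd_mm": (3.31, 0.42),
                 "km_d": (43.44, 1.63), "lt_mm": (4.55, 0.47),
                 "wtw_mm": (12.24, 0.54), "cct_um": (554.04, 36.53),
                 "ast_d": (0.97, 0.86), "age_years": (70.65, 10.15)},
    }


def _default_bounds() -> dict:
    # Truncation windows roughly +/- 4 SD around the means, kept inside the
    # biometry type invariants; AST is truncated at zero by construction.
    return {"al_mm": (19.0, 30.0), "acd_mm": (1.6, 5.0), "km_d": (38.5, 49.5),
            "lt_mm": (3.0, 6.5), "wtw_mm": (10.2, 14.2),
            "cct_um": (420.0, 700.0), "ast_d": (0.0, 6.0),
            "age_years": (40.0, 100.0)}


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic cohort; one seed drives everything."""

    n_patients: int = 5519
    prop_female: float = 0.569
    prob_bilateral: float = 0.53
    marginals: dict = field(default_factory=_default_marginals)
    correlations: tuple = (("al_mm", "acd_mm", 0.45),
                           ("al_mm", "km_d", -0.30),
                           ("al_mm", "wtw_mm", 0.25))
    bounds: dict = field(default_factory=_default_bounds)
    world_formula: str = "srkt"
    true_constants: dict = field(
        default_factory=lambda: {"female": 119.0, "male": 119.0})
    haigis_a1: float = 0.4
    haigis_a2: float = 0.1
    gender_offset_d: dict = field(
        default_factory=lambda: {"female": 0.0, "male": 0.0})
    noise_sd_d: float = 0.40
    target_refraction_d: float = 0.0
    iol_step_d: float = 0.5
    intra_patient_rho: float = 0.9
    cyl_factor: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 < self.prop_female < 1.0:
            raise ConfigError("prop_female must lie in (0, 1)")
        if not 0.0 <= self.prob_bilateral <= 1.0:
            raise ConfigError("prob_bilateral must lie in [0, 1]")
        if self.noise_sd_d < 0:
            raise ConfigError("noise_sd_d must be >= 0")
        if not 0.0 <= self.intra_patient_rho < 1.0:
            raise ConfigError("intra_patient_rho must lie in [0, 1)")
        if self.world_formula not in FORMULAS:
            raise ConfigError(f"unknown world formula {self.world_formula!r}")
        if self.iol_step_d < 0:
            raise ConfigError("iol_step_d must be >= 0")
        try:
            np.linalg.cholesky(self.correlation_matrix())
        except np.linalg.LinAlgError as exc:
            raise ConfigError("correlation matrix is not positive definite") from exc
        for gender in ("female", "male"):
            for var, (mean, sd) in self.marginals[gender].items():
                lo, hi = self.bounds[var]
                if not lo <= mean <= hi:
                    raise ConfigError(
                        f"bounds for {var} ({lo}, {hi}) exclude the {gender} "
                        f"mean {mean}")
                if sd < 0:
                    raise ConfigError(f"negative SD for {var}")

    def correlation_matrix(self) -> np.ndarray:
        c = np.eye(len(CORR_VARS))
        idx = {v: i for i, v in enumerate(CORR_VARS)}
        for v1, v2, rho in self.correlations:
            i, j = idx[v1], idx[v2]
            c[i, j] = c[j, i] = rho
        return c

    def world_constants(self, gender: str) -> LensConstants:
        value = self.true_constants[gender]
        if self.world_formula == "haigis":
            return LensConstants.haigis(value, self.haigis_a1, self.haigis_a2)
        return LensConstants.for_formula(self.world_formula, value)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["correlations"] = [list(t) for t in self.correlations]
        return d


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Seeded rejection sampling of N(mean, sd) restricted to [lo, hi]."""
    out = np.empty(n)
    need = np.arange(n)
    rounds = 0
    while need.size:
        draw = mean + sd * rng.standard_normal(need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
        rounds += 1
        if rounds > 10_000:
            raise ConfigError(
                f"truncation bounds ({lo}, {hi}) are inconsistent with the "
                f"moments ({mean}, {sd}); rejection did not terminate")
    return out


def _sample_corr_block(config: GeneratorConfig, gender: str, n: int,
                       rng: np.random.Generator,
                       paired: bool = False) -> tuple:
    """Draw the correlated (AL, ACD, Km, LT, WTW) block for n eyes.

    With ``paired=True`` a second, fellow-eye block is drawn whose latent
    normals correlate with the first at ``intra_patient_rho``. Rows with any
    out-of-bounds coordinate (in either eye of a pair) are rejected and
    redrawn jointly.
    """
    chol = np.linalg.cholesky(config.correlation_matrix())
    means = np.array([config.marginals[gender][v][0] for v in CORR_VARS])
    sds = np.array([config.marginals[gender][v][1] for v in CORR_VARS])
    los = np.array([config.bounds[v][0] for v in CORR_VARS])
    his = np.array([config.bounds[v][1] for v in CORR_VARS])
    rho = config.intra_patient_rho

    first = np.empty((n, len(CORR_VARS)))
    second = np.empty((n, len(CORR_VARS))) if paired else None
    need = np.arange(n)
    rounds = 0
    while need.size:
        z1 = rng.standard_normal((need.size, len(CORR_VARS))) @ chol.T
        x1 = means + sds * z1
        ok = np.all((x1 >= los) & (x1 <= his), axis=1)
        if paired:
            w = rng.standard_normal((need.size, len(CORR_VARS))) @ chol.T
            z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * w
            x2 = means + sds * z2
            ok &= np.all((x2 >= los) & (x2 <= his), axis=1)
            second[need[ok]] = x2[ok]
        first[need[ok]] = x1[ok]
        need = need[~ok]
        rounds += 1
        if rounds > 10_000:
            raise ConfigError("biometry truncation bounds are inconsistent "
                              "with the configured moments")
    return (first, second) if paired else (first, None)


def sample_biometry(config: GeneratorConfig, gender: str, n: int,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw ``n`` independent per-eye biometry records for one gender.

    Returns a DataFrame with columns al_mm, acd_mm, km_d, lt_mm, wtw_mm,
    cct_um, ast_d and the derived ad_mm = acd_mm - cct_um/1000.
    """
    if gender not in ("female", "male"):
        raise ConfigError(f"unknown gender {gender!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    block, _ = _sample_corr_block(config, gender, n, rng)
    df = pd.DataFrame(block, columns=list(CORR_VARS))
    for var in ("cct_um", "ast_d"):
        mean, sd = config.marginals[gender][var]
        lo, hi = config.bounds[var]
        df[var] = _truncated_normal(rng, mean, sd, lo, hi, n)
    df["ad_mm"] = df["acd_mm"] - df["cct_um"] / 1000.0
    return df


def assign_iol_power(config: GeneratorConfig, gender: str, *,
                     al_mm, acd_mm, km_d,
                     params: OpticalModelParams = DEFAULT_PARAMS) -> np.ndarray:
    """Select the implanted power the way a surgeon targeting ``target``
    would: the world formula's power for the target refraction, rounded to
    the configured step with exact ties broken toward the higher (more
    myopic) power, then clipped to the deliverable power range."""
    constants = config.world_constants(gender)
    elp, l_opt, dc = elp_arrays(config.world_formula, constants,
                                al_mm=al_mm, km_d=km_d, acd_mm=acd_mm,
                                params=params)
    exact = _power_for_target(config.target_refraction_d, elp, l_opt, dc, params)
    step = config.iol_step_d
    if step > 0:
        # floor(x/step + 0.5): the midpoint tie goes to the higher power
        power = step * np.floor(np.asarray(exact) / step + 0.5)
    else:
        power = np.asarray(exact, dtype=float)
    return np.clip(power, *IOL_POWER_RANGE)


def simulate_postop_refraction(config: GeneratorConfig, gender: str, *,
                               al_mm, acd_mm, km_d, ast_d, iol_power_d,
                               rng: np.random.Generator,
                               params: OpticalModelParams = DEFAULT_PARAMS
                               ) -> dict:
    """Simulate the observed month-one manifest refraction.

    observed SE = world prediction(true constant) - delta_gender + noise,
    decomposed into a consistent (sphere, plus-cylinder) pair with the
    cylinder proportional to the corneal astigmatism.
    """
    constants = config.world_constants(gender)
    predicted = predict_refraction_arrays(
        config.world_formula, constants, al_mm=al_mm, km_d=km_d,
        iol_power_d=iol_power_d, acd_mm=acd_mm, params=params)
    n = np.shape(predicted)[0] if np.ndim(predicted) else 1
    noise = config.noise_sd_d * rng.standard_normal(n)
    offset = config.gender_offset_d[gender]
    observed_se = np.asarray(predicted) - offset + noise
    cyl = config.cyl_factor * np.asarray(ast_d, dtype=float)
    sphere = observed_se - cyl / 2.0
    return {"postop_se_d": observed_se, "postop_sphere_d": sphere,
            "postop_cyl_d": cyl, "world_predicted_se_d": np.asarray(predicted),
            "noise_d": noise, "offset_d": np.full(n, offset)}


def generate_cohort(config: GeneratorConfig,
                    cohort_path: Optional[str] = None,
                    truth_path: Optional[str] = None,
                    params: OpticalModelParams = DEFAULT_PARAMS) -> tuple:
    """Generate a full synthetic cohort and its ground-truth sidecar.

    Patients carry one or two operated eyes (fellow-eye biometry redrawn
    with high intra-patient correlation on the correlated block); each eye
    row follows the documented cohort CSV schema. Returns ``(cohort_df,
    truth_dict)`` and optionally writes them to ``cohort_path`` (CSV) and
    ``truth_path`` (JSON).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    is_female = rng.random(n) < config.prop_female
    is_bilateral = rng.random(n) < config.prob_bilateral
    first_eye_od = rng.random(n) < 0.5

    frames = []
    for gender, mask in (("female", is_female), ("male", ~is_female)):
        pidx = np.flatnonzero(mask)
        if pidx.size == 0:
            continue
        n_g = pidx.size
        mean, sd = config.marginals[gender]["age_years"]
        lo, hi = config.bounds["age_years"]
        ages = _truncated_normal(rng, mean, sd, lo, hi, n_g)

        bilat = is_bilateral[pidx]
        first, second = _sample_corr_block(config, gender, n_g, rng, paired=True)

        def eye_frame(block: np.ndarray, rows: np.ndarray) -> pd.DataFrame:
            df = pd.DataFrame(block[rows], columns=list(CORR_VARS))
            for var in ("cct_um", "ast_d"):
                m, s = config.marginals[gender][var]
                l, h = config.bounds[var]
                df[var] = _truncated_normal(rng, m, s, l, h, rows.size)
            df["ad_mm"] = df["acd_mm"] - df["cct_um"] / 1000.0
            df["patient_idx"] = pidx[rows]
            df["age_years"] = ages[rows]
            df["gender"] = gender
            return df

        all_rows = np.arange(n_g)
        df1 = eye_frame(first, all_rows)
        df1["is_second_eye"] = False
        frames.append(df1)
        if np.any(bilat):
            df2 = eye_frame(second, np.flatnonzero(bilat))
            df2["is_second_eye"] = True
            frames.append(df2)

        for df in frames[-2 if np.any(bilat) else -1:]:
            power = assign_iol_power(config, gender,
                                     al_mm=df["al_mm"].to_numpy(),
                                     acd_mm=df["acd_mm"].to_numpy(),
                                     km_d=df["km_d"].to_numpy(), params=params)
            df["iol_power_d"] = power
            post = simulate_postop_refraction(
                config, gender, al_mm=df["al_mm"].to_numpy(),
                acd_mm=df["acd_mm"].to_numpy(), km_d=df["km_d"].to_numpy(),
                ast_d=df["ast_d"].to_numpy(),
                iol_power_d=power, rng=rng, params=params)
            for key, arr in post.items():
                df[key] = arr
            df["true_constant"] = config.true_constants[gender]

    eyes = pd.concat(frames, ignore_index=True)
    eyes["patient_id"] = eyes["patient_idx"].map(lambda i: f"P{i + 1:06d}")
    od_first = first_eye_od[eyes["patient_idx"].to_numpy()]
    eyes["eye"] = np.where(eyes["is_second_eye"].to_numpy() ^ od_first,
                           "OD", "OS")
    eyes = eyes.sort_values(["patient_idx", "eye"], kind="mergesort",
                            ignore_index=True)

    columns = ["patient_id", "eye", "gender", "age_years", "al_mm", "cct_um",
               "ad_mm", "acd_mm", "lt_mm", "km_d", "ast_d", "wtw_mm",
               "iol_power_d", "postop_sphere_d", "postop_cyl_d", "postop_se_d"]
    cohort = eyes[columns].copy()

    truth = {
        "config": config.to_jsonable(),
        "world_formula": config.world_formula,
        "eyes": [
            {"patient_id": row.patient_id, "eye": row.eye,
             "gender": row.gender,
             "true_constant": float(row.true_constant),
             "offset_d": float(row.offset_d),
             "noise_d": float(row.noise_d),
             "world_predicted_se_d": float(row.world_predicted_se_d)}
            for row in eyes.itertuples()
        ],
    }
    if cohort_path is not None:
        cohort.to_csv(cohort_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
    return cohort, truth
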