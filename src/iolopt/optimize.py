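"""Lens-constant optimization ("zeroization").

A personalized lens constant is the one that removes the systematic
component of the refraction prediction error on a reference (training)
cohort: the constant at which the mean signed prediction error (SPE,
predicted minus observed postoperative spherical equivalent) is zero. Since
a larger constant places the assumed lens plane more posteriorly and makes
every prediction more hyperopic, the map constant -> mean SPE is strictly
increasing, and minimizing |mean SPE| is equivalent to root-finding on it.
Optimization can be run on the pooled training set or separately per gender
stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .errors import InvalidInputError, StratumEmptyError
from .formulas import (DEFAULT_PARAMS, FORMULAS, LensConstants,
                       OpticalModelParams, predict_refraction_arrays)

logger = logging.getLogger(__name__)

#: Optimizer starting constants: nominal values for a one-piece acrylic
#: monofocal IOL of A-constant 119 and their published conversions to the
#: other formulas' constants (Haigis a0 via a0 = 0.62467*A - 72.434, the
#: classical conversion valid for the standard a1 = 0.4, a2 = 0.1).
DEFAULT_START_CONSTANTS = {
    "srkt": 119.0,
    "holladay1": 1.84,
    "hofferq": 5.64,
    "haigis": 1.90,
}

#: Default search half-widths around the starting constant, generous versus
#: plausible inter-stratum differences (< 0.3 units).
DEFAULT_HALF_WIDTH = {
    "srkt": 2.0,
    "holladay1": 1.0,
    "hofferq": 1.5,
    "haigis": 1.0,
}

DEFAULT_TOL_D = 1e-3


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of a single constant search on one training stratum."""

    formula_id: str
    stratum: str                 # "all", "female" or "male"
    constant_value: float
    mean_spe_at_optimum: float   # on the same training records, diopters
    search_bounds: tuple
    tolerance: float
    n_train: int
    converged: bool
    message: str = ""


def _predicted_se(records: pd.DataFrame, formula_id: str,
                  constants: LensConstants,
                  params: OpticalModelParams) -> np.ndarray:
    return predict_refraction_arrays(
        formula_id, constants,
        al_mm=records["al_mm"].to_numpy(float),
        km_d=records["km_d"].to_numpy(float),
        iol_power_d=records["iol_power_d"].to_numpy(float),
        acd_mm=records["acd_mm"].to_numpy(float),
        ad_mm=records["ad_mm"].to_numpy(float) if "ad_mm" in records else None,
        params=params)


def mean_signed_pe(records: pd.DataFrame, formula_id: str,
                   constants: LensConstants,
                   params: OpticalModelParams = DEFAULT_PARAMS) -> float:
    """Mean signed prediction error (predicted - observed SE) in diopters."""
    if len(records) == 0:
        raise InvalidInputError("mean_signed_pe requires at least one record")
    observed = records["postop_se_d"].to_numpy(float)
    if np.any(~np.isfinite(observed)):
        raise InvalidInputError("postop_se_d contains non-finite values")
    predicted = _predicted_se(records, formula_id, constants, params)
    return float(np.mean(predicted - observed))


def optimize_constant(train: pd.DataFrame, formula_id: str,
                      start_constant: Optional[float] = None,
                      bounds: Optional[tuple] = None,
                      tol: float = DEFAULT_TOL_D,
                      params: OpticalModelParams = DEFAULT_PARAMS,
                      stratum: str = "all",
                      base_constants: Optional[LensConstants] = None,
                      ) -> OptimizationResult:
    """Find the constant whose training-set mean SPE is (closest to) zero.

    Root-finds the strictly increasing map constant -> mean SPE inside
    ``bounds``; when the bounds do not bracket a sign change, falls back to
    bounded golden-section minimization of |mean SPE| and flags
    non-convergence if the residual still exceeds ``tol``.
    """
    if formula_id not in FORMULAS:
        raise InvalidInputError(f"unknown formula {formula_id!r}")
    if tol <= 0:
        raise InvalidInputError("tol must be positive")
    if len(train) == 0:
        raise StratumEmptyError(f"training stratum {stratum!r} is empty")
    if start_constant is None:
        start_constant = DEFAULT_START_CONSTANTS[formula_id]
    if bounds is None:
        hw = DEFAULT_HALF_WIDTH[formula_id]
        bounds = (start_constant - hw, start_constant + hw)
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise InvalidInputError(f"invalid bounds {bounds}")
    base = (base_constants if base_constants is not None
            else LensConstants.for_formula(formula_id, start_constant))

    def f(c: float) -> float:
        return mean_signed_pe(train, formula_id, base.with_value(c), params)

    f_lo, f_hi = f(lo), f(hi)
    message = ""
    if f_lo == 0.0:
        c_opt = lo
    elif f_hi == 0.0:
        c_opt = hi
    elif f_lo * f_hi < 0:
        c_opt = float(brentq(f, lo, hi, xtol=1e-10))
    else:
        res = minimize_scalar(lambda c: abs(f(c)), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-9})
        c_opt = float(res.x)
        message = ("no sign change of mean SPE inside bounds; "
                   "golden-section fallback used")
    residual = f(c_opt)
    converged = abs(residual) <= tol
    if not converged:
        message = (message + "; " if message else "") + (
            f"|mean SPE| = {abs(residual):.4g} D > tol = {tol:g} D at the "
            f"best constant in [{lo}, {hi}]")
        logger.warning("optimize_constant(%s, stratum=%s) did not converge: %s",
                       formula_id, stratum, message)
    return OptimizationResult(
        formula_id=formula_id, stratum=stratum, constant_value=c_opt,
        mean_spe_at_optimum=float(residual), search_bounds=(lo, hi),
        tolerance=tol, n_train=int(len(train)), converged=converged,
        message=message)


def optimize_by_gender(train: pd.DataFrame, formula_id: str,
                       start_constant: Optional[float] = None,
                       bounds: Optional[tuple] = None,
                       tol: float = DEFAULT_TOL_D,
                       params: OpticalModelParams = DEFAULT_PARAMS,
                       base_constants: Optional[LensConstants] = None,
                       ) -> dict:
    """Optimize the constant pooled and separately for each gender stratum.

    Returns ``{"all": ..., "female": ..., "male": ...}`` of
    :class:`OptimizationResult`; raises :class:`StratumEmptyError` when a
    gender stratum has no training records.
    """
    results = {"all": optimize_constant(train, formula_id, start_constant,
                                        bounds, tol, params, "all",
                                        base_constants)}
    for gender in ("female", "male"):
        stratum = train[train["gender"] == gender]
        if len(stratum) == 0:
            raise StratumEmptyError(
                f"no {gender} records in the training set for {formula_id}")
        results[gender] = optimize_constant(stratum, formula_id,
                                            start_constant, bounds, tol,
                                            params, gender, base_constants)
    return results
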