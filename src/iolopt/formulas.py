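"""Refraction prediction for four published theoretic IOL power formulas.

Each formula predicts the postoperative spherical-equivalent refraction of a
pseudophakic eye from its preoperative biometry, the implanted IOL power and
one personalization constant. All four share the same two-element vergence
skeleton — a thin corneal lens of power ``Dc`` and a thin IOL of power ``P``
separated by the effective lens position (ELP), immersed in aqueous/vitreous
of index 1.336 — and differ in

* how the ELP is estimated from biometry and the lens constant,
* which fictitious corneal index converts the keratometric radius to ``Dc``,
* what optical axial length ``L_opt`` (retinal-thickness corrected or not)
  enters the vergence chain.

The supported formulas and their constants:

========== ===========================  =====================================
formula id constant                     ELP model
========== ===========================  =====================================
srkt       A-constant (dimensionless)   corneal-height + A-derived offset
holladay1  Surgeon Factor (mm)          anatomic corneal height + SF
hofferq    personalized ACD (mm)        pACD + AL/K terms (published chain)
haigis     a0 (mm; a1, a2 fixed)        a0 + a1*ACD + a2*AL
========== ===========================  =====================================

All public functions are pure and accept either scalars or NumPy arrays for
the biometric arguments; lengths are millimetres and powers diopters at the
interface, converted to metres exactly once inside the vergence core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import DomainError, InvalidInputError, NonPhysicalEyeError

logger = logging.getLogger(__name__)

#: Formula identifiers, in the reporting order used throughout the package.
FORMULAS = ("srkt", "holladay1", "hofferq", "haigis")

_CONSTANT_FIELD = {
    "srkt": "a_const",
    "holladay1": "sf_mm",
    "hofferq": "pacd_mm",
    "haigis": "haigis_a0",
}

#: Human-readable name of each formula's lens constant.
CONSTANT_NAMES = {
    "srkt": "A constant",
    "holladay1": "Surgeon Factor",
    "hofferq": "pACD",
    "haigis": "a0",
}

IOL_POWER_RANGE = (-10.0, 40.0)


@dataclass(frozen=True)
class OpticalModelParams:
    """Optical constants of the prediction model.

    Every fixed constant of the formula dialects lives here rather than being
    inlined, so divergent dialects (different keratometer index, different
    fictitious corneal indices, different ACD semantics for Haigis) can be
    expressed and tested without touching formula code.

    Parameters
    ----------
    n_aqueous : refractive index of aqueous/vitreous used in the vergence
        chain (1.336 in all four publications).
    keratometer_index : index the biometer used to convert the anterior
        corneal radius to keratometric diopters; 1.3375 gives r = 337.5/K.
    vertex_mm : spectacle vertex distance for the reported refraction.
    nc_srkt, nc_holladay, nc_haigis : fictitious corneal indices of the
        respective formulas (1.333, 4/3, 1.3315). Hoffer Q uses the
        keratometric power directly.
    retinal_thickness_holladay_mm : additive retinal-thickness term of
        Holladay 1 (SRK/T uses its own AL-dependent term).
    hofferq_elp_offset_mm : the 0.05 mm augmentation Hoffer Q applies to its
        ACD estimate inside the vergence stage.
    haigis_acd_source : which measured chamber depth feeds the Haigis ELP:
        ``"acd"`` (epithelium-to-lens, the biometer's ACD column, default) or
        ``"ad"`` (aqueous depth, endothelium-referenced).
    """

    n_aqueous: float = 1.336
    keratometer_index: float = 1.3375
    vertex_mm: float = 12.0
    nc_srkt: float = 1.333
    nc_holladay: float = 4.0 / 3.0
    nc_haigis: float = 1.3315
    retinal_thickness_holladay_mm: float = 0.200
    hofferq_elp_offset_mm: float = 0.05
    haigis_acd_source: str = "acd"

    def __post_init__(self) -> None:
        for name in ("n_aqueous", "keratometer_index", "nc_srkt",
                     "nc_holladay", "nc_haigis"):
            if not getattr(self, name) > 1.0:
                raise InvalidInputError(f"refractive index {name!r} must exceed 1")
        if self.vertex_mm < 0:
            raise InvalidInputError("vertex_mm must be non-negative")
        if self.haigis_acd_source not in ("acd", "ad"):
            raise InvalidInputError("haigis_acd_source must be 'acd' or 'ad'")


DEFAULT_PARAMS = OpticalModelParams()


@dataclass(frozen=True)
class EyeBiometry:
    """Preoperative optical biometry of one eye.

    al_mm : axial length. acd_mm : anterior chamber depth measured from the
    corneal epithelium to the lens. ad_mm : aqueous depth (ACD minus corneal
    thickness). cct_um : central corneal thickness. lt_mm : lens thickness.
    km_d : mean keratometry. ast_d : corneal astigmatism magnitude.
    wtw_mm : white-to-white corneal diameter.
    """

    al_mm: float
    acd_mm: float
    km_d: float
    ad_mm: Optional[float] = None
    cct_um: Optional[float] = None
    lt_mm: Optional[float] = None
    ast_d: float = 0.0
    wtw_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("al_mm", "acd_mm", "km_d", "ast_d"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
        for name in ("ad_mm", "cct_um", "lt_mm", "wtw_mm"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
        if not 15.0 < self.al_mm < 40.0:
            raise InvalidInputError(f"al_mm out of (15, 40): {self.al_mm}")
        if not 30.0 < self.km_d < 60.0:
            raise InvalidInputError(f"km_d out of (30, 60): {self.km_d}")
        if not 1.5 < self.acd_mm < 6.0:
            raise InvalidInputError(f"acd_mm out of (1.5, 6): {self.acd_mm}")
        if self.ast_d < 0:
            raise InvalidInputError(f"ast_d must be >= 0: {self.ast_d}")


@dataclass(frozen=True)
class LensConstants:
    """Per-formula personalization constant(s).

    Exactly the field relevant to ``formula`` must be set (Haigis a1/a2 carry
    fixed defaults that are not optimized, matching common single-constant
    personalization practice, but can be overridden).
    """

    formula: str
    a_const: Optional[float] = None
    sf_mm: Optional[float] = None
    pacd_mm: Optional[float] = None
    haigis_a0: Optional[float] = None
    haigis_a1: float = 0.4
    haigis_a2: float = 0.1

    def __post_init__(self) -> None:
        if self.formula not in FORMULAS:
            raise InvalidInputError(f"unknown formula {self.formula!r}")
        field = _CONSTANT_FIELD[self.formula]
        if getattr(self, field) is None:
            raise InvalidInputError(
                f"formula {self.formula!r} requires {field!r} to be set")
        for other, f in _CONSTANT_FIELD.items():
            if other != self.formula and f != field and getattr(self, f) is not None:
                raise InvalidInputError(
                    f"constant {f!r} is irrelevant to formula {self.formula!r}")
        if self.a_const is not None and not 110.0 < self.a_const < 125.0:
            raise InvalidInputError(f"a_const out of (110, 125): {self.a_const}")
        if self.pacd_mm is not None and not 3.0 < self.pacd_mm < 8.0:
            raise InvalidInputError(f"pacd_mm out of (3, 8): {self.pacd_mm}")
        if self.sf_mm is not None and not 0.0 < self.sf_mm < 4.0:
            raise InvalidInputError(f"sf_mm out of (0, 4): {self.sf_mm}")

    @property
    def value(self) -> float:
        """The scalar constant being personalized for this formula."""
        return float(getattr(self, _CONSTANT_FIELD[self.formula]))

    def with_value(self, value: float) -> "LensConstants":
        """Return a copy with the personalized constant replaced."""
        return replace(self, **{_CONSTANT_FIELD[self.formula]: float(value)})

    @classmethod
    def for_formula(cls, formula: str, value: float, **kwargs) -> "LensConstants":
        if formula not in FORMULAS:
            raise InvalidInputError(f"unknown formula {formula!r}")
        return cls(formula=formula, **{_CONSTANT_FIELD[formula]: float(value)},
                   **kwargs)

    @classmethod
    def srkt(cls, a_const: float) -> "LensConstants":
        return cls(formula="srkt", a_const=a_const)

    @classmethod
    def holladay1(cls, sf_mm: float) -> "LensConstants":
        return cls(formula="holladay1", sf_mm=sf_mm)

    @classmethod
    def hofferq(cls, pacd_mm: float) -> "LensConstants":
        return cls(formula="hofferq", pacd_mm=pacd_mm)

    @classmethod
    def haigis(cls, a0: float, a1: float = 0.4, a2: float = 0.1) -> "LensConstants":
        return cls(formula="haigis", haigis_a0=a0, haigis_a1=a1, haigis_a2=a2)


@dataclass(frozen=True)
class ElpResult:
    """The three formula-specific quantities consumed by the vergence core."""

    elp_mm: float      # effective lens position from the corneal vertex
    l_opt_mm: float    # optical axial length used by the formula
    dc_d: float        # corneal power used by the formula

    def __post_init__(self) -> None:
        if not 0.0 < self.elp_mm < self.l_opt_mm:
            raise NonPhysicalEyeError(
                f"ELP {self.elp_mm:.4f} mm outside (0, L_opt={self.l_opt_mm:.4f})")
        if not 25.0 < self.dc_d < 60.0:
            raise InvalidInputError(f"corneal power out of (25, 60): {self.dc_d}")


# ---------------------------------------------------------------------------
# elementary optical conversions


def _is_scalar(x) -> bool:
    return np.ndim(x) == 0


def keratometry_to_radius(km_d, keratometer_index: float = 1.3375):
    """Convert keratometric power (D) to anterior corneal radius (mm).

    r = 1000 * (keratometer_index - 1) / K; the default index 1.3375 gives
    the familiar r = 337.5 / K.
    """
    km = np.asarray(km_d, dtype=float)
    if np.any(~np.isfinite(km)) or np.any(km <= 0):
        raise InvalidInputError("keratometry must be finite and positive")
    r = 1000.0 * (keratometer_index - 1.0) / km
    return float(r) if _is_scalar(km_d) else r


def corneal_to_spectacle(rc_d, vertex_mm: float = 12.0):
    """Transpose a refraction from the corneal plane to the spectacle plane."""
    rc = np.asarray(rc_d, dtype=float)
    denom = 1.0 + (vertex_mm / 1000.0) * rc
    if np.any(np.abs(denom) < 1e-9):
        raise DomainError("singular vertex transposition (1 + v*R = 0)")
    out = rc / denom
    return float(out) if _is_scalar(rc_d) else out


def spectacle_to_corneal(rs_d, vertex_mm: float = 12.0):
    """Inverse of :func:`corneal_to_spectacle`; round-trips to 1e-12."""
    rs = np.asarray(rs_d, dtype=float)
    denom = 1.0 - (vertex_mm / 1000.0) * rs
    if np.any(np.abs(denom) < 1e-9):
        raise DomainError("singular vertex transposition (1 - v*R = 0)")
    out = rs / denom
    return float(out) if _is_scalar(rs_d) else out


# ---------------------------------------------------------------------------
# vergence core (shared by all formulas)


def _vergence_refraction(power_d, elp_mm, l_opt_mm, dc_d, params: OpticalModelParams):
    """Array vergence chain: predicted spectacle refraction for IOL power P.

    With lengths in metres and n the aqueous index:
        Rc = n / (ELP + n / (n/(L_opt - ELP) - P)) - Dc
    transposed to the spectacle plane. Strictly decreasing in P.
    """
    p = np.asarray(power_d, dtype=float)
    elp = np.asarray(elp_mm, dtype=float) / 1000.0
    l_opt = np.asarray(l_opt_mm, dtype=float) / 1000.0
    dc = np.asarray(dc_d, dtype=float)

    if np.any(elp <= 0):
        raise NonPhysicalEyeError("effective lens position <= 0")
    gap = l_opt - elp
    if np.any(gap <= 0):
        raise NonPhysicalEyeError("optical axial length does not exceed ELP "
                                  "(term: L_opt - ELP)")
    n = params.n_aqueous
    v_post = n / gap - p
    if np.any(v_post <= 0):
        raise NonPhysicalEyeError("non-positive vergence behind the IOL "
                                  "(term: n/(L_opt - ELP) - P)")
    t = elp + n / v_post
    if np.any(t <= 0):
        raise NonPhysicalEyeError("non-positive corneal-plane distance "
                                  "(term: ELP + n/V)")
    rc = n / t - dc
    return corneal_to_spectacle(rc, params.vertex_mm)


def vergence_refraction(params: OpticalModelParams, elp: ElpResult,
                        iol_power_d: float) -> float:
    """Predicted spectacle-plane refraction for one eye and IOL power."""
    lo, hi = IOL_POWER_RANGE
    if not lo <= iol_power_d <= hi:
        raise InvalidInputError(f"iol_power_d out of [{lo}, {hi}]: {iol_power_d}")
    return float(_vergence_refraction(iol_power_d, elp.elp_mm, elp.l_opt_mm,
                                      elp.dc_d, params))


def _emmetropic_power(elp_mm, l_opt_mm, dc_d, params: OpticalModelParams):
    elp = np.asarray(elp_mm, dtype=float) / 1000.0
    l_opt = np.asarray(l_opt_mm, dtype=float) / 1000.0
    dc = np.asarray(dc_d, dtype=float)
    n = params.n_aqueous
    gap = l_opt - elp
    focal = n / dc - elp
    if np.any(gap <= 0) or np.any(focal <= 0):
        raise NonPhysicalEyeError("degenerate geometry in emmetropic power "
                                  "(L_opt - ELP or n/Dc - ELP <= 0)")
    return n / gap - n / focal


def emmetropic_power(params: OpticalModelParams, elp: ElpResult) -> float:
    """IOL power that makes the predicted refraction exactly zero."""
    return float(_emmetropic_power(elp.elp_mm, elp.l_opt_mm, elp.dc_d, params))


def _power_for_target(target_se_d, elp_mm, l_opt_mm, dc_d,
                      params: OpticalModelParams):
    """IOL power whose predicted spectacle refraction equals the target."""
    rc = spectacle_to_corneal(target_se_d, params.vertex_mm)
    elp = np.asarray(elp_mm, dtype=float) / 1000.0
    l_opt = np.asarray(l_opt_mm, dtype=float) / 1000.0
    dc = np.asarray(dc_d, dtype=float) + np.asarray(rc, dtype=float)
    n = params.n_aqueous
    gap = l_opt - elp
    focal = n / dc - elp
    if np.any(gap <= 0) or np.any(focal <= 0):
        raise NonPhysicalEyeError("degenerate geometry while solving for the "
                                  "target refraction")
    return n / gap - n / focal


# ---------------------------------------------------------------------------
# formula-specific ELP models (millimetre domain)


def _elp_srkt_arrays(a_const, al, km, params: OpticalModelParams):
    r = keratometry_to_radius(km, params.keratometer_index)
    al = np.asarray(al, dtype=float)
    # axial-length correction for long eyes
    lcor = np.where(al > 24.2, -3.446 + 1.716 * al - 0.0237 * al ** 2, al)
    cw = -5.41 + 0.58412 * lcor + 0.098 * np.asarray(km, dtype=float)
    arg = r ** 2 - (cw / 2.0) ** 2
    n_clamped = int(np.sum(arg < 0))
    if n_clamped:
        logger.warning("SRK/T corneal-height sqrt argument clamped to 0 for "
                       "%d eye(s)", n_clamped)
    h = r - np.sqrt(np.maximum(arg, 0.0))
    acd_const = 0.62467 * a_const - 68.747
    elp = h + (acd_const - 3.336)
    l_opt = al + (0.65696 - 0.02029 * al)   # retinal-thickness term
    dc = 1000.0 * (params.nc_srkt - 1.0) / r
    return elp, l_opt, dc


def _elp_holladay1_arrays(sf_mm, al, km, params: OpticalModelParams):
    r = keratometry_to_radius(km, params.keratometer_index)
    al = np.asarray(al, dtype=float)
    rag = np.maximum(r, 7.0)
    ag = np.minimum(12.5 * al / 23.45, 13.5)
    arg = rag ** 2 - (ag / 2.0) ** 2
    n_clamped = int(np.sum(arg < 0))
    if n_clamped:
        logger.warning("Holladay corneal-height sqrt argument clamped to 0 "
                       "for %d eye(s)", n_clamped)
    h = rag - np.sqrt(np.maximum(arg, 0.0))
    elp = h + sf_mm
    l_opt = al + params.retinal_thickness_holladay_mm
    dc = 1000.0 * (params.nc_holladay - 1.0) / r
    return elp, l_opt, dc


def _elp_hofferq_arrays(pacd_mm, al, km, params: OpticalModelParams):
    al = np.asarray(al, dtype=float)
    km = np.asarray(km, dtype=float)
    alc = np.clip(al, 18.5, 31.0)
    n_clamped = int(np.sum(alc != al))
    if n_clamped:
        logger.warning("Hoffer Q axial length clamped to [18.5, 31] for %d "
                       "eye(s)", n_clamped)
    m = np.where(alc <= 23.0, 1.0, -1.0)
    g = np.where(alc <= 23.0, 28.0, 23.5)
    tan_k = np.tan(np.radians(km))
    correction = 0.1 * m * (23.5 - alc) ** 2 * np.tan(np.radians(0.1 * (g - alc) ** 2))
    acd_est = pacd_mm + 0.3 * (alc - 23.5) + tan_k ** 2 + correction - 0.99166
    elp = acd_est + params.hofferq_elp_offset_mm
    l_opt = al
    dc = km
    return elp, l_opt, dc


def _elp_haigis_arrays(constants: LensConstants, al, acd_pre, km,
                       params: OpticalModelParams):
    al = np.asarray(al, dtype=float)
    acd_pre = np.asarray(acd_pre, dtype=float)
    elp = (constants.haigis_a0 + constants.haigis_a1 * acd_pre
           + constants.haigis_a2 * al)
    r = keratometry_to_radius(km, params.keratometer_index)
    dc = 1000.0 * (params.nc_haigis - 1.0) / r
    return elp, al, dc


def _haigis_chamber_depth(eye: EyeBiometry, params: OpticalModelParams) -> float:
    if params.haigis_acd_source == "acd":
        return eye.acd_mm
    if eye.ad_mm is None:
        raise InvalidInputError("haigis_acd_source='ad' but ad_mm is missing")
    return eye.ad_mm


def _make_elp_result(elp, l_opt, dc) -> ElpResult:
    return ElpResult(elp_mm=float(elp), l_opt_mm=float(l_opt), dc_d=float(dc))


def elp_srkt(constants: LensConstants, eye: EyeBiometry,
             params: OpticalModelParams = DEFAULT_PARAMS) -> ElpResult:
    """SRK/T effective lens position from corneal height and the A-constant."""
    if constants.formula != "srkt":
        raise InvalidInputError("constants are not for srkt")
    return _make_elp_result(*_elp_srkt_arrays(constants.a_const, eye.al_mm,
                                              eye.km_d, params))


def elp_holladay1(constants: LensConstants, eye: EyeBiometry,
                  params: OpticalModelParams = DEFAULT_PARAMS) -> ElpResult:
    """Holladay 1 ELP: anatomic corneal height plus the Surgeon Factor."""
    if constants.formula != "holladay1":
        raise InvalidInputError("constants are not for holladay1")
    return _make_elp_result(*_elp_holladay1_arrays(constants.sf_mm, eye.al_mm,
                                                   eye.km_d, params))


def elp_hofferq(constants: LensConstants, eye: EyeBiometry,
                params: OpticalModelParams = DEFAULT_PARAMS) -> ElpResult:
    """Hoffer Q ELP from the personalized ACD and the published AL/K chain."""
    if constants.formula != "hofferq":
        raise InvalidInputError("constants are not for hofferq")
    return _make_elp_result(*_elp_hofferq_arrays(constants.pacd_mm, eye.al_mm,
                                                 eye.km_d, params))


def elp_haigis(constants: LensConstants, eye: EyeBiometry,
               params: OpticalModelParams = DEFAULT_PARAMS) -> ElpResult:
    """Haigis ELP: the linear model a0 + a1*ACD + a2*AL."""
    if constants.formula != "haigis":
        raise InvalidInputError("constants are not for haigis")
    acd_pre = _haigis_chamber_depth(eye, params)
    return _make_elp_result(*_elp_haigis_arrays(constants, eye.al_mm, acd_pre,
                                                eye.km_d, params))


_ELP_DISPATCH = {
    "srkt": elp_srkt,
    "holladay1": elp_holladay1,
    "hofferq": elp_hofferq,
    "haigis": elp_haigis,
}


def compute_elp(formula_id: str, constants: LensConstants, eye: EyeBiometry,
                params: OpticalModelParams = DEFAULT_PARAMS) -> ElpResult:
    """Dispatch to the matching formula's ELP model."""
    if formula_id not in FORMULAS:
        raise InvalidInputError(f"unknown formula {formula_id!r}")
    return _ELP_DISPATCH[formula_id](constants, eye, params)


def predict_refraction(formula_id: str, constants: LensConstants,
                       eye: EyeBiometry, iol_power_d: float,
                       params: OpticalModelParams = DEFAULT_PARAMS,
                       label: str | None = None) -> float:
    """Predicted postoperative spherical-equivalent refraction for one eye.

    Pure and deterministic; errors from the ELP model or the vergence chain
    are re-raised annotated with the formula id (and ``label`` if given).
    """
    try:
        elp = compute_elp(formula_id, constants, eye, params)
        return vergence_refraction(params, elp, iol_power_d)
    except NonPhysicalEyeError as exc:
        where = f" eye={label}" if label else ""
        raise NonPhysicalEyeError(f"[{formula_id}{where}] {exc}") from exc


def predict_refraction_arrays(formula_id: str, constants: LensConstants,
                              *, al_mm, km_d, iol_power_d,
                              acd_mm=None, ad_mm=None,
                              params: OpticalModelParams = DEFAULT_PARAMS):
    """Vectorized :func:`predict_refraction` over parallel biometry arrays.

    ``acd_mm``/``ad_mm`` are consumed only by Haigis, according to
    ``params.haigis_acd_source``.
    """
    if formula_id == "srkt":
        elp, l_opt, dc = _elp_srkt_arrays(constants.a_const, al_mm, km_d, params)
    elif formula_id == "holladay1":
        elp, l_opt, dc = _elp_holladay1_arrays(constants.sf_mm, al_mm, km_d, params)
    elif formula_id == "hofferq":
        elp, l_opt, dc = _elp_hofferq_arrays(constants.pacd_mm, al_mm, km_d, params)
    elif formula_id == "haigis":
        acd_pre = acd_mm if params.haigis_acd_source == "acd" else ad_mm
        if acd_pre is None:
            raise InvalidInputError(
                f"haigis prediction needs {params.haigis_acd_source}_mm")
        elp, l_opt, dc = _elp_haigis_arrays(constants, al_mm, acd_pre, km_d, params)
    else:
        raise InvalidInputError(f"unknown formula {formula_id!r}")
    return _vergence_refraction(iol_power_d, elp, l_opt, dc, params)


def elp_arrays(formula_id: str, constants: LensConstants, *, al_mm, km_d,
               acd_mm=None, ad_mm=None,
               params: OpticalModelParams = DEFAULT_PARAMS):
    """Vectorized ELP components ``(elp_mm, l_opt_mm, dc_d)`` for a formula."""
    if formula_id == "srkt":
        return _elp_srkt_arrays(constants.a_const, al_mm, km_d, params)
    if formula_id == "holladay1":
        return _elp_holladay1_arrays(constants.sf_mm, al_mm, km_d, params)
    if formula_id == "hofferq":
        return _elp_hofferq_arrays(constants.pacd_mm, al_mm, km_d, params)
    if formula_id == "haigis":
        acd_pre = acd_mm if params.haigis_acd_source == "acd" else ad_mm
        if acd_pre is None:
            raise InvalidInputError(
                f"haigis ELP needs {params.haigis_acd_source}_mm")
        return _elp_haigis_arrays(constants, al_mm, acd_pre, km_d, params)
    raise InvalidInputError(f"unknown formula {formula_id!r}")
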