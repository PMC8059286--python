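"""Independent transcriptions of the four published formulas.

These are deliberately written as plain scalar, step-by-step scripts that
follow the algebraic layout of the original publications (single-fraction
refraction formulas for SRK/T and Holladay 1; inversion of the published
power formula, one vergence stage at a time, for Hoffer Q and Haigis).
They share no code with ``iolopt.formulas`` and serve as the second route
in the dual-route correctness checks.
"""

import math

VERTEX_MM = 12.0


def spectacle_from_corneal(rc, vertex_mm=VERTEX_MM):
    return rc / (1.0 + vertex_mm / 1000.0 * rc)


def srkt_refraction(a_const, al, km, power):
    """SRK/T predicted refraction via the published single-fraction formula
    (lengths in mm, keratometer index 1.3375, corneal index 1.333)."""
    na = 1.336
    ncm1 = 1.333 - 1.0
    v = VERTEX_MM
    r = 337.5 / km
    if al > 24.2:
        lcor = -3.446 + 1.716 * al - 0.0237 * al * al
    else:
        lcor = al
    cw = -5.41 + 0.58412 * lcor + 0.098 * km
    h_arg = r * r - cw * cw / 4.0
    if h_arg < 0.0:
        h_arg = 0.0
    h = r - math.sqrt(h_arg)
    acd_const = 0.62467 * a_const - 68.747
    offset = acd_const - 3.336
    acd_est = h + offset
    rethick = 0.65696 - 0.02029 * al
    lopt = al + rethick
    num = (1000.0 * na * (na * r - ncm1 * lopt)
           - power * (lopt - acd_est) * (na * r - ncm1 * acd_est))
    den = (na * (v * (na * r - ncm1 * lopt) + lopt * r)
           - 0.001 * power * (lopt - acd_est)
           * (v * (na * r - ncm1 * acd_est) + acd_est * r))
    return num / den


def holladay1_refraction(sf, al, km, power):
    """Holladay 1 predicted refraction via the published single-fraction
    formula (corneal index 4/3, 0.200 mm retinal thickness)."""
    na = 1.336
    ncm1 = 4.0 / 3.0 - 1.0
    v = VERTEX_MM
    r = 337.5 / km
    rag = r if r >= 7.0 else 7.0
    ag = 12.5 * al / 23.45
    if ag > 13.5:
        ag = 13.5
    h = rag - math.sqrt(rag * rag - ag * ag / 4.0)
    acd_est = h + sf
    alm = al + 0.2
    num = (1000.0 * na * (na * r - ncm1 * alm)
           - power * (alm - acd_est) * (na * r - ncm1 * acd_est))
    den = (na * (v * (na * r - ncm1 * alm) + alm * r)
           - 0.001 * power * (alm - acd_est)
           * (v * (na * r - ncm1 * acd_est) + acd_est * r))
    return num / den


def hofferq_elp(pacd, al, km):
    """Hoffer Q ACD estimate (published chain, tangents in degrees),
    including the 0.05 mm augmentation used by the vergence stage."""
    alc = al
    if alc < 18.5:
        alc = 18.5
    if alc > 31.0:
        alc = 31.0
    if alc <= 23.0:
        m, g = 1.0, 28.0
    else:
        m, g = -1.0, 23.5
    tan_k = math.tan(math.radians(km))
    acd = (pacd + 0.3 * (alc - 23.5) + tan_k * tan_k
           + 0.1 * m * (23.5 - alc) ** 2
           * math.tan(math.radians(0.1 * (g - alc) ** 2))
           - 0.99166)
    return acd + 0.05


def hofferq_refraction(pacd, al, km, power):
    """Hoffer Q predicted refraction: invert the published power formula
        P = 1336/(AL - ACD) - 1.336/(1.336/(K + Rc) - ACD/1000)
    for the corneal-plane refraction Rc, one stage at a time."""
    acd = hofferq_elp(pacd, al, km)
    front = 1336.0 / (al - acd)              # vergence of the axial gap
    stage = 1.336 / (front - power)          # 1.336/(K+Rc) - ACD/1000
    inv = stage + acd / 1000.0               # 1.336/(K + Rc)
    rc = 1.336 / inv - km
    return spectacle_from_corneal(rc)


def haigis_refraction(a0, a1, a2, al, acd_pre, km, power):
    """Haigis predicted refraction: ELP = a0 + a1*ACD + a2*AL, corneal power
    from the 1.3315 index, stepwise vergence inversion in metres."""
    r = 337.5 / km
    dc = 1000.0 * (1.3315 - 1.0) / r
    d = (a0 + a1 * acd_pre + a2 * al) / 1000.0
    l = al / 1000.0
    n = 1.336
    vergence_retina = n / (l - d)            # required vergence behind IOL
    vergence_front = vergence_retina - power  # vergence arriving at IOL
    z = n / vergence_front + d               # back to the corneal plane
    rc = n / z - dc
    return spectacle_from_corneal(rc)
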