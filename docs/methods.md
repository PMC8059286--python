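# Methods

## Optical model

All four formulas are implemented over one thin-lens vergence skeleton: a
corneal lens of power `Dc` and an IOL of power `P` separated by the
effective lens position (ELP), immersed in a medium of index
`n = 1.336`. With lengths in metres, the predicted corneal-plane refraction
is

```
Rc = n / (ELP + n / (n/(L_opt − ELP) − P)) − Dc
```

transposed to the spectacle plane by `R = Rc / (1 + v·Rc)` with
`v = 12 mm`. Lengths are converted from millimetres to metres exactly once,
at the vergence boundary; the ELP models operate in millimetres. The chain
is strictly decreasing in `P`, strictly increasing in ELP, and invertible
in closed form, which gives the emmetropic power
`P* = n/(L_opt − ELP) − n/(n/Dc − ELP)` and, more generally, the power for
any target refraction (used by the synthetic generator's surgeon policy).

The formula dialects differ only in their fixed constants and ELP models,
all held in `OpticalModelParams` rather than inlined, so that divergent
biometer dialects can be expressed and tested:

| formula   | corneal index | optical axial length | ELP model |
|-----------|---------------|----------------------|-----------|
| SRK/T     | 1.333         | AL + (0.65696 − 0.02029·AL) | corneal height from the corneal-width quadratic + A-constant offset (0.62467·A − 68.747 − 3.336), long-eye AL correction above 24.2 mm |
| Holladay 1| 4/3           | AL + 0.200 mm        | anatomic corneal height from Rag = max(r, 7) and AG = min(12.5·AL/23.45, 13.5) + Surgeon Factor |
| Hoffer Q  | Km used directly | AL                | pACD + 0.3·(ALc − 23.5) + tan²K + short/long-eye tangent term − 0.99166, ALc clamped to [18.5, 31], tangents in degrees, +0.05 mm in the vergence stage |
| Haigis    | 1.3315        | AL                   | a0 + a1·ACD + a2·AL |

The keratometer index is 1.3375 (`r = 337.5/Km`). Square-root arguments in
the corneal-height computations are clamped at zero with a warning rather
than an error, because real radius/width combinations can violate the
circular-segment geometry. Degenerate geometry anywhere in the vergence
chain (ELP ≤ 0, non-positive vergence behind the IOL, axial length not
exceeding the ELP) raises a `NonPhysicalEyeError` naming the offending
term.

**Haigis ACD semantics.** The Haigis ELP consumes the preoperative chamber
depth. Biometers report both an epithelium-referenced ACD and an aqueous
depth (AD = ACD − CCT); which one feeds the formula differs between
installations, so it is a configuration switch
(`OpticalModelParams.haigis_acd_source`), defaulting to the
epithelium-referenced ACD column.

**Haigis constants.** Only a0 is personalized; a1 = 0.4 and a2 = 0.1 are
the classical fixed defaults of single-constant Haigis use (they can be
overridden for triple-optimized constant sets). Consistently with that
dialect, the optimizer's default starting a0 uses the published A-constant
conversion a0 = 0.62467·A − 72.434 (≈ +1.90 for A = 119). Note that
triple-optimized constant files quote very different (a0, a1, a2) triples —
e.g. a0 near −0.7 with a1 ≈ 0.23, a2 ≈ 0.22 — which describe nearly the
same ELP at average biometry; a0 values are only comparable within one
(a1, a2) dialect.

## Constant optimization

The personalized constant is defined as the value minimizing the absolute
mean signed prediction error (SPE = predicted − observed postoperative
spherical equivalent) on the training records. Since mean SPE is strictly
increasing and nearly linear in the constant, this is implemented as
Brent root-finding on constant → mean SPE (equivalent at the optimum,
better conditioned), with a bounded golden-section minimization of
|mean SPE| as fallback when the search interval does not bracket a sign
change; a fallback that still leaves |mean SPE| above tolerance is flagged
`converged = False` with diagnostics, never silently. Defaults: tolerance
1e−3 D on the training mean SPE (two orders below the stratum differences
of interest); search half-widths ±2.0 (A-constant), ±1.0 mm (Surgeon
Factor), ±1.5 mm (pACD), ±1.0 mm (a0) around the configured starting
constants — generous relative to plausible inter-stratum differences
(< 0.3 units). Optimization uses all training eyes; the one-eye-per-patient
restriction applies to evaluation only.

## Cohort pipeline

* **Validation** rejects rows (never silently) for: prior refractive
  surgery flag, unknown gender or eye codes, incomplete or inconsistent
  refraction (SE must equal sphere + cyl/2 to 1e−9), missing or
  out-of-range biometry (AL ∈ (15, 40) mm, Km ∈ (30, 60) D, ACD ∈ (1.5, 6)
  mm, AST ≥ 0), IOL power off the half-diopter grid or outside [−10, 40] D,
  duplicate (patient, eye) keys. A row violating several rules is counted
  under each reason and rejected once.
* **Outlier screen**: a single pass removing eyes whose SPE lies more than
  1.96 sample SDs from the cohort mean, computed under one reference
  formula (configurable; SRK/T at its starting constant by default) before
  the split. A zero-variance SPE vector removes nothing.
* **Split**: patient-level Bernoulli(1/2) assignment from a seeded
  generator (both eyes of a patient on the same side), then one uniformly
  chosen eye per test patient so that each patient carries equal weight in
  all test-set statistics.
* **Statistics**: gender contrasts of biometry use the Wilcoxon rank-sum
  test on a one-eye-per-patient subsample (exact null distribution when the
  smaller sample has ≤ 25 untied observations, tie/continuity-corrected
  normal approximation otherwise); SPE/APE gender contrasts use Welch's
  unequal-variance t-test; the pooled-versus-stratified MAE comparison uses
  a *paired* Wilcoxon signed-rank test on per-eye APE differences, since
  the two constant sets are evaluated on the same eyes. Exact small-sample
  p-values are verified against full-enumeration oracles in the test suite.
* **Regression**: per-formula OLS of SPE on AL, CCT, ACD (or AD), LT, Km,
  AST, WTW, age, and a male indicator (male = 1), with a likelihood-ratio
  test for the gender term against the nested model. With
  male-hyperopic-signed SPE this coding reproduces negative gender
  coefficients. Rank-deficient designs fail with the collinear columns
  named.
* No multiple-comparison correction is applied across formulas.

## Synthetic cohort generator

The generator emulates the statistical structure of a large single-IOL
optical-biometry cohort so that every pipeline stage has ground truth:

* **Marginals**: per-gender Gaussian (mean, SD) for AL, ACD, Km, LT, WTW,
  CCT, AST and age, truncated to plausibility windows (≈ ±4 SD, AST at 0,
  age to [40, 100]); AD is derived as ACD − CCT/1000. Defaults are the
  per-gender moments of a large clinical cohort (e.g. AL 23.90 ± 1.35 mm
  female / 24.49 ± 1.32 mm male; ACD 3.19 ± 0.40 / 3.31 ± 0.42 mm; Km
  44.17 ± 1.58 / 43.44 ± 1.63 D), with 56.9 % female eyes and a 53 %
  bilateral fraction chosen to reproduce an eyes-to-patients ratio near
  8431/5519.
* **Correlations**: only the marginals of the emulated cohort are known;
  the correlation structure on the (AL, ACD, Km, LT, WTW) block is a
  plausible default (AL–ACD 0.45, AL–Km −0.30, AL–WTW 0.25, others 0),
  fully configurable, and deliberately *not* targeted by any calibration
  test. Fellow eyes of bilateral patients redraw the block with latent
  correlation 0.9.
* **Surgeon policy**: the implanted power solves predicted refraction =
  target (plano by default) under a "world" formula with known true
  constants, rounded to the 0.5 D grid with exact midpoints going to the
  higher (more myopic) power, clipped to [−10, 40] D.
* **Outcome model**: observed SE = world prediction − δ_gender + ε with
  ε ~ N(0, 0.40 D). Subtracting δ from the *observed* refraction makes the
  pipeline's SPE equal +δ in expectation for that gender; the offsets enter
  through the observed refraction rather than the formula because the
  phenomenon being emulated is a residual gender effect that survives
  constant optimization — this is the minimal mechanism that produces it.
  A consistent (sphere, cylinder) pair is emitted with the cylinder
  proportional (factor 0.7) to corneal astigmatism.

What passing tests on this generator do **not** show: the generator has
Gaussian tails, a single device/surgeon, no axis structure for
astigmatism, no measurement-error model and no ocular pathology, so
calibration and recovery results demonstrate correctness of the pipeline's
mechanics, not clinical performance on real data.

## Problem sizes and numerical choices

Calibration checks use 200,000 eyes per gender (Monte-Carlo SE ≈ 0.003 on
AL), zeroization/recovery checks use seeded 4,000-eye single-eye training
strata, and the gender-effect analysis uses 4,000 eyes per stratum with
δ_f = +0.07 D, δ_m = −0.10 D — sizes at which the quantities of interest
are estimated an order of magnitude more precisely than the tolerances
tested. Root-finding runs at xtol 1e−10; vertex transpositions round-trip
to 1e−12; truncated-normal rejection sampling aborts with a configuration
error after 10,000 unproductive rounds (bounds inconsistent with moments).

## Known limitations

* Formula dialects follow the original publications and their errata; a
  specific biometer's proprietary variant (e.g. its SRK/T erratum handling)
  may differ at the 0.01 D level. The committed oracle transcriptions pin
  this package's dialect explicitly.
* Only single-constant personalization is implemented (no Haigis triple
  regression, no per-surgeon constants, no MAE- or median-targeted
  variants).
* Formulas with no published closed form (e.g. lens-factor/online-calculator
  formulas, RBF methods) are out of scope.
* Toric/multifocal IOLs and post-refractive-surgery eyes are excluded
  upstream; the validator only mirrors the exclusion flag.
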