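# Methods

## The resolution problem and its model

All three procedures assume Beer–Lambert additivity on a common wavelength
grid: a mixture spectrum is A(λ) = c₁a₁(λ) + c₂a₂(λ), with aᵢ the
unit-concentration absorptivity profiles (AU·mL/µg) and cᵢ the
concentrations (µg/mL). Each method constructs a scalar signal that is
linear in one concentration and—exactly, under the model—independent of
the other:

* **DW**: ΔA(pair) = A(λ₂) − A(λ₁) with a pair chosen so that
  a₂(λ₂) = a₂(λ₁). The cancellation is only as good as the pair: the
  package quantifies "negligible" as |ΔA| of the interferent at its top
  calibration level ≤ 0.002 AU (configurable; the underlying studies state
  no number), and the exhaustive pair search ranks qualifying pairs by
  analyte |ΔA|, breaking ties by smaller interferent |ΔA| and then by
  lower wavelength, so results are deterministic.
* **RD**: on the ratio spectrum R(λ) = A(λ)/(c_d·a₂(λ)), the interferent
  contributes the constant c₂/c_d, removed by any amplitude difference.
  The signal order (λ_plus, λ_minus) is stored explicitly in the
  configuration so persisted calibrations are unambiguous about sign.
* **¹DD**: the first derivative of R(λ) kills the same constant. The
  derivative operator is a central difference over the window Δλ:
  D(λ) = s·[R(λ+Δλ/2) − R(λ−Δλ/2)]/Δλ, with Δλ = 4 nm and scale s = 10 by
  default. A Savitzky–Golay first derivative (quadratic, same window) is
  available behind `DerivativeConfig(method="savgol")`, default off; on
  smooth bands at 0.2 nm sampling the two agree to O(Δλ²) and the central
  form is the simplest operator consistent with treating Δλ as a smoothing
  window.

Numerical conventions: wavelengths in nm on a uniform closed grid
(default 200–350 nm, 0.2 nm step, 751 points); off-grid measurement
wavelengths (e.g. 242.5 nm on a 0.2 nm grid) are evaluated by linear
interpolation, which is adequate for smooth solution-phase UV bands;
points where a divisor falls below a guard threshold (default 0.01 AU)
are masked and refuse evaluation rather than amplifying noise; derivative
traces additionally mask half a window at each grid end. Ratio
reconstruction (ratio × divisor = numerator) and derivative linearity hold
to 1e-9 on valid points and are tested as properties.

## Divisor optimisation

The original method development reports divisor choice only as "optimum
with regard to baseline noise and sensitivity". `optimize_divisor` makes
that reproducible: each candidate divisor is scored by the leave-one-out
recovery RSD% over the calibration standards (a noise figure computable
from the calibration set alone), ties within 1e-6 RSD broken by larger
calibration |slope| (sensitivity), then by input order. Noise-free, every
candidate scores RSD ≈ 0 and the most dilute divisor wins, since ratio
amplitudes — and hence the slope — scale inversely with divisor
concentration. This LOO criterion is an interpretation of the qualitative
published procedure, not a reproduction of it.

## Validation statistics

`fit_line` is ordinary least squares with Pearson r and the n−2 residual
SD; LOD/LOQ use 3.3σ/|S| and 10σ/|S| with σ the regression residual SD by
default (the intercept-SD variant is selectable; published work rarely
states which was used, and the LOQ/LOD ratio 10/3.3 is forced either
way). Standard addition regresses signal on added concentration including
the unspiked point and reports the x-intercept magnitude.

Method comparison uses the pooled-variance two-sample t test
(sp² = ((n₁−1)v₁ + (n₂−1)v₂)/(n₁+n₂−2), df = n₁+n₂−2) and the
variance-ratio F oriented larger/smaller so F ≥ 1, with two-tailed 5% (t)
and upper 5% (F) critical values from scipy's exact distributions. The
pooled (not Welch) form is deliberate: the critical values printed in the
comparison tables (2.145 at df 14, 2.179 at df 12) match pooled degrees
of freedom exactly. Both tests are verified to 1e-10 against textbook
computations on raw samples constructed to the exact summary statistics.

## The synthetic generator

Components are sums of Gaussian bands; mixtures add component responses,
an optional broad baseline, and additive homoscedastic Gaussian noise
(reproducible under a seed). Gaussian band shapes are an adequate and
analytically convenient stand-in for solution UV bands; no attempt is
made to match real aspirin/rivaroxaban absorptivities. The default
components are:

* ASP-like: bands (228 nm, σ 6 nm, 0.050 AU·mL/µg) and (269, 8, 0.009) —
  dark past ~290 nm (< 0.005 AU at 293 nm even at 40 µg/mL);
* ROX-like: bands (249, 12, 0.015) and (297, 10, 0.050) — still absorbing
  strongly past 290 nm (> 0.01 AU at 293 nm at 2 µg/mL).

Both absorb heavily and simultaneously through 230–270 nm, and the
ROX-like main band is symmetric about 249 nm so mirrored dual-wavelength
pairs cancel it exactly. Calibration ranges follow the assay protocol:
4–40 µg/mL (ASP-like, 7 levels) and 2–20 µg/mL (ROX-like, 6 levels), with
divisors at 20 µg/mL (ROX-like) and 36 µg/mL (ASP-like). The plasma-like
baseline is one broad band (210, 28, 0.35 AU) decaying to a few mAU by
290 nm, which is what makes red-side measurements matrix-tolerant;
blank subtraction removes the rest.

**Frozen measurement protocol.** Because the synthetic shapes are
structural stand-ins, measurement wavelengths were selected once on
noise-free default-model spectra and frozen in `default_protocol()`:
DW pairs (228.0, 320.4) nm for ASP-like and (305.0, 345.0) nm for
ROX-like from the pair search; RD wavelengths (228, 297) and (289, 223);
¹DD at 232.0 and 288.0 nm. The ratio-method wavelengths balance
sensitivity against divisor-noise amplification: a ratio point's noise
scales as 1/divisor absorbance, so the protocol trades a little slope for
a much stronger divisor where the two conflict (e.g. ¹DD ASP at 232 nm on
the flank rather than the 228 nm trough). One consequence of the frozen
shapes: the ASP-like component's required darkness past 290 nm puts its
36 µg/mL divisor below the 0.01 AU guard at 293–297 nm, so the published
ROX ratio wavelengths are masked on synthetic data and the synthetic
protocol measures at 288/289 nm instead; the published wavelengths remain
fully usable as fixed calibrations.

**What the generator does not emulate**: stray light, wavelength-axis
error, heteroscedastic shot noise, band asymmetry, solvent shifts, or
real plasma variability. Passing tests therefore demonstrate correctness
of the algebra and the statistical machinery under the stated model, not
instrument-grade performance on real matrices.

**Noise conventions.** "1% relative noise" for a single sample means an
additive SD of 1% of that sample's peak absorbance. Recovery-under-noise
checks use noise-free calibration and divisor standards (stored,
averaged references) with 16 noisy replicates per level at the accuracy
levels (10, 14, 22) and (5, 9, 11) µg/mL: the check isolates measurement
noise propagation through signal construction and inversion, not
calibration-transfer error. Slope-recovery coverage checks use a single
noise SD for the whole calibration set (1% of the top standard's peak),
matching the homoscedastic noise model that the OLS standard error
assumes.

## Bioanalytical arithmetic

The plasma workflow is modelled as pure volume ratios: 0.5 mL plasma
+ 4 mL spiking mixture + 0.5 mL methanol gives a 5 mL intermediate (the
only arithmetic consistent with the protocol's final concentrations —
the intermediate volume is not stated explicitly in the protocol), then
2 mL of filtrate to 10 mL; centrifugation and filtration are
volume-neutral. Matrix interference is reported per method as
|blank signal|/|top-standard signal| with a 0.02 default pass threshold.
Protein binding, extraction losses and recovery efficiency are out of
scope.

## Greenness

G = (H·S·E·W)^¼ over positive user-supplied sub-scores; the geometric
mean is monotone, permutation-invariant and bounded by the extreme
sub-scores. Published composite scores for the candidate solvents
(ethanol 6.6, DMSO 6.4, methanol 5.8) ship as reference constants and
are not recomputed, since sub-score derivation is external data.

## Problem sizes and determinism

Tests and the acceptance script run on the 751-point default grid with
the calibration designs above; the noisy-recovery and coverage checks use
16 replicates/level and 200 calibration replicates respectively. All
randomness flows through numpy `SeedSequence`-derived seeds; the pipeline
writes its seed, config hash and version, and identical configurations
produce byte-identical reports.

## Known limitations

* The pair search is exhaustive over the grid (trivial at 751 points) but
  does not model wavelength-registration error between runs.
* Divisor optimisation presumes the candidate divisors share the
  interferent's true shape; shape mismatch (concentration-dependent
  spectra, temperature shifts) is not modelled.
* JCAMP-DX support reads only `##XYDATA=(X++(Y..Y))` blocks in plain
  (AFFN) form; compressed (SQZ/DIF) encodings are not parsed.
* Critical values assume normal-theory t and F; no nonparametric
  alternatives are provided.
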