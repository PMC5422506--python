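# Methods

`craniomat` implements the constitutive-modelling layer of infant
head-impact biomechanics: nonlinear elasticity for the cranial soft tissues
(suture, scalp, dura, brain), an age-dependent orthotropic description of
the unfused skull bone, and the correlation-score metric used to judge how
biofidelic a simulated impact response is against a cadaveric drop test.
It deliberately stops where finite-element machinery begins: no meshes, no
contact, no explicit time integration.

## Hyperelastic soft-tissue laws

All soft tissues are modelled in their uniaxial nominal-stress
(engineering-stress) form, the form in which tension tests on suture and
scalp specimens are reported.

**Ogden.** For stretch ratio λ > 0,

```
σ(λ) = Σᵢ μᵢ (λ^(αᵢ−1) − λ^(−1−αᵢ/2))
```

Every term vanishes at λ = 1, so the unloaded state is exactly stress-free
for any parameter set — this is asserted as a property over randomized
materials. Suture and both scalp layers are single-term materials; brain
tissue uses a two-term set with a negative (μ, α) pair. The tangent
(Young's) modulus is the analytic derivative dσ/dλ, which at λ → 1 reduces
to Σᵢ 1.5 μᵢ αᵢ; it is verified against a central-difference oracle to
1 part in 10⁵ over λ ∈ [1.01, 3].

A note on the bundled suture constants (μ₁ = 1.48·10⁴ Pa, α₁ = 6.9): they
were produced by fitting a single 2-month-old specimen curve and rescaling
μ₁ so the modulus at λ = 2.5 matches the 8.1 MPa population average. With
the tangent definition used here, the modulus at λ = 2.5 evaluates to
≈7.78 MPa, about 4 % below 8.1 MPa. The original slope definition at that
stretch (tangent vs chord, and the strain measure) is ambiguous; we commit
to the tangent of nominal stress with respect to stretch and accept the 4 %
residual, testing it at a 10 % band.

**Mooney–Rivlin** (dura mater), incompressible uniaxial form:

```
σ(λ) = 2 (C₁ + C₂/λ) (λ − λ⁻²)
```

Incompressibility is assumed because only (C₁, C₂) and ν ≈ 0.49 are
available for foetal dura.

**Calibration.** `fit_ogden` minimizes squared nominal-stress residuals
with scipy's trust-region Levenberg–Marquardt (`least_squares`, method
`trf`, bounds α ∈ (0, 50]). Default initialization is
μ₁ = max|σ|/2, α₁ = 5 plus two randomized restarts (seeded); the best
residual wins. A `weighting="relative"` option divides each residual by
the local stress magnitude — the matched maximum-likelihood estimator when
measurement error is multiplicative, and necessary in practice because a
soft-tissue curve spans several decades of stress and an absolute-residual
fit is governed by its top few points. Parameter recovery on noise-free
synthetic curves is exact to 0.1 %; with 2 % multiplicative noise the
relative-weighted fit recovers within 10 %.

`rescale_to_target_modulus` multiplies every μᵢ by
(target / current tangent at the reference stretch); because the tangent is
linear in μ, the post-condition holds to machine precision and the
operation is idempotent.

## Age-dependent orthotropic skull bone

Age is measured in months since 40-week gestation; negative ages are
preterm (the bundled "newborn" row is a 34-week specimen, −1.35 months);
adulthood is taken as 216 months.

**Anisotropy decay.** The ratio f(age) = E1/E2 of parallel- to
perpendicular-to-fibre Young's moduli is a two-term exponential

```
f(age) = 0.9071 e^(−0.3017 age) + 1.398 e^(−0.00155 age)
```

giving 2.31 at term birth, 1.25 at six years and 1.00 (isotropy) at
18 years. `fit_anisotropy_model` recovers such coefficients from (age,
ratio) scatter by bounded least squares (amplitudes ≥ 0, rates ≤ 0),
returning the fastest-decaying term first; noise-free recovery is within
1 %.

**Stiffness growth.** Measured E2(age) scatter is fitted by a cubic
B-spline constrained to be monotone nondecreasing and concave — the shape
of a saturating biological growth process. Knots sit at age quantiles
(at most 6 interior). The constraints are imposed through a cone
reparametrization: with derivative-spline coefficients
dᵢ = k(cᵢ₊₁ − cᵢ)/(tᵢ₊ₖ₊₁ − tᵢ₊₁), monotonicity-plus-concavity is exactly
d₀ ≥ d₁ ≥ … ≥ 0; substituting dᵢ = Σⱼ≥ᵢ uⱼ with uⱼ ≥ 0 (and splitting the
free intercept into a positive pair) turns the fit into a plain
non-negative least-squares problem solved exactly by Lawson–Hanson NNLS.
Unlike an SLSQP-style solver, this leaves no constraint-violation slack:
the returned spline satisfies the shape constraints to floating-point
round-off, verified on a 0.5-month grid. When the constraints are
inactive (e.g. data on a straight line) the fit coincides with ordinary
least squares.

E1 data are derived as E1 = E2 · f(age) and fitted with their own curve;
a material card at age *a* reads E1 and E2 off their independently fitted
curves, not E2 · f at evaluation time.

**Nine-constant assembly.** With E1 ≥ E2 and Poisson defaults
ν12 = ν13 = 0.22, ν23 = 0.19 (adult values, assumed age-invariant):

- E3 = E2 (through-thickness ≡ perpendicular),
- ν21 = ν12 E2/E1 (compliance symmetry),
- G23 = E2 / (2(1 + ν23)) — isotropic relation in the transverse plane,
- G12 = G31 = √(E1E2) / (2(1 + √(ν12ν21))) — Huber's geometric-mean
  in-plane shear estimate.

No published statement fixes the shear closure; this pair was committed
because it reproduces all twelve bundled shear entries to one unit in the
printed decimal (eleven exactly at printed precision; one entry, the 9-month
parietal G23, computes to 258.78 against a printed 258.7, consistent with
the source having used an unrounded E2). The 6×6 compliance matrix is
checked for symmetric positive definiteness at construction; within the
ranges the closure enforces the matrix is provably SPD, so the stability
gate exists to catch hand-built constant sets.

**Density** uses a lookup of the three bundled values
{−1.35 mo: 2150.0, 5 mo: 2080.0, 9 mo: 2075.3 kg/m³} with linear
interpolation, clamped outside the table. The published one-line
extrapolation recipe cannot reproduce all three printed densities
simultaneously, so the printed values are authoritative.

**Frontal bone** resolves to parietal properties (stated assumption).

## Correlation-score biofidelity rating

Both curves are resampled to a common uniform grid (default Δt = 0.2 ms)
spanning the union of their time windows, zero-padded outside each curve's
own support. The exact sub-score normalizations of the source rating
method are not publicly tabulated; the formulation below is this package's
own, chosen to satisfy every documented behaviour (identical curves score
100/100/100; a pure amplitude scaling leaves phase and shape at 100; the
phase score decreases monotonically with time shift; the published
averages follow by arithmetic mean):

- **N-phase** = 100 · max(0, 1 − |δ|/D), where δ is the lag maximizing the
  cross-correlation of the two gridded signals and D is the reference
  pulse duration (time between 5 %-of-peak crossings).
- **N-amp** = 100 · max(0, 1 − |A_t − A_r|/A_r) on the lag-aligned test
  curve, with A = √∫v² dt the RMS-integral amplitude.
- **N-shape** = 100 · max(0, 1 − ‖x̂ − y‖₂/‖y‖₂), where x̂ is the aligned
  test curve rescaled to the reference amplitude.

CS is the arithmetic mean of the three, and maps to a biofidelity label:
≥ 86 excellent, ≥ 65 good, ≥ 44 fair, ≥ 26 marginal, else unacceptable.
A score of exactly 100 is classified excellent (perfect agreement cannot
be unrated). An identically-zero reference raises an error; an
identically-zero test scores (0, 0, 0).

Kinematics helpers cover the validation protocols: free-fall impact
velocity √(2gh) (30 cm standard drop, 82 cm for the historical whole-body
drops), acceleration from measured force a = F/(m·9.81) in g, pulse peak
and 5 %-threshold duration with interpolated crossing times,
characteristic head length (length + width + circumference) and its
scaling factor, and plate velocity = 0.3 s⁻¹ × head dimension for
compression tests.

## Synthetic data

No experimental records are publicly tabulated for the tissue tests or
drop signals, so every input class is emulated (`craniomat.fixtures`); all
generators are pure functions of their arguments.

- **Uniaxial curves:** exact Ogden/Mooney–Rivlin stresses times (1 + ε),
  ε ~ N(0, noise_sd) — multiplicative noise keeps the λ = 1 zero exact.
- **Age–stiffness scatter:** multiplicative lognormal noise around a
  saturating-growth truth E(age) = 600(1 − e^(−age/12)) + 150 MPa
  (defaults chosen to match the order of magnitude and time scale of
  infant cranial stiffening: ~150 MPa near term, rising by several hundred
  MPa over the first two years). Lognormal scatter keeps moduli positive,
  matching the large specimen-to-specimen variability of infant bone.
  Default noise_sd = 0.2.
- **Impact pulses:** haversine A·sin²(πt/T); the sampling step is shrunk
  (never grown) so the midpoint lies on the grid and the sampled maximum
  is exact. Double-peak parietal-type pulses superpose a second haversine
  delayed by a separation and scaled by a fraction (default 0.6).

A green test on synthetic data establishes that the estimators recover
known ground truth under the stated noise model — not that real suture or
bone follows these laws, and not that any finite-element model is valid;
those questions need the experiments themselves.

## Numerical choices and limitations

- Stresses are stored in Pa internally; MPa is accepted in material JSON
  via an explicit `units` field. CSV headers embed units.
- Printed-value comparisons in `verify_reference_tables` use one unit in
  the last printed digit (0.1 MPa for shear moduli, 0.01 for score
  averages) — the minimal band consistent with the sources' own rounding
  of intermediate values.
- Growth curves clamp, rather than extrapolate, outside their fitted age
  span.
- The toolkit models uniaxial response only: no 3-D stress tensors, no
  viscoelasticity, no compressible hyperelasticity, no failure criteria.
- The anisotropy model is calibrated on foetal/child/adult ratio data; its
  validity band is [−5, 216] months and evaluation outside raises.
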