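# Methods

## Model overview

The package predicts a child's stature twice over: once at adulthood and
once at an arbitrary intermediate ("stage") age. The two predictions
share one object, the per-sex population mean height-for-age curve
*f*(*x*), and differ in what they add to it: a regression model for the
endpoint, a three-parameter curve registration for the path.

### Mean growth curve

*f* is a polynomial fitted by least squares to a growth reference's mean
(0 SD) height column. The least-squares problem is the textbook one —
minimise Σ(*P*(*x*ᵢ) − *y*ᵢ)² over polynomial coefficients, equivalently
solve the normal equations *A* = (*X*ᵀ*X*)⁻¹*X*ᵀ*y* for the Vandermonde
design *X* — but the production solver works on ages affinely mapped to
[−1, 1] and converts the coefficients back to the raw power basis: a raw
Vandermonde on ages 6–18 at degree 5 has condition number ~10⁹, and the
explicit normal equations square it. The normal-equation route is kept
(`normal_equation_fit`) purely as a cross-check; tests verify both agree
to 10⁻⁶ relative.

Degree defaults to 5 (configurable). Degrees 4–6 reproduce the smooth
sigmoid shape of mean-height curves on typical half-year grids; the
reported `fit_rmse_` makes the approximation error visible. Above the
last grid age the curve is clamped to its value at `age_max` (the adult
plateau); below the first grid age evaluation raises rather than
extrapolate a polynomial outside its support.

### Adult-height network

Architecture: 6 inputs → 100 ReLU units → 1 linear output, one network
per sex (sex is a model key, never a feature). Inputs, in fixed order:
bone age (y), age (y), height (cm), weight (kg), BMI (kg/m²), and the
deviation of BMI from a standard BMI-for-age table (linear interpolation
in age). BMI is always recomputed from height and weight.

The loss is the banded squared loss with band *b* = 0.5 cm,
mean(max(0, |residual| − *b*)²): repeat measurements of the same child
differ by about half a centimetre between morning and evening, so
residuals inside the band are treated as already correct rather than
overfit. The squared hinge is C¹ everywhere, including the band
boundary; *b* = 0 recovers mean squared error exactly, which the tests
exploit by comparing a *b* = 0 training trajectory against an
independent MSE backprop transcription step for step.

Optimisation is deliberately plain: full-batch gradient descent at a
constant learning rate of 5 × 10⁻⁵ for a fixed iteration count (46,000
male / 48,500 female by default), no early stopping. Three recipe
choices the optimiser needs but the architecture does not dictate:

* **Input z-scoring** per feature, stored in the model. Raw cm/kg scales
  at this learning rate would stall.
* **Target z-scoring**, also stored. The forward pass maps the network's
  raw output back to cm, so the loss and its gradient are always exact
  in cm; but the descent itself operates on unit-scale quantities.
  Without this the constant 5 × 10⁻⁵ rate needs on the order of 10⁵
  iterations merely to move the output from zero to the cohort mean.
* **Seeded He-uniform initialisation** (weights ∝ √(6/fan-in)), zero
  biases. With the target z-scored, a zero output bias already predicts
  the cohort mean at iteration 0.

Training is bitwise deterministic given (data, parameters, seed). An
optional momentum term exists and is off by default. Train/validation
splitting is a seeded shuffle with validation count ⌊n/4⌋ at the default
3:1 ratio, so 615 records split 462/153.

### Personal-curve registration

A child's curve is *H*(*x*) = *f*(α*x* + β) + γ: tempo α > 0 compresses
(α > 1 is actually a *flatter*, slower-resolving trajectory when read
against calendar age; fast-puberty children have α < 1), phase β shifts
(positive = early developer), amplitude γ lifts (short children have
small γ).

Fitting is two-stage, mirroring how the quantities are defined:

1. γ = *H*<sub>final</sub> − *f*(18), with *H*<sub>final</sub> the
   predicted (or known) adult height and 18 the configurable adult age.
2. (α, β) minimise the summed squared residuals of the anchor equations
   — each observed (age, height) pair plus the adult anchor — by bounded
   nonlinear least squares (trust-region reflective), bounds
   α ∈ [0.5, 1.5], β ∈ [−4, 4] years, started from the population
   average (1, 0) plus a small deterministic multistart grid. With a
   single observation this is the classic two-equation system in two
   unknowns; measurement error makes it inconsistent, hence least
   squares, and additional historical visits simply add residuals.

During the search a transformed age above the base domain uses the adult
plateau (clamp), while one below the domain is evaluated at the clamped
age *plus* a smooth quadratic penalty (10 cm per year of violation), so
the objective stays continuous instead of failing hard.

The two-stage system is intrinsically overdetermined: at the true
parameters of a warped child the anchor equations cannot all be zero
unless *f* is flat over the interval between the warped and nominal
adult ages. A joint three-parameter refit (`joint_refit=True`) is
therefore provided; on noiseless data it recovers a generated (α, β, γ)
triple to solver precision, and it is the mode the loop-closure tests
use. The two-stage path remains the default because γ's definition as
"adult height minus population adult mean" is the quantity users
interpret.

Deviations are always reported as predicted − observed. Display rounding
is half-away-from-zero to two decimals; internal arithmetic never
rounds. (The bundled worked-example tables contain rows whose published
deviation differs by 0.01 cm from the difference of the published
rounded heights — those deviations were computed upstream from unrounded
predictions; the evaluation keeps both full-precision and display
columns so this cannot happen downstream.)

### Baselines

The mid-parental formulas (boys 56.699 + 0.419·father + 0.265·mother;
girls 40.089 + 0.306·father + 0.431·mother, cm) and Bayley–Pinneau
*Y* = *H*/FP with FP linearly interpolated in bone age from a per-sex,
per-developmental-category table. FP is stored as a fraction in (0, 1];
percent-published tables are divided by 100 at load time. Developmental
category (early/normal/late) is an input: the package does not infer it.

## Synthetic data

Real cohorts of this kind are private clinical records, and the national
0 SD, WHO standard-BMI and Bayley–Pinneau FP tables are licensed
publications, so everything the tests and the acceptance script consume
is generated:

* **Reference tables**: Preece–Baines model-1 heights
  (h₁ − 2(h₁ − h_θ)/(e^{s₀(t−θ)} + e^{s₁(t−θ)})) tabulated on a 6–18
  half-year grid, rounded to 0.1 cm. Parameters (boys h₁ = 174.5,
  h_θ = 163, s₀ = 0.12, s₁ = 0.9, θ = 13.0; girls 162.5, 152, 0.16,
  0.8, 10.8) give realistic East-Asian mean statures while keeping the
  spurt gentle enough that the default degree-5 fit is non-decreasing
  over the whole domain and nearly flat at 18 — the shape the
  registration model assumes. The pubertal peak velocity is accordingly
  somewhat lower than real national references.
* **Cohorts**: per child, α ~ lognormal(0, 0.05), β ~ N(0, 0.8 y),
  γ ~ N(0, 4 cm); two visits one year apart, first age uniform on
  [8, 15]; observed heights add N(0, 0.5 cm) stadiometer noise; true
  adult height is the child's own warped curve at 18 (noise-free). Bone
  age tracks the developmental age α·age + β, is advanced further by
  0.15 y per kg/m² of the child's stable BMI offset (~N(0, 1.5 kg/m²),
  emulating adiposity-accelerated maturation), and carries N(0, 0.25 y)
  assessment noise. Weight is derived from the BMI trajectory and the
  true height, so the BMI channels carry real signal. All draws flow
  from a single seed.

What the generator does **not** emulate: secular trends, measurement
rounding to 0.1 cm, visit-frequency heterogeneity, catch-up growth after
illness, or any demographic structure. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, not
that it attains any particular accuracy on real cohorts.

A consequence worth stating plainly: with one visit per child the
simulation's own information floor for adult-height prediction is about
1.1 cm MAE — bone-age noise (0.25 y) multiplied by pubertal growth
velocity (~5 cm/y), plus the unobservable tempo — which an analytic
predictor that knows the true generative model cannot beat. The trained
network approaches that floor at full iteration counts and sits ~0.2 cm
above it at the desk-scale 2,000 iterations used in the acceptance
script.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics (type 7) —
  stated because boxplot IQRs and hence the 1.5·IQR outlier set depend
  on the convention. Within-*k* accuracy counts |deviation| strictly
  less than *k*.
* Constant features in training data get scale 1 (no division by zero);
  training data with non-finite values, empty batches, mismatched
  lengths, duplicate reference ages, non-monotone reference heights and
  out-of-range table lookups all raise `ValueError` with the offending
  quantity named.
* Non-finite training loss aborts with the iteration index.
* Problem sizes: the test-suite and acceptance runs use 400 subjects per
  sex, 2,000 training iterations and a 200-child registration study —
  the sizes at which every qualitative behaviour of the full-scale
  configuration is already visible.

## Known limitations

* Stage-height error compounds adult-height error with registration
  error; accuracy at intermediate ages is accordingly lower than at the
  endpoint, most visibly mid-spurt.
* (α, β) are weakly identified from visits on the post-spurt plateau;
  the fitted curve (and hence stage predictions) remains stable, but the
  individual parameters can trade off against each other, and tempo α is
  essentially unidentifiable from a single visit with realistic noise.
* The polynomial mean curve is only as monotone as its reference grid
  allows; users supplying their own reference should check `fit_rmse_`
  and the curve shape at the domain edges (degree is configurable for
  exactly this reason).
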