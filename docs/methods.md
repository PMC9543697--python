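# Methods

## The calibration model

A film calibration is a bijective map between net optical density
`o = log10(Ī_before / I_after)` (red channel of a transmission flatbed
scan) and absorbed dose `d` in Gy. Two families are implemented:

* **bimolecular (saturation) model** — `f⁻¹(o) = θ₂ (o/(θ₁−o))^{1/θ₃}`,
  with `θ₁` the saturation net OD (the OD approached at infinite dose),
  `θ₂` the dose at half-saturation (Gy) and `θ₃` a dimensionless shape
  exponent. The forward map is the sigmoid
  `f(d) = θ₁ (d/θ₂)^{θ₃} / (1 + (d/θ₂)^{θ₃})`, closed-form in both
  directions and strictly monotone for positive parameters.
* **polynomial** — `f⁻¹(o) = Σ_{m=0}^{N} θ_m o^m`, default degree 4. The
  forward map is obtained by bracketed root finding (Brent, `xtol` 1e−12)
  over the validity interval, after an explicit monotonicity check. The
  constant term is free: the zero-OD region is outside the validity range
  anyway, and pinning it would bias low-dose reconstruction.

All fitting is done in normalized coordinates — net OD divided by the
largest OD in training, dose by the largest dose — so both span [0, 1] and
start-value scales are meaningful across data sets. Polynomial
coefficients denormalize as `θ_m^phys = θ_m^norm · s_d / s_o^m`; the
saturation model as `θ₁^phys = θ₁ s_o`, `θ₂^phys = θ₂ s_d`.

A fitted calibration is only considered valid between the lowest and
highest net OD observed in its training films (gradient and plateau
regions alike); it is never extrapolated, and an accepted fit must pass a
bijectivity check (strictly increasing and positive dose on a 512-point
grid over the validity interval).

## The dose-ratio objective

One relative profile `d(r)` (normalized to 1 on the plateau) is delivered
at levels `k_i`; film `i` records `o_i(r) = f(k_i d(r))`. Eliminating the
unknown profile via the quotient of two levels and clearing the
denominator gives the per-position residual

```
h_{i,j,r} = (k_i k_j)⁻¹ (k_j f⁻¹(o_{i,r}) − k_i f⁻¹(o_{j,r}))
```

whose square, summed over the gradient-region positions (default
15–27 mm) with weights `w_r` (default 1) and over all measurement pairs
from *different* dose levels, is χ_a. With N levels and 3 repetitions the
pair count is `9 N (N−1)/2`; repetitions of one level are never paired
with each other. χ_a alone fixes the curve only up to transformations that
distort all reconstructions consistently, so an absolute side objective
χ_b — the squared dose residual of one known reference point — is added.
One point per selected level enters χ_b (repetitions averaged to a single
plateau OD; by default only the highest training level, so N_d = 1), with
weight `w_b = w_s · N_r · n_pairs / N_d` balancing the two sums by their
summand counts; `w_s = 10`. Raising `w_s` by orders of magnitude forces
the curve exactly through the anchor.

Including every repetition as a separate χ_b point is deliberately *not*
done: with the large `w_b`, the optimizer can then lower the spread of the
replicate plateau residuals by locally flattening the top of the curve,
which biases the rest of the range by several percent. Anchoring on the
replicate mean removes that lever.

The analytic gradient of χ w.r.t. θ uses the per-family partials of
`f⁻¹`: powers `o^m` for polynomials, and for the saturation model
`∂d/∂θ₁ = −d/(θ₃(θ₁−o))`, `∂d/∂θ₂ = d/θ₂`,
`∂d/∂θ₃ = −d ln(o/(θ₁−o))/θ₃²`. Both are verified against central finite
differences in the test suite.

## Optimization

χ is a sum of squares, so the default minimizer is trust-region least
squares (`scipy.optimize.least_squares`, method `trf`) on the stacked
residual vector `[√w_r h_{i,j,r}, √w_b (f⁻¹(o_i)−d_i)]` with its analytic
Jacobian; termination at gradient tolerance 1e−10 (normalized) or 1000
evaluations. A quasi-Newton path (BFGS on χ with its gradient) is
available and agrees with the default to well below 0.01% in reconstructed
dose on noise-free recovery; a plain quasi-Newton line search is however
much less robust on this stiff surface (w_b is of order 10⁴–10⁵), which is
why the trust-region solver is the default.

Start values are i.i.d. normal, zero-centered with σ = 0.1 in normalized
coordinates for polynomials (small values avoid the oscillation /
start-value correlation that plagues high-degree polynomial fits). For
the saturation family a zero-centered start is never physically meaningful
— θ₁ must exceed every observed net OD — so the same draws are re-centered
on a feasible anchor (θ₁ = 1.2·o_max, θ₂ = 0.5, θ₃ = 1, normalized) and
the solver keeps θ₁ above o_max as a domain bound. Starts with non-finite
initial cost and fits that fail the bijectivity check are rejected;
among accepted restarts (default 20 per fit) the lowest cost wins, ties
broken by restart index. Parameter vectors that wander outside the model
domain during optimization receive a large finite penalty instead of NaN
so step control stays well defined.

The standard (reference) method minimizes the unweighted squared dose
residuals of the plateau points only, with the same normalization,
restart and acceptance machinery; it is only evaluated when the number of
points strictly exceeds the number of free parameters. Its validity range
still spans everything *measured* on the training films, including the
gradient region, so both methods are scored on identical held-out points.

## Synthetic measurements

The generator emulates a pencil-beam-scanning-like radial field: dose 1.0
up to a 15 mm plateau radius, a cosine shoulder to 80% at 17 mm, linear
falloff to 20% at 26 mm, then an exponential tail with matched slope;
samples below 5% of the plateau are excluded. Films are 67 mm squares
scanned at 300 dpi (0.085 mm pixels); test images are rendered at a
coarsened 0.4 mm pixel to keep suites fast, which preserves the profile
shape well below the per-mille level.

Ground-truth response defaults to the saturation model with
θ = (0.9, 7.0 Gy, 1.0): net OD ≈ 0.11 at 1 Gy and ≈ 0.57 at 12 Gy (about
two thirds of saturation), matching published EBT3 red-channel response
curves. The choice matters for cross-family experiments: a much more
saturated truth makes the best achievable quartic approximation worse
than the few-percent envelope that quartics reach on real film, which
would say nothing about the method and everything about an unrealistic
phantom. These parameters are synthetic stand-ins, not measured batch
values.

Noise has two parts: a per-film multiplicative response factor
(σ = 0.5%, the inter-repetition repeatability) applied to the whole OD
profile, and additive per-pixel OD noise (σ = 0.002 + 0.01·o) that
averages down as 1/√count when pixels are rebinned — per-bin counts follow
the annulus areas, so gradient-region bins carry of order 10³–10⁴ pixels.
The generator therefore produces nearly noise-free profile *shapes* with
film-to-film response scatter, which reproduces the plateau repeatability
seen in repeated film measurements but not spatially correlated artifacts
(film mottle, scanner banding, curl); conclusions about how such
structured noise propagates through the method cannot be drawn from these
tests. Monte-Carlo beam transport is out of scope; the four-field
single-exposure layout adds an optional uniform cross-scatter term
(default off; 1% of the lowest plateau dose when enabled) to probe the
mutual-field perturbation at that magnitude.

## Evaluation experiments

Calibrations are scored by the percent deviations of reconstructed
held-out plateau doses and their RMSD. Dose levels move between train and
test as units (a level with all its repetitions). Test points whose
plateau OD lies outside the fitted validity range are excluded from the
RMSD but counted and reported. The split experiment draws `n_train`
levels uniformly without replacement, fits with a single fresh random
start per repeat, and derives each repeat's level choice and start seed
only from (seed, repeat), so ratio and standard methods can be compared
on identical splits and start values. Default 200 repeats (1000 by
configuration). Within the split and sweep experiments the
highest-dose-in-training requirement is relaxed to a warning and the side
objective anchors on the highest *training* level; the two-level sweep
admits only pairs containing the overall highest level, where the anchor
is exact.

The split-trend experiment is run with the generating (saturation) family
by default in the acceptance script: with a cross-family fit the held-out
error at many training levels is dominated by the quartic's fixed
approximation error to the synthetic truth rather than by the statistics
of the method, and the question "how many dose levels are needed" is only
well posed when the family can represent the truth. The two-level
dose-ratio sweep uses the quartic, where the interplay of model
flexibility and low-dose noise is precisely the effect under study — it
is what makes the extreme dose ratios (≈1.2 and ≈48) worse than the
mid-range (≈16–24).

Problem sizes used by the acceptance script: 12 levels × 3 repetitions,
0.25 mm radial bins (48 gradient positions), 200 split repeats per
training-set size, 50 sweep repeats per admissible pair, 50 rendered
films for center-finding statistics at 0.4 mm pixels.

## Numerical notes and limitations

* Radial rebinning centers values before accumulating first and second
  moments; the naive `E[x²]−E[x]²` form loses all significance on
  near-constant maps.
* Center finding is a two-stage grid search (coarse ±5 mm / 1 mm, fine
  ±1 mm / 0.1 mm) minimizing the OD spread over the ring at the 50% dose
  radius (default 21.5 mm, from the known profile); the annulus half-width
  defaults to max(pixel, 0.5 mm). Ties resolve to the first grid point in
  row-major order; a structureless map raises a degeneracy error.
* The χ_b count normalization `w_b = w_s N_r n_pairs / N_d` reduces to
  the balance-by-summand-count rule at N_d = 1, the only case exercised
  by default; its behavior for many side points is untested against
  practice.
* Uncertainty propagation (parameter covariance, dose-map error bars),
  multichannel dosimetry, scanner lateral-response / polarization / curl
  corrections and beam-quality response corrections are out of scope.
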