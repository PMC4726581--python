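# Methods

This note documents the models, numerical choices and limitations behind
`soilbme`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A small plot (35 m × 35 m in the default configuration) carries two coupled
attributes: soil temperature T, measurable densely (1-m grid, 1225 nodes),
and soil CO₂ efflux Rs, measurable only at sparse points (a 7×7 grid at 5-m
spacing, or nested subsets of 9/21/37 points). The goal is a map of Rs with
quantified uncertainty, using the dense temperature as auxiliary information.

## Soft data from the flux–temperature response

The response model is exponential (Arrhenius-type), `Rs = a·e^{bT}`, fitted
by `scipy.optimize.curve_fit` initialized from the linear regression of
ln(Rs) on T (fallback initialization `b₀ = 0.1` when fluxes are not all
positive). From the fit we keep, besides (a, b):

| quantity | meaning | default/source |
| --- | --- | --- |
| `S_TP` | residual SD, `sqrt(SSE/(n−2))`, flux units | computed |
| `S_TT` | `Σ(Tᵢ − T̄)²`, °C² | computed |
| `CR` | Pearson correlation of observed vs fitted flux | computed |
| `t_crit` | Student-t quantile, df = n−2, two-sided 95% | computed from the quantile function |

`t_crit` is deliberately **computed**, not copied from published tables: for
n = 49 the two-sided 95% value at df = 47 is ≈ 2.012, whereas a commonly
printed 1.761 corresponds to a different df/one-sided convention. A
`t_crit_override` argument reproduces printed arithmetic when needed.

A temperature reading at location s becomes a soft datum: a Student-t density
with center `a·e^{bT(s)}`, scale `S_TP·sqrt(1 + 1/n + (T−T̄)²/S_TT)`, df = n−2,
truncated at 0 (fluxes are physically non-negative) and renormalized. The
scale is even in (T − T̄) and non-decreasing in |T − T̄|: temperatures far from
the calibration mean constrain the flux less. The 95% central interval of the
untruncated density equals the regression prediction interval by construction.

Parameter confidence intervals use the curve_fit covariance; for the positive
multiplicative coefficient *a* the well-calibrated interval is the Wald
interval on ln a (the linear-scale interval undercovers because a's sampling
distribution is right-skewed).

## Variography

Experimental semivariograms use half-open lag bins `[k·w, (k+1)·w)` with
default width w = 5 m (the sampling spacing) and maximum lag = half the
maximum pairwise distance; empty bins are kept and flagged rather than
dropped. The cross-variogram requires exactly co-located samples. Models:

* gaussian: `γ(h) = C₀ + C(1 − e^{−3h²/a²})` — practical range a where γ
  reaches ≈ C₀ + 0.95·C;
* spherical: `γ(h) = C₀ + C(1.5 h/a − 0.5 (h/a)³)` for h ≤ a, the sill beyond.

Both use the exact-interpolator convention γ(0) = 0. Fitting is weighted
least squares with pair counts as weights (the convention of the widely used
GS+ software), from five deterministic starts spanning the empirical sill and
lag span; ties break on weighted SSE then smaller range. A flat empirical
variogram returns a flagged pure-nugget model instead of crashing. The
nugget-to-sill ratio C₀/(C₀+C) classifies spatial dependence: strong < 0.25,
moderate 0.25–0.75, weak above.

## Kriging and cokriging

Both solvers are semivariance-form Lagrange systems over the nearest
neighbors (default 16 per attribute; nearest-neighbor ties break
lexicographically by (x, y) for determinism). OK enforces Σλ = 1; Co-OK
enforces Σλ₁ = 1 and, by default, Σλ₂ = 0 — the traditional condition that
keeps the estimator unbiased whatever the secondary attribute's mean. The
alternative Σλ₂ = 1 convention that some sources print is available as
`secondary_constraint="paper"`; it biases the estimate unless the secondary
is rescaled, which is why it is not the default.

When the three variogram structures are *fitted independently* (the
experiment drivers), the cross sill routinely violates the linear model of
coregionalization and the cokriging matrix becomes indefinite. The drivers
therefore adopt an intrinsic coregionalization: all three structures share
the primary's correlation shape, the secondary and cross keep their fitted
sills, and the cross sill is clipped to 0.95·sqrt of the product of auto
partial sills. Nuggets are floored at 1e-4 of the sill because zero-nugget
gaussian covariance matrices are numerically near-singular.

## The BME engine

The prior over (estimation point, hard points, soft points) is the
maximum-entropy density under mean and covariance constraints — in closed
form, the multivariate Gaussian with constant mean (the hard-data mean by
default; the plot is treated as second-order stationary) and covariance
C(h) = sill − γ(h), with C(0) = sill (coincident locations are the same
random variable). A discretized Lagrange-multiplier solver in the test suite
verifies that this closed form is the entropy maximum.

The posterior at the estimation point is

```
f_K(x_k) ∝ ∫ f_S(χ_soft) · f_G(x_k, χ_soft | χ_hard) dχ_soft
```

computed by conditioning the Gaussian on the hard values and integrating the
soft coordinates with 21-node Gauss–Legendre tensor quadrature (≤ 4 soft
neighbors; the default is 3, keeping the worst case under 10⁴ nodes). The
integrand factorizes so the posterior is a mixture of Gaussians with common
variance, evaluated vectorized over the support. Numerical safeguards:

* **Quadrature bounds.** Each soft dimension is integrated over the overlap
  of its truncated 99.9% support with the ±8 SD region of its Gaussian
  conditional given the hard data — 21 nodes stay accurate when the soft
  density and the conditional have very different widths (vague soft data,
  near-delta soft data).
* **Support.** The flux support covers all non-negligible mixture-component
  means ±8 kernel SDs, resolved to a third of the kernel SD (281–4001
  points), clipped below at 0, and widened automatically until the mass
  outside is < 1e-6.
* **Co-located soft data.** A soft datum at the estimation point itself is
  perfectly correlated with x_k under C(0) = sill, so its density multiplies
  the posterior directly (the exact limit); the product is evaluated in log
  space to survive underflow, with the support refined locally around the
  co-located density.
* **Log-space weights** throughout; a posterior that cannot be normalized
  raises instead of returning garbage.

The point estimate is the posterior mean by default (trapezoid rule); the
mode (grid argmax + parabolic refinement, ties toward lower flux) is
available. With zero soft data the machinery reduces to the Gaussian
conditional, i.e. simple kriging — the suite checks mean and variance to
1e-6. Estimation at a hard-data location returns the measured value with
SD 0 (exactness).

## Synthetic world

The generator draws stationary Gaussian fields by dense Cholesky
factorization (exact at ≤ ~5000 nodes; 1e-10 jitter) and couples flux to
temperature through the exponential link plus a zero-mean correlated
residual. Defaults, chosen once to match the emulated warm-day regime and
then frozen:

| component | default | rationale |
| --- | --- | --- |
| temperature field | mean 27.18 °C, gaussian variogram, nugget 0.01, partial sill 0.15, range 20 m | reproduces the reported day-2 mean/SD (27.18 / 0.4 °C); smooth 20-m structure typical of plot-scale soil temperature |
| link (a, b) | 0.1331, 0.1370 | the reported day-2 fit; the day-1 printed pair implies a mean flux ~6× the reported one and is treated as unreliable |
| flux residual | spherical, nugget 0.02, partial sill 0.15, range 15 m | yields flux SD ≈ 0.5 and a temperature-explained variance fraction ≈ 0.35, consistent with the reported flux SD (0.512) and fit correlation (CR ≈ 0.57) |

Negative simulated fluxes are counted, not clipped, unless clipping is
requested — keeping the Gaussian assumptions transparent for the recovery
tests. Sampling designs are nested and symmetric: the centre node, 1–3
points per half-axis, and 1/3/6/9 points per quadrant (in a frame rotated
with the quadrant), giving 9 ⊂ 21 ⊂ 37 ⊂ 49. The published experiment never
prints its exact point placement; this construction is one consistent,
deterministic reading.

**What the generator does not emulate:** non-Gaussian flux distributions
(real fluxes are right-skewed), anisotropy, temporal dynamics, soil-moisture
or biological covariates, and measurement-protocol artifacts. A green test on
this world establishes that the estimators behave as claimed *under their own
assumptions*, not that they would rank identically on any real plot.

## Validation design

Hold-out cross-validation selects interior, pairwise non-adjacent points
(no two within one grid spacing), uniformly at random under a seed — the
formalization of "avoid boundary and contiguous points". RMSE, mean bias and
Pearson correlation are the scores. The shrinking-design experiment
validates each method against the simulated truth at the non-sampled nodes
of the dense grid, thinned by a stride of 2 per axis (~320 targets) to keep
a 30-replicate run on one CPU in minutes; aggregation reports mean ± SD
across seeds and comparisons use paired per-seed differences.

A known limitation surfaced by this design: with temperature explaining only
~32% of flux variance (the realistic regime above), soft data cannot push
BME's error below the unexplained-residual floor, so BME with 9 points does
not beat OK with 37 points even though BME beats OK like-for-like at every
design size. The corresponding acceptance assertion is kept as specified and
fails honestly; see the repository's decision log for the quantitative
analysis.

## Pipeline and formats

Point samples travel as `x,y,value` CSV; rasters as ESRI ASCII grids
(cell-centre convention, plain metres; the writer emits rows north-to-south).
`run_pipeline` executes simulate → variogram → softdata → krige → bme →
validate with a single seed feeding every random draw; identical
configurations produce byte-identical text outputs (6-significant-digit
formatting).
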