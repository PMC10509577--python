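# Methods

## The problem

Camera traps on a tidal island record sequences of capuchin monkey
detections. The scientific question is whether detection rates — used as a
proxy for activity — track the tidal cycle, and whether that tracking varies
with distance from the coast, between a stone-tool-using group and
non-tool-using groups, and between seasons. The tide regime is mixed
semidiurnal: two unequal low tides roughly every 12.5 h, so the tidal clock
advances ~1 h per day relative to the solar day and a fixed daily visiting
time cannot exploit the intertidal zone.

## Data preparation

* **Sequences.** Camera triggers less than 30 s apart (strict inequality)
  are chained into one sequence; the sequence count is the maximum
  simultaneous individual count across its triggers, the standard camera-trap
  convention that avoids double counting. Sequences with zero target animals
  are dropped — only positive counts are modelled, because a missing
  detection does not imply an absent animal.
* **Service days.** Sequences dated on a deployment's set-up or collection
  day are excluded (human presence disturbs behaviour). A sampling night is
  a deployment night excluding those two days.
* **Time to low tide.** Each sequence timestamp is converted to signed hours
  from the nearest low tide (negative before the low, positive after, range
  about −6.25 to +6.25 at a 12.5 h interval). A timestamp exactly midway
  between two lows goes to the earlier low — a deterministic tie-break for a
  measure-zero case. Timestamps are naive local time; the tide table and
  cameras share one clock.
* **Seasons.** December–April is dry, May–November wet (whole months).
* **z-transforms.** Time to low tide, distance to coast and hour of day are
  standardized (sample sd, n−1) on the final modelling table; the
  standardizers are stored so model output can be reported in hours and
  metres.

## The model

Counts are Poisson with log link (fitting plain Poisson to positive counts
reproduces the analysed study's choice; see *Zero truncation* below):

    log E[y_i] = b0 + b1 * index_i + f(t_i, d_i) + f_{g(i)}(t_i, d_i) + u_{cam(i)}

with a global tensor-product smooth `f` over (time-to-low-tide × distance)
— or (hour-of-day × distance) in the diurnal models — plus one deviation
smooth per level of the grouping factor (tool/nontool in MT_1, dry/wet in
MT_2/MT_3/MD_1/MD_2), the factor as a 0/1 index, and Gaussian camera random
intercepts.

* **Bases.** Both marginals use the value-at-knot parameterization of cubic
  regression splines with the exact integrated-squared-second-derivative
  penalty. Time to low tide is cyclic on ±L/2 where L is the tide table's
  mean low–low interval (the wrap is imposed on the raw-hours scale and maps
  affinely to the z-scale); hour of day is cyclic on [0, 24) by default
  since 23:00 adjoins 00:00; distance uses a natural (non-cyclic) basis with
  quantile knots and linear extension outside the knot range. `k = 8`
  coefficients per margin by default (configurable); each margin is
  sum-to-zero centered, so a tensor smooth carries (k−1)² = 49 columns. The
  tensor design is the row-wise Kronecker product of the centered marginals;
  consequently the fitted surface's average over the training rows is close
  to, but not exactly, zero (an exact tensor-level constraint would cost a
  further column; the marginal-centered bookkeeping was kept).
* **Priors.** Normal(0, 2) on intercept and index; Exponential(1) on every
  scale. Each tensor block gets one scale per penalty direction, so its
  prior precision is `S_t/σ_t² + S_d/σ_d²`; the two penalties commute
  (Kronecker pair), so this precision diagonalizes in one orthogonal basis,
  which makes the prior, its normalizer and all gradients cheap. Directions
  in a joint penalty null space (none, after centering, for the default
  bases) fall back to the Normal(0, 2) ridge. Deviation smooths have their
  own scales by default ("GI" flavour); a shared-scale ("GS") switch exists.
* **Sampling.** A No-U-Turn sampler (multinomial variant, dual-averaging
  step size, diagonal mass adaptation in windows) written against the
  analytic gradient of the joint density. Penalized blocks are sampled
  non-centered (whitened coordinates z with β = V·den^{−1/2}·z), which
  removes the scale–coefficient funnel that cripples centered hierarchical
  GAM sampling; draws are mapped back to model coefficients before
  reporting. Initialization is penalized IRLS at unit scales with per-chain
  jitter. Defaults mirror the reference analysis (3 chains × 4000
  iterations, 2000 warm-up); the scaled-down experiments below use 2 chains
  × (400 warm-up + 500 retained) — sampler settings, not study conditions.
  Convergence is declared at split-Rhat < 1.01 (arviz); non-convergence is
  flagged and warned, never hidden, and draws are still returned.
* **Checks.** Prior predictive simulation through the link (rates capped at
  1e6 for count simulation only) and posterior predictive checks on mean,
  s.d. and max with tail probabilities.

## Derivative reliability mapping

To locate where activity *changes* along the tide-distance surface, each
posterior draw's smooth is finite-differenced with the four-point stencil

    [f(t+h, d+k) − f(t+h, d−k) − f(t−h, d+k) + f(t−h, d−k)] / (4hk)

with offsets h = k = 0.001 on the z-scale (1/1000 of a standard deviation of
each predictor). The stencil is the mixed partial ∂²f/∂t∂d; the literature
applying it to fitted smooths calls the quantity "the first derivative" of
the tensor interaction — the naming discrepancy is noted, the formula is
implemented as printed. Each draw is differenced against itself only. A grid
cell is flagged *reliable* when ≥ 89% of draws share a sign (ties at exactly
zero count toward neither side); an equal-tail-interval variant would behave
identically at this threshold. Stencil exactness on polynomials of total
degree ≤ 2, O(eps²) truncation behaviour and agreement with analytic
tensor-smooth mixed partials are all tested.

Heatmaps colour the posterior-mean smooth (link scale, zero ≈ mean activity)
and saturate colour only in flagged cells; rug marks show the observation
density. Companion contour plots show the raw sign proportions with the
threshold contour.

## Synthetic studies and what they show

The generator plants a known log-rate surface:

    log λ = β0 + A · g(t) · exp(−d/ρ) · m_group · m_season + b_cam

with `g` a raised-cosine bump centered at low tide (half-width 3 h —
elevated coastal activity around the exposed intertidal window, echoing the
published pattern without copying fitted values), ρ = 150 m distance decay,
and lognormal camera heterogeneity (σ_cam = 0.7). Counts are zero-truncated
Poisson — a sequence exists only if at least one animal is present. Defaults
are a scaled-down desk campaign: 40 cameras over 120 days at 1.1 sequences
per camera-day (the field study's empirical per-camera-night sequence rate),
β0 = log(1.594) − σ²/2 so the marginal zero-truncated mean is ≈ 2 with s.d.
≈ 1.4, near the field moments. Cameras are spaced as truncated-exponential
quantiles over 0–470 m (scale 150 m), matching the field design's dense
coastal sampling and sparse inland grids. The analytic mixed partial
A·g′(t)·(−1/ρ)·e^(−d/ρ) is carried as ground truth; its "nonzero region" is
defined by a floor of 10% of the field's maximum absolute value.

**Zero truncation vs plain Poisson.** The generator truncates; the model does
not — deliberately mirroring the analysed study's exclusion of zeros. The
fitted log-mean surface is then an attenuated, monotone transform of the
planted one (local slope ≈ 0.59 at these rates). Recovery assertions
therefore target shape and derivative *sign*, which survive the mismatch,
not absolute levels. In scaled-down recovery runs the posterior-mean
derivative correlates with truth at ≈ 0.96 in the strong-signal cells with
the predicted attenuation; flagged cells agree with the true sign
essentially always. The flagged region itself is conservative: the full
posterior of the mixed partial under Exponential(1) scale priors is
substantially wider than a plug-in (REML-style) Gaussian approximation, so
at this n the 89% criterion flags only the strongest core of the true
region. Null campaigns (A = 0) flag essentially nothing — the criterion's
false-positive behaviour is the property the threshold is designed for.

What the synthetic studies do *not* emulate: species misidentification,
camera failure, within-day detection autocorrelation, real island geography,
and real tide-height variation (timing only). Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated sampling design, not field-data fidelity.

## Numerical choices and edge cases

* Cyclic basis evaluation reduces x modulo the period (a circle has no
  outside); construction-time data must lie in the stated domain. The
  non-cyclic basis extends linearly outside its knots, so the derivative
  stencil can evaluate at hull edges.
* Quantile knots fall back to uniform knots under heavy ties.
* The Poisson log density returns −inf on overflow (the sampler treats the
  proposal as divergent); scale parameters are sampled on the log scale with
  |log σ| > 20 rejected.
* Exact midpoint ties in the tide clock go to the earlier low; exact zeros
  in derivative draws count toward neither sign.
* Grid queries beyond 1.05× the observed distance hull warn (extrapolation).
* Tide tables with low–low gaps outside [11, 14] h warn; gaps above 24 h are
  errors (a missing tide).

## Known limitations

* Random camera intercepts and the global intercept are identified only
  through their priors (no hard sum-to-zero on camera effects).
* The global + per-level deviation decomposition is itself only softly
  identified; level-specific *sums* (what the figures show) are the
  well-identified quantities.
* The sampler is plain NUTS with a diagonal mass matrix; strongly correlated
  posteriors (very small k, tiny n) mix slowly, and Rhat is reported for
  every parameter so such runs are visible.
* LOO/Pareto-k diagnostics are not implemented; posterior predictive checks
  are the supported fit assessment.
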