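# tidegam

Hierarchical Bayesian Poisson GAMs for camera-trap detection counts over the
tidal cycle and distance to coast, with finite-difference reliability mapping
of the fitted activity surfaces.

## What this is for

Field studies of coastal wildlife — here, white-faced capuchins on a tidal
island, including a stone-tool-using group that forages in the intertidal
zone — ask whether detection rates track the tides, and whether that
tracking changes with distance from the coast, between groups, or between
seasons. In a mixed semidiurnal regime (two unequal low tides every ~12.5 h)
the tidal clock drifts ~1 h/day against the solar day, so tidal and diurnal
rhythms are separable. `tidegam` turns raw camera-trap trigger tables, a
deployment table and a tide table into per-sequence counts with covariates,
fits hierarchical Poisson GAMs, and maps where the fitted surface changes
*reliably*.

The model for the count `y_i` of animals in detection sequence `i` is

    y_i ~ Poisson(λ_i)
    log λ_i = β0 + β1 x_i + f(t_i, d_i) + f_g(i)(t_i, d_i) + u_cam(i)

where `t` is z-scored time to nearest low tide (cyclic cubic spline margin) —
or hour of day in the diurnal variants — `d` is z-scored distance to the
coastal vegetation boundary (cubic regression spline margin), `f` is a global
tensor-product smooth, `f_g` are per-level deviation smooths (tool/nontool
or dry/wet season), `x` the level index, and `u_cam` Gaussian camera random
intercepts. Priors are Normal(0, 2) on unpenalized coefficients and
Exponential(1) on all scales; posteriors come from a built-in No-U-Turn
sampler with analytic gradients.

To locate change, each posterior draw of the surface is finite-differenced
with the four-point stencil

    f_td(t, d) ≈ [f(t+h, d+k) − f(t+h, d−k) − f(t−h, d+k) + f(t−h, d−k)] / (4hk)

at offsets h = k = 0.001 (1/1000 s.d. of each z-scored predictor). A grid
cell is flagged reliable when ≥ 89% of posterior draws of this derivative
share one sign; heatmaps saturate colour only there.

A synthetic-data module generates complete campaigns (tide schedule,
deployments, triggers) from a planted log-rate surface with known analytic
mixed partial, for end-to-end recovery testing.

## Worked example

```python
import numpy as np
from tidegam import (SyntheticConfig, simulate_study, assemble_sequences,
                     filter_service_days, build_model_table, ModelSpec,
                     assemble_design, fit, derivative_field,
                     reliability_mask, Grid2D)

cfg = SyntheticConfig(seed=1, n_cameras=12, n_days=40)
triggers, deployments, tides, truth = simulate_study(cfg)
sequences = filter_service_days(assemble_sequences(triggers), deployments)
table = build_model_table(sequences, deployments, tides)
print(f"{len(table)} sequences, mean count {table.data['count'].mean():.2f}, "
      f"sd {table.data['count'].std(ddof=1):.2f}")

design = assemble_design(table, ModelSpec("MT_1"))
result = fit(design, chains=2, iterations=700, warmup=400, seed=1,
             max_treedepth=8)
print(f"max Rhat {result.max_rhat():.3f}")

grid = Grid2D.regular(design.t_domain, design.d_range, 30, 30)
field = derivative_field(result, grid, level="tool")
mask = reliability_mask(field, 0.89)
print(f"flagged cells: {int(mask.flagged.sum())} of {grid.n_cells}")
strongest = np.argmax(np.abs(field.mean))
t_h = table.t_std.inverse(grid.points()[strongest, 0])
d_m = table.d_std.inverse(grid.points()[strongest, 1])
print(f"strongest mean derivative {field.mean[strongest]:+.2f} at "
      f"{t_h:+.1f} h from low tide, {d_m:.0f} m from coast "
      f"(P(>0) = {field.prop_pos[strongest]:.2f})")
```

Output:

```
493 sequences, mean count 2.10, sd 1.23
max Rhat 1.019
flagged cells: 0 of 900
strongest mean derivative +0.38 at +3.2 h from low tide, 0 m from coast (P(>0) = 0.66)
```

Read: the small campaign's counts average ~2 animals per sequence; the
largest estimated rate of change of (log) activity sits right at the coast a
few hours after low tide and is positive in 66% of posterior draws — real
structure, but at 493 sequences no cell clears the conservative 89%
criterion, so nothing would be rendered as saturated. Larger campaigns (the
default `SyntheticConfig()` is 40 cameras × 120 days) begin to flag the
strongest coastal cells.

The same pipeline runs from the shell on CSV inputs or a synthetic config:

```
tidegam run --config config.yaml --out artifacts/ --seed 1 --model MT_1 \
            --grid 50x50 --chains 3 --iter 4000 --warmup 2000
```

writing the model table, the fit archive (draws, diagnostics), per-level
derivative CSVs, heatmaps with saturation masks, sign-proportion contour
plots, and a run log. `simulate`, `prepare`, `fit`, `derive` and `report`
expose the individual stages.

## Layout

    src/tidegam/tide_clock.py        tide tables, time-to-nearest-low-tide
    src/tidegam/detections.py        sequences, filters, covariates, z-transforms
    src/tidegam/gam_engine/          spline bases, model assembly, NUTS, predictive checks
    src/tidegam/smooth_derivative.py four-point stencil, sign proportions, 89% mask
    src/tidegam/synthetic_data.py    campaign generator with analytic ground truth
    src/tidegam/reporting.py         heatmaps, contours, pipeline driver
    src/tidegam/cli.py               command-line interface
    docs/methods.md                  modelling and design notes
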