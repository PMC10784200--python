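# Methods

## Problem and scope

The package estimates how staple-crop yields respond to the sudden loss
of industrial agricultural inputs.  It couples three components: a
statistical yield response fitted to gridded baseline data, a scenario
layer that rewrites the per-cell input table for the first year after
the catastrophe (phase 1) and for the years after stocks are exhausted
(phase 2), and an aggregation layer producing production-weighted loss
summaries by crop, phase and region.  A synthetic-landscape generator
with known ground truth makes every stage testable without the
multi-gigabyte global source products.

## Data model

All stages exchange one structure: a long-format table with one row per
(5-arcmin grid cell, crop), carrying yield (kg ha⁻¹), harvested area
(ha), N fertilizer and manure rates (kg ha⁻¹), cumulated pesticide rate
(kg ha⁻¹), irrigated fraction and the fraction of irrigation reliant on
powered pumps (both 0–1), a 0/1 machinery indicator, and thermal /
moisture / soil class codes.  Grids are cell-center registered, rows
north→south, columns west→east; `cell_id` is the row-major index.  This
ordering is fixed deliberately: the forward-fill step of preprocessing
is order-dependent, so the traversal order is part of the method.

Raster layers are read from CSV (`cell_id,value`), plain TIFF arrays,
or NetCDF.  Layers on coarser grids are aligned by nearest-neighbour
assignment (each target cell takes the value of the source cell
containing its center).  Nearest assignment is used for rate layers as
well as categorical ones because the rates are intensive, per-hectare
quantities; nothing is conserved by resampling, by design.  The tillage
layer's six management systems collapse to a binary machinery
indicator; the two draft-power ("traditional") systems map to 0 and the
rest — including conservation agriculture, which is practiced almost
exclusively on motorized farms — to 1.

## Yield response

Per crop, yield is modelled as Gamma(shape, scale) with mean
μ = shape·scale and natural-log link, ln μ linear in the predictors
with no interactions.  Yields are non-negative and strongly
right-skewed, which rules out ordinary least squares on the raw scale;
the gamma family with log link is the standard choice for such data.
Categorical classes are dummy-coded against the lowest-ordered level
(T1, M2, S1); when a calibration subset happens to lack the reference
level, the lowest observed level stands in.  Estimation is IRLS via
statsmodels; the dispersion φ is the Pearson χ²/df of the calibration
fit, the implied shape is 1/φ, and the per-observation scale μ·φ
satisfies μ = shape·scale row-wise.

Fit quality is judged on a held-out 20% split (seeded, default seed
20100) with McFadden's ρ² = 1 − lnL_model/lnL_null.  Both
log-likelihoods are evaluated on the validation rows using the
calibration dispersion, with the null an intercept-only gamma GLM
fitted on the calibration split.  Refitting the null on the validation
rows would be an equally defensible convention; the one implemented
keeps validation strictly out-of-sample for both likelihoods.
Validation rows whose class levels never occurred in calibration are
excluded from the likelihood and reported.

Per-factor influence is summarised by predicting at the factor's
observed minimum and maximum with everything else held constant and
expressing the difference as a percentage of the maximum-input
prediction.  Under the log link with no interactions this equals
exp(β_j(x_min − x_max)) − 1 and is independent of the held-constant
values — a property the tests verify directly.  Multi-level categorical
factors have no min/max axis and are excluded.

Multicollinearity is screened with the generalized variance inflation
factor, GVIF_j = det(R_jj)·det(R_(−j)(−j))/det(R) over the correlation
matrix of the dummy-coded design.  Predictors are compared on the
GVIF^(1/(2·Df)) scale; its square reduces to the ordinary VIF for
single-column predictors, so the conventional alarm thresholds (5, 10)
apply to the squared value.  Singular designs yield infinite GVIFs with
flags rather than an exception.

## Preprocessing ledger

Operations run per crop, in a fixed order, each appending a row with
telescoping counts to a cleaning report:

1. **Area filter** — rows with harvested area strictly below 100 ha are
   dropped; 100 ha exactly is retained.  The report records the dropped
   rows' share of total production (Σ yield·area), the quantity that
   justifies the filter: many cells, little food.
2. **Missing data** — rows missing pesticides or mechanization are
   dropped (no defensible covariate model exists for imputing them);
   missing N fertilizer and class codes are forward-filled in cell-id
   order within each crop, and leading gaps are dropped.  A column
   entirely missing for a crop is an error, not a silent drop.
3. **Outlier trims** — values strictly above the per-crop 99.9th
   percentile of N fertilizer, pesticides and yield and the 99th
   percentile of manure are removed.  Percentiles use linear
   interpolation between order statistics; values exactly at the
   threshold are retained; thresholds are recorded in the report.
4. **N merge** — `n_total = n_fert + n_manure`, computed after the
   source-column trims so data errors are caught before blending, then
   itself trimmed at the 99.9th percentile.
5. **Class merge** — the three coldest thermal regimes pool into T7,
   and the moisture extremes into M2 (growing period < 120 d) and M6
   (270+ d), against sparse-class instability.  The same merge applies
   to every crop for comparability, even where a crop-specific merge
   would fit better.

## Scenario construction

Constants default to published global figures: projected 2020 N use
for crop fertilization T_NG = 118 763 kt, projected 2020 N surplus
T_NG1 = 14 477 kt, agricultural fuel demand 111 062 ktoe yr⁻¹ (2018),
above-ground fuel stocks 319 000 ktoe (172 000 gasoline, 147 000
diesel), cattle excretion 39.77 kg N head⁻¹ yr⁻¹ (derivable as
131 000 kt N × 0.437 / 1.44·10⁹ head ≈ 40), and a conservative draft
working capacity of 5 ha head⁻¹ (7.4 is a typical figure; modern
cattle are not bred to work).

Phase-1 fertilizer follows the three-step reallocation — each cell's
share of the global applied total, a new global pool scaled by
T_NG1/T_NG, and reallocation of the pool by share — which collapses
algebraically to uniform scaling of every rate by the surplus ratio.
Both routes are computed and asserted equal to machine precision on
every call; the returned values use the direct scaling, which is exact
in the ratio-1 limit.  Pesticides use the same construction with the
same surplus ratio (no pesticide surplus statistics exist; the share is
assumed comparable, ≈10%): the global pesticide total enters the pool
formula once in the numerator and once in the denominator and cancels,
so its numeric value is never needed.  Diesel stocks cover
147 000/111 062 ≈ 1.32 years of demand, so phase-1 machinery stays at
baseline; with user-supplied figures below one year of coverage the
pipeline zeroes mechanization and logs the departure.  Draft-cattle
manure, identical in both phases, is C = A/ha_per_head head per cell
and M = excretion·C/A — a constant excretion/ha_per_head ≈ 7.95
kg N ha⁻¹ (the simplified constant form is used so the rate is
bit-identical across cells).  Irrigation, also phase-invariant, drops
to I_AC(1 − I_RC).  Phase 2 zeroes fertilizer, pesticides and
machinery; manure is the sole N source.

## Prediction and aggregation

Per (cell, crop, phase) the fitted response surface is evaluated on
the scenario inputs and the relative change RC = (Y_pred − Y_base)/Y_base
is clipped at zero from above: predicted increases are read as "yield
stable", not gains.  Cells outside model support (unseen class levels)
get missing predictions, are excluded from weighted means, and are
counted.  Summaries per crop × phase × region plus a global rollup
weight mean yields by harvested area and mean RC by baseline
production.  Confidence intervals for the weighted means use a normal
approximation with effective sample size n_eff = (Σw)²/Σw², treating
the weights as known constants; no convention for these intervals is
canonical, and this one is recorded so results are auditable.

Two RC baselines exist.  The headline definition divides by the
recorded baseline yield.  For pipeline diagnostics the denominator can
instead be the model's own prediction under baseline inputs
(`baseline_mode="modeled"`), which isolates the scenario effect from
model error: in the identity limit (surplus ratio 1, no pump reliance,
machinery unchanged, baseline manure at the draft-cattle rate) the
scenario inputs equal the baseline inputs and RC is identically zero —
a property that cannot hold against observed yields, since the model
never reproduces them exactly.

## Synthetic landscapes

The generator emulates the joint structure the pipeline assumes in real
gridded products: gamma-distributed yields (shape 2.0, giving the
strong right-skew seen in per-cell yield data) responding log-linearly
to inputs through known per-crop coefficients; log-normal input rates
(medians ≈50 kg N ha⁻¹ fertilizer, 15 manure, 1 kg ha⁻¹ pesticides);
beta-distributed irrigation fractions; blocky class mosaics (one draw
per coarse block, block edges 8/6/5 cells for thermal/moisture/soil —
distinct sizes so the three mosaics cannot alias into a rank-deficient
dummy design); harvested areas log-normal around 150 ha with σ = 2, so
roughly 40% of cells fall under the 100-ha filter, mirroring the heavy
small-cell tail of real allocations; continent bands by longitude.
Rare cold thermal and extreme moisture classes get small but positive
probabilities so the class-merge step has work to do.

Corruption is injected after the yields are drawn, so it behaves as
data error rather than signal: multiplicative ×10–100 spikes in the
rate columns (rate 0.002) emulate the implausible values the trim
step removes, and missingness (15% pesticides, 10% mechanization,
~2% fertilizer and classes) mirrors the relative coverage of real
pesticide/tillage products.  One independent random stream per column,
all spawned from the master seed, makes the columns orthogonal in the
pseudorandom sense: toggling missingness cannot change the yields.

What the generator does not emulate: spatial autocorrelation beyond
blocky classes, measurement error structure in yields, cross-cell
correlation of input rates, or any real-world geography.  Passing tests
therefore demonstrate the pipeline's internal correctness and the
statistical behaviour of its estimators under the assumed model — not
that real-data headline numbers would be reproduced.  Matching
published global results requires the actual source products, which
are out of scope here.

## Numerical choices and degenerate inputs

- Percentile definition: linear interpolation (numpy default), recorded
  per threshold in the cleaning report.
- Splits: `round(0.8·n)` calibration rows, clamped so both sides are
  non-empty; tables under 5 rows refuse to split.
- An exactly constant response puts the gamma deviance at a 0/0 corner
  of the IRLS implementation and is rejected upstream by validation
  (strictly positive response is required; degenerate validation sets
  warn).
- Rank-deficient designs report the offending columns (pivoted QR)
  instead of producing unstable estimates.
- GVIF on singular correlation matrices returns infinities with flags.
- Reallocation with a zero global applied total and nonzero rates is an
  error; an all-zero rate column reallocates to zeros.

## Problem sizes used in the tests

The default test suite runs on landscapes of 900–3 600 cells per crop;
the coefficient-recovery study uses 20 replicates of ≈20 000-cell
single-crop landscapes with corruption switched off, checking that the
95% confidence intervals cover the true coefficients at their nominal
rate (the aggregate coverage over all coefficient × replicate pairs
must reach 90%; joint all-coefficient coverage per replicate is not a
meaningful target for ~19 simultaneous 95% intervals).

## Known limitations

- The yield response is associational: coefficients fitted to
  cross-sectional intensity gradients are applied to a counterfactual
  input withdrawal, assuming the cross-section transfers to the shock.
- No adaptation dynamics: cropland extent, crop choice, labor
  reallocation, trade and storage drawdown are all fixed.
- Livestock accounting is a static head-count conversion; no herd
  dynamics or slaughter timeline.
- The irrigation-reliance fraction is treated as exact per cell, though
  in real sources it derives from country-level statistics.
- Forward-filling class codes and fertilizer rates assumes spatial
  continuity along the row-major order; a different traversal order
  would fill different values.
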