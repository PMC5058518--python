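# Methods

`borealrange` reconstructs, attributes and projects decadal changes in a
species' predicted range from a fixed logistic species distribution model
(SDM). The reference system is a boreal ungulate expanding northward under
easing winters, lengthening growing seasons and industrial land-use growth;
everything below is phrased for that system but parameterised, so other
systems with the same data shapes fit.

## The model

Presence probability in a grid cell is

```
logit p = β0 + β1·deciduous + β2·wetland + β3·footprint + β4·WSI + β5·GS
```

with default coefficients β = (−10.12, 4.98, −3.11, 9.79, −0.07, 0.11).
These are treated as *configuration*, not as something the pipeline refits:
hindcasting and forecasting apply them unchanged, which assumes the
species–environment relationship is stationary across decades. Refitting
exists only in the validation module, for parameter-recovery and calibration
experiments on synthetic data.

Covariates, per cell and decade:

- `deciduous`, `wetland` — proportions of the cell in deciduous forest and
  wetland cover, in [0, 1].
- `footprint` — total developed proportion (wells + cut blocks +
  agriculture), in [0, 1].
- `WSI` — mean annual winter severity index (index points) from a base year
  (default 1961) through the decade start.
- `GS` — mean annual growing-season length (days) from a base year (default
  1950) through the decade start.

Probabilities are converted to presence with an inclusive threshold
(p ≥ 0.73 by default, the training-data prevalence 218/299 rounded for
display; the operation itself keeps full precision).

## Climate indices

**Winter severity index (WSI).** Count of days in the Nov 1 – Apr 30 window
(spanning the year boundary; a winter is labelled by its November year) with
minimum temperature strictly below −17.7 °C and/or snow depth strictly
above 38 cm. A day meeting both criteria counts once; the upper bound is
therefore the window length, 181 or 182 days depending on the leap status of
the spring. The snow criterion operates on snow depth in cm as supplied by
the data layer; if only snow-water-equivalent is available, the conversion
(and any adjusted threshold) is the responsibility of input preparation —
the threshold is configurable for that reason.

**Growing-season length.** The season starts on the first day of the first
run of ≥5 consecutive days with mean temperature ≥ 5 °C, searched from
March 1; it ends on the first day strictly after August 1 with minimum
temperature ≤ −2 °C, or December 31 if no such frost occurs. Length is
end − start in whole days (end exclusive), floored at 0 — including the
degenerate case where the first qualifying run begins only after the first
frost. These start/end conventions are choices where the verbal definition
is silent; they are documented here and configurable
(`t_start_c`, `run_days`, `t_end_c`).

Missing days inside a required window are an error that lists the gaps —
never silently imputed.

**Cumulative means and trends.** Decadal climate covariates are arithmetic
means of the annual indices from the base year through the decade start,
both endpoints inclusive ("decade d" covers calendar years [d, d+9]).
Per-cell trends are ordinary least squares of annual value on calendar year
(≥3 years required), kept as slope/intercept/reference-year triplets.
Extrapolated WSI is floored at 0; extrapolated growing season is floored at
0 and capped at 366 days.

## Decadal landscapes

The land-use snapshot for decade d is taken at the decade end (d+9). Which
endpoint the snapshot uses is genuinely open; decade end is the default and
the choice is isolated in one function.

- **Well pads** accumulate indefinitely (no reclamation assumption); each
  pad contributes a 100 m² clearing by default (configurable).
- **Cut blocks** contribute only while the regrowth is young enough to be
  browse: cuts with year ≥ d − 30 (anchored at the decade *start*, so the
  2000s exclude pre-1970 cuts, with 1970 itself included) through the decade
  end. Records without a cut year — about 30 % in real inventories — are
  included by default (`include_undated_cuts`), giving the maximum-footprint
  reading; excluding them is monotone downward.
- **Agriculture** persists once developed: a decade's agricultural footprint
  is the union of all epochs dated at or before the decade end.

Per-cell layer areas are capped at the cell area before and after summation;
the cap stands in for the geometric union of overlapping polygons, which a
desk-scale pipeline cannot compute without the original geometries.

**Land-cover reconciliation.** Where footprint + deciduous + wetland
exceeds 1 (a real artifact of mixed-resolution source layers), the excess is
subtracted from the two cover classes in proportion to their coverage and
the results floored at 0. This conserves: footprint + adjusted cover =
min(1, original sum), and means development functionally erases cover.

## Counterfactual attribution

For a decade pair (prev, curr), two counterfactual landscapes are formed:
climate frozen at prev with current land use/cover, and land use/cover
frozen at prev with current climate. With p() the model probability,

```
Δclimate  = p(curr) − p(climate frozen at prev)
Δland_use = p(curr) − p(land use frozen at prev)
```

and the cell's driver is the factor with the larger |Δ|; `none` when both
are exactly zero. Because the model is nonlinear in its covariates,
Δclimate + Δland_use need not equal the actual change p(curr) − p(prev);
all three are reported so the non-additivity stays visible. Exact ties with
nonzero deltas (measure zero on continuous inputs) are labelled `climate`
deterministically and counted separately. Cells whose presence
classification flips carry the crossing direction (gains *and* losses,
though only gains matter for an expansion narrative) and the crossing
driver. Summaries tally drivers over cells with increased probability
(cell counts, which equal area shares on an equal-area grid) and over
crossings; empty denominators are flagged, not divided through.

When exactly one factor changed, the other factor's counterfactual equals
the current landscape, its Δ is identically zero, and every changed cell is
labelled with the changed factor — the module's strongest exact guarantee,
and the core acceptance property.

## Validation

- **Confusion counts** use the same inclusive threshold rule as
  classification. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); a
  missing class yields NaN with a flag rather than an exception.
- **TSS** = sensitivity + specificity − 1, by construction.
- **AUC** is the rank-based (Mann–Whitney) probability that a random
  presence outscores a random absence, ties counting ½; computed via
  scikit-learn and cross-checked in tests against brute-force pair counting.
- **Calibration** regresses observed outcome on predicted probability with
  a binomial-logit GLM. The regressor is the *raw probability* by default
  (the logit-scale variant is available via `regressor="logit"`). Note the
  raw-probability family cannot represent the identity curve exactly: on
  perfectly self-consistent data its large-sample best fit has slope ≈ 4.88
  and intercept ≈ −2.44 (for probabilities spread uniformly on
  (0.05, 0.95)) and deviates from the identity by up to ≈ 0.027 on
  [0.1, 0.9]. The logit-scale variant does contain the identity and
  recovers slope 1/intercept 0 on the same data. Constant regressors are
  flagged `degenerate`; perfectly separating ones are flagged `separation`
  with unbounded coefficients.
- **Bootstrap SDs** for sensitivity/specificity use a seeded nonparametric
  bootstrap (1,000 replicates by default); replicates missing a class
  contribute NaN and are excluded from that rate's spread. The choice of a
  bootstrap is ours — the accuracy-table SD columns in the source material
  state no method — and it is testable against the binomial approximation
  sqrt(r(1−r)/n).
- **Township aggregation** reduces survey records to township-year
  presences: any detection scores the township, and presence is sticky
  across later years (later absences are treated as false absences).

## Forecasting

Land use and land cover are frozen at the base decade. For a future decade
d, each climate covariate is the cumulative mean from its base year through
d, built from observed annual values where the record covers them and from
the per-cell trend line (floored/capped at physical bounds) beyond — the
"blended" convention, mirroring the hindcast's cumulative-mean definition.
Two consequences used as consistency checks: forecasting the base decade
itself reproduces the hindcast exactly (only observed years enter), and a
zero-slope trend fitted to a constant history leaves every future mean — and
hence every probability — exactly equal to the base decade's. Range change
between presence layers is reported as area gained (absent→present) and
lost (present→absent) in km².

## Synthetic data

The generator provides inputs with the statistical structure the analysis
assumes, not a meteorological simulation. Daily weather is constructed
winter-by-winter and season-by-season so the index definitions hold exactly:

- Each winter receives a contiguous severe block centred mid-window whose
  length is the annual WSI target: per-cell baseline + trend·(year −
  start) + Gaussian interannual noise, rounded and clipped to the window.
  Block days have tmin ≈ −25 °C (kept strictly below −17.7), and a central
  sub-block (60 % of the block by default) carries snow ≈ 55 cm (strictly
  above 38), so both criteria fire and overlap; outside the block, baseline
  winter weather (tmin ≈ −6 °C, snow ≤ 37 cm) never qualifies.
- Each growing season starts May 1 and ends with a first frost placed
  start + target days later (target = baseline + trend·year + noise, clipped
  to [100, ~181] so the frost lands after Aug 1 and before Nov 1); shoulder
  seasons are held below the 5 °C onset and above the −2 °C frost.

Defaults are the study conditions: per-cell WSI baseline 120 index points
(spatially smoothed, sd 10) and growing season 164 days — the training-data
covariate means — with trends −1.2 index points/yr and +0.15 days/yr,
inside the per-cell ranges reported for the real region (−2.248…−0.155 and
−0.059…+0.375), interannual noise sd 8 index points and 4 days, daily noise
sd 1.5 °C, over 1961–2009 on 10 km² cells. Trends accept per-cell fields.

Land use grows as Poisson event streams (wells 3/yr at 100 m², cuts 2/yr at
0.5 km², 30 % of cuts undated) placed near fixed cluster nuclei with
probability `clustering` (0.8) or uniformly otherwise; agriculture arrives
as southern-row epoch masks (fractions of the grid at epoch years) that
persist. Land cover is a smoothed random field (deciduous mean 0.24, max
0.9) plus exponential wetland (mean 0.02, max 0.13). Observations are
Bernoulli(p × detection) at cells sampled without replacement.

What the generator does *not* emulate: spatial autocorrelation of daily
weather between cells (anomalies are independent), precipitation phase,
elevation effects, observation processes beyond thinning (no false
positives), and polygon geometry (areas are scalar per cell). Tests passing
on this generator therefore certify the pipeline's arithmetic and logic —
index definitions, compositing rules, attribution exactness, statistical
identities — not the realism of any particular regional dataset.

## Numerical choices and conventions

- Grids are row-major with origin at the northwest corner; rasters are
  written as delimited matrices with a JSON sidecar (rows, cols, cell area,
  origin), a bit-stable dialect with no geospatial dependencies.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixed per-purpose stream constants keep climate, land use, land
  cover and observations independently reproducible. Same seed + config ⇒
  bit-identical outputs, including written files.
- Strict inequalities for the WSI thresholds and inclusive ones for the
  5 °C onset and presence threshold follow the verbal definitions.
- GLM fits use statsmodels IRLS (tol 1e−10); convergence additionally
  requires score-gradient norm < 1e−6. Rank-deficient designs and
  single-class responses are rejected up front; separation is detected
  before fitting for the single-regressor calibration and flagged from
  warnings/magnitudes otherwise.
- `logit(expit(x)) = x` holds only to ~8·eps·e^|x| in float64 (probabilities
  near 1 lose logit information); tests assert that error model rather than
  a flat tolerance.
- Test and demonstration problem sizes: grids of 40–1,000 cells, daily
  records of 20–50 years, 100-replicate recovery experiments at n = 5,000,
  calibration at n = 10,000. These sizes make every property sharp while
  keeping the full suite under a minute.

## Known limitations

- Attribution inherits the subtraction scheme's non-additivity; driver
  labels near |Δclimate| ≈ |Δland_use| are sensitive to covariate noise.
- The raw-probability calibration regression is a misspecified family for
  self-consistent data (see above); use the logit variant when the question
  is "does calibration recover the identity".
- Freezing land use at the base decade makes forecasts conservative where
  development would continue; the linear-trend assumption for climate is
  only defensible over a few decades.
- The cell-area cap is an upper bound for true footprint union when layers
  overlap within a cell.
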