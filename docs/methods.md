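# Methods

## The model

The pipeline treats climate-lag detection as a variable-selection
problem. For each sampling location there are twelve candidate
descriptions of climate: eleven 10-year climatologies (decades ending
December 31 of 1959 through 2009, overlapping by five years) and a
1-year contemporary climatology of the collection year. Each
climatology summarises ten monthly variables (mean/min/max temperature,
diurnal range, precipitation, wet-day and frost-day frequency, vapour
pressure, cloud cover, potential evapotranspiration). A single PCA is
fitted with every (location, window) combination as an observation and
the ten variables as columns, centred and scaled (sample standard
deviation, n−1) before the SVD; the first three components — which in
both regions of interest load mainly on temperature mean, precipitation
and temperature range — replace the ten raw variables so that
exhaustive subset search stays feasible (36 candidates instead of 120).

Responses are modelled linearly on a transformed scale: natural log for
richness and Shannon diversity (and soil properties are used
untransformed), empirical logit for relative abundances,
x′ = (x·(n−1)+0.5)/n applied to all values whenever any proportion sits
on the boundary. Linearity is a deliberate guard against overfitting;
no interactions or smooth terms are considered.

### Subset search and its loss

Every subset of candidates up to `max_size` (default 5) is fitted by
OLS and scored by leave-one-out mean squared prediction error, computed
with the hat-matrix identity e₍ᵢ₎ = eᵢ/(1−hᵢᵢ), which is exact: tests
verify agreement with n explicit refits to 1e−10. The intercept-only
model competes as a null; its LOO error has the closed form
mean(((yᵢ−ȳ)·n/(n−1))²). Ties are broken deterministically — fewer
predictors first, then the lexicographically smallest candidate tuple,
candidates being ordered oldest window first and lowest component
first. Subsets whose normal equations are singular (or whose leverages
reach 1) are treated as inadmissible rather than patched with a
pseudoinverse. The enumeration is evaluated in batched chunks over the
Gram matrix, capped at about 64 MB of temporaries per chunk.

`max_size = 5` is a package choice: the procedure itself never needs a
cap, but exhaustive search over 36 candidates is only desk-scale with
one (≈4.4×10⁵ subsets), and five matches the width of the
top-variable screen in the robustness route.

### LMG importance

Within the winning model, importance is the Lindeman–Merenda–Gold
statistic, computed through the subset-weighting identity

LMGⱼ = Σ_{S ⊆ P∖{j}} |S|!(p−|S|−1)!/p! · (R²(S∪{j}) − R²(S)),

with all 2^p subset R² values cached. For p ≤ 6 the implementation is
tested to 1e−12 against direct averaging over all p! orderings (subset
R² from an independent OLS), and Σⱼ LMGⱼ = R² is asserted to 1e−10 on
every fitted model.

### Lag summaries

A response is "associated with climate from year Y" when its winning
model contains a predictor whose window covers Y (contemporary = the
collection year). Across responses, the selection frequency of each
window is the lag signature; each response also gets an
earliest-selected-window label. Because consecutive decades share five
years, adjacent windows are strongly correlated and earliest-window
labels are intrinsically fuzzy at one-window resolution; concordance
between the PC route and the raw-variable robustness route is therefore
assessed at the level of the conclusion (historic pre-1980 association
or not), where it is near-perfect on synthetic data.

### Two-step robustness route

With raw variables the pool has 120 candidates and exhaustive search is
impractical. Step 1 ranks the ten variables by their best univariate
LOO error restricted to the 1960–1969 and contemporary windows and
keeps the top ~5; step 2 runs the full subset search for those
variables across all twelve windows. The step-1 ranking statistic is an
interpretation (univariate LOO R²); nothing in the procedure pins it
down further.

### Equilibration forecast

Equilibrium predictions re-evaluate each historical-window predictor at
the same component's score in the most recent decadal window of the
schedule (2000–2009 under the default; configurable, since a
2002–2011-style window ending at the collection year can be scheduled
instead). Contemporary 1-year predictors are left unchanged by default
— equilibrium means responding to today's climate wherever the
community previously responded to old climate — with a switch to
substitute them as well. Shifts are differences between equilibrium and
current *predictions*, never observations, avoiding the spurious
correlation between residuals and observed values; percent change uses
the predicted current value as denominator, on the back-transformed
scale. Summaries report: the fraction of locations increasing, mean and
standard error (sd/√n) of percent change, the Pearson correlation of
shift with current level, and intersample variability before vs after —
pairwise percent differences 100·(vᵢ−vⱼ)/vⱼ over ordered pairs, whose
distribution is permutation-invariant, compared with the within-sample
percent shifts. Site-level aggregation (mean of three plots before
summarising) is available.

### MESS screening

Geographic projection evaluates the model at every grid cell (per-cell
climatologies, projected through the stored PC model). Extrapolation is
screened with MESS: per variable, with f the percent of reference
values strictly below the query (ties count as not-below, a documented
convention),

- f = 0: 100·(q−min)/(max−min)
- 0 < f ≤ 50: 2f
- 50 < f < 100: 2(100−f)
- f = 100: 100·(max−q)/(max−min)

and the MESS value is the minimum over variables — negative exactly
when the cell lies outside the training range on some variable. Cells
below a threshold (default −20, i.e. more than 20% of the range out of
bounds) can be flagged; values are marked, never removed, and masking
is off by default.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, not any
particular region. Monthly values per variable are
base + latitudinal/longitudinal gradient + trend + seasonal cosine +
iid Gaussian noise; trends are linear or linear-then-flat (breakpoint
year configurable), matching series that trend consistently or level
off. Defaults describe a cold high-plateau: e.g. mean temperature base
−2 °C, +0.03 °C/yr, seasonal amplitude 10 °C, noise sd 1.2 °C;
precipitation 40 mm/month saturating at 1990. The sampling design is 60
sites × 3 plots = 180 samples, plots jittered within one 0.5° cell;
collection year 2011; OTU tables are one multinomial of size 3000 per
sample (the analysis rarefaction depth, so rarefaction is a no-op on
them; deeper tables exercise true subsampling), with expected
proportions softmax-linear in PC scores of a *known* window and/or soil
properties.

Identifiability of the lag window rests on windows being spatially
distinguishable. In the generator, decadal climatologies differ across
windows through averaged weather noise (sd/√120 per cell), while the
shared spatial base field makes them collinear. The `trend_to_noise`
knob scales the deterministic structure against the noise: the default
1.0 is the realistic, collinear regime; recovery experiments use 0.3
(the "well-separated" regime). Signal taxa use coefficient 0.8 on PC1
of the 1960–1969 window over a background of 25 flat taxa, keeping the
logit of relative abundance approximately linear in the predictor.

What the generator does *not* emulate: spatially correlated weather,
temporal autocorrelation beyond the trend, sequencing error and
compositional artifacts of PCR, phylogenetic structure among taxa, or
site-level random effects (an optional hook exists, but no variance
estimate is available to calibrate it). Passing recovery tests
therefore show the inference machinery is sound under the stated
assumptions — not that real surveys identify lags with the same ease.

## Numerical choices and degenerate inputs

- Shannon diversity in nats (configurable base); Shannon ≤ ln(richness)
  asserted as a property.
- Rarefaction by multivariate hypergeometric draw; under-depth samples
  are dropped with a warning, never scaled.
- Bray–Curtis is a semimetric: the triangle inequality is deliberately
  not asserted.
- Mantel p-values use the add-one convention
  (1+#{r_perm ≥ r_obs})/(1+n_perm); the correlation-screen FDR uses
  Benjamini–Hochberg across the whole family of tests, skipping
  constant columns with a logged reason.
- PCA loading signs are fixed (largest-magnitude entry positive) so
  component labels are stable across runs; constant columns raise an
  error naming the variable.
- Nearest-cell lookup breaks ties toward the lower index; coordinates
  outside the grid extent raise rather than clamp.
- Missing months inside a scheduled window raise an error — no
  imputation. Twenty-year windows run through the same schedule
  machinery (tested at 120 and 240 months).
- PCA is fitted per region/grid, one observation per sampling location
  per window (plots of a site share the cell, so the site is the
  climatic unit).

## Problem sizes

The test suite and acceptance script run everything at the study's
native scale (180 samples, 36- and 120-candidate pools) but keep
enumeration depth at `max_size = 2` inside replicated simulations, and
use 100 replicate datasets for lag recovery (30 in the acceptance
script), 1000 (200) replicates for the FDR null, and 50 (20) random
problems for each oracle comparison. These are the package's chosen
simulation sizes; all are seeded.

## Known limitations

Forecasts assume temporal niche conservatism and free dispersal — no
adaptation, dispersal limitation or neutral assembly — and are baseline
estimates at best. Lag attribution cannot see drivers predating the
climate record's start (1950 here), and five-year-overlapping windows
bound its temporal resolution. Gradient-boosted robustness models are
an extension hook only. No UniFrac, NMDS or ordination wrappers are
provided; those belong to general-purpose ecology packages.
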