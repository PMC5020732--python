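# Methods

This note documents the models and numerical choices behind `lurcity`:
what each stage assumes, the defaults and why, what the synthetic data
does and does not emulate, and the known limitations.

## The regression model

Station-period mean concentrations y (ppb) are modelled as

    t(y) = b0 + sum_j b_j * g_j(x_j) + e,     t(y) = (ln y)^p

where x_j are GIS-derived predictor values at the station's grid cell,
g_j is a per-predictor linearizing transform, and p is an integer power
chosen so that t(y) is as close to normal as the data allow. p = 1 (the
plain log) is kept whenever ln y passes a Shapiro–Wilk test at
alpha = 0.05; otherwise p is picked from {-4, -3, -2, -1, 2, 3} to
maximize the Shapiro–Wilk p-value. These exponents cover the transforms
that arise in practice for seasonal nitrogen-oxide responses.

A subtlety worth spelling out: for concentrations above 1 ppb, ln y > 0,
so (ln y)^p is *order-reversing* when p < 0. The a-priori effect
directions (e.g. "green space lowers NOx") are statements about y, so on
the transformed scale the expected coefficient signs flip with the sign
of p. `forward_select` takes the transform's monotonicity sign and
checks priors against `sign(coef) * sign(monotonicity)`. Inverting the
transform for mapping uses the real branch consistent with the observed
response range (ln y > 0); transformed cell values with no preimage on
that branch (possible for even or negative p) are flagged and later
floored.

## Predictor catalogue

210 variables in six classes, named `KIND.RADIUS` for buffered variables
and `DIST to KIND` / `LNDIST to KIND` for distances:

* traffic (26): buffered road length (m) for streets, highways, major
  roads, all roads, bridges; radii 100–500 m (100–1000 m for the road
  aggregates, 400–500 m for bridges). Computed as circular focal sums of
  the presence raster times the pixel size.
* land use (50): buffered area (m²) of 10 polygon classes, radii
  100–500 m; focal sum times pixel area.
* distance (58): straight-line distance and its natural log to each of
  the 15 traffic/land-use kinds and 14 point/zone features (schools,
  petrol stations, airports, the traffic access control zone and its
  extended episode variant, etc.). `LNDIST = ln(d + cell)`: the one-cell
  offset keeps feature cells finite, and the log form reflects the
  near-exponential decay of concentrations away from sources.
* population (22): quartic-kernel density (persons/km²) of total and
  adjusted (working-age employed) population centroids, kernel radii
  500–3000 m in 250 m steps (11 radii per weighting; the density kernel
  integrates each centroid's weight exactly in the continuum and to
  within 1% on grids with radius ≥ ~10 cells).
* products (52): buffered road length divided by distance (or squared
  distance) to the same road kind, the distance floored at one cell size
  to avoid division by zero at source cells.
* geographic (2): DEM elevation and Horn-gradient slope (degrees).

Each variable carries an a-priori effect direction (+, −, or none);
distances inherit the opposite sign of their source kind. Every raster
passes through a null→0 step before station extraction, so design
tables never contain missing predictor values.

Two bookkeeping notes. The class header counts in the source material
sum to 212, but the printed sub-class enumeration (and the stated total)
give 210, which is what the catalogue implements; `catalog_summary`
reports the realized counts. And the exact radii within each sub-class
count are a convention — they are configurable via `radii_config`.

## Synthetic city and ground truth

The generator emulates the *statistical structure* the analysis assumes,
not any real geography: a connected jittered road grid (three classes),
bridge segments at major-road crossings, contiguous land-use patches
from seeded region growing on a block lattice (all 10 classes always
present), facility points of every kind, a circular central traffic
access control zone, block-centroid population weights, and a DEM with a
northward gradient plus smoothed noise. Defaults are a 2 km × 2 km
extent at 10 m cells; tests mostly use 20 m cells (the operators are
resolution-agnostic; the 5 m production resolution is just a config
value).

Concentrations follow a log-linear ground truth:

    ln C(s, h) = ln(base * season_base) + sum_i c_i * m_i(season) * x_i(s)
                 + eps(h),   eps ~ N(0, noise_sd)

with a multiplicative diurnal cycle normalized to annual mean 1, NO and
NO₂ generated as fixed shares (0.59/0.41) of the modelled level with
independent hourly noise, and NOₓ defined as their sum at every hour (so
the species identity is exact by construction). Per-season coefficient
multipliers m_i let sources switch on/off seasonally — that is what
makes the seasonal-comparison experiment meaningful. Defaults (base
40 ppb, cooler/warmer base multipliers 1.35/0.75, hourly noise sd 0.4 on
the log scale) put station annual means in the tens-to-hundreds of ppb
with cooler ≈ 1.8 × warmer, the regime reported for heavily trafficked
megacities with winter heating. The observational analogue is a real
monitoring record; the generator does not emulate meteorology,
dispersion physics, instrument drift, or shared measurement error, so
passing recovery tests demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to
real-world misspecification.

Missingness is MCAR by default (exactly round(rate·8760) hours per
track, so the realized rate is within one hour of the request) with a
block mode — contiguous outages of geometric mean length 24 h — because
real gaps come from instrument downtime. The default rate 0.28 matches
the regime of the motivating network.

## Imputation

Missing hours are imputed under a joint multivariate normal over station
columns plus fully observed time covariates (sin/cos of hour-of-day and
day-of-year, 11 month indicators with January as reference — the
encoding is our choice; only "month, day, hour were supplied" is given).
Each of the 10 runs bootstraps rows, fits the normal by EM (sufficient
statistics accumulated per missingness pattern; convergence when the
relative observed-data log-likelihood change < 1e-6, max 200 iterations,
error on non-convergence; a 1e-6 relative diagonal ridge keeps the
near-collinear covariate block invertible), then fills each missing cell
of the *original* matrix with its conditional mean plus a draw from the
conditional covariance. Observed cells are never altered — bitwise.
Negative imputed concentrations are clipped to 0 when averaging; EM runs
on the raw scale by default (mirroring the normality assumption of the
standard tool for this protocol) with a log-scale option. Imputation is
per-pollutant, joint across stations; a joint-across-pollutants variant
was considered and left out because the NOₓ = NO + NO₂ identity makes
the joint covariance singular.

Calibration (recomputed by the acceptance script): at 28% MCAR on
correlated hourly data the run-averaged station means sit well within 2
total standard errors (Rubin's rule: within-variance + (1+1/m) ×
between-run variance) of the complete-data means, and the mean absolute
error at masked cells grows monotonically over 10/30/50% missingness.

## Selection algorithm

Forward stepwise under simultaneous constraints, evaluated for the model
*including* the candidate: (1) every coefficient sign consistent with
its prior (adjusted for response monotonicity, and re-checked for all
included terms at every step, so accepted models are sign-consistent
throughout); (2) every term's p < 0.1; (3) leave-one-out cross-validated
R² = 1 − PRESS/TSS strictly increases (PRESS via the hat-matrix
shortcut, which the tests verify equals n explicit refits to 1e-10);
(4) max VIF < 5 (the threshold is our default — reported maxima in
comparable analyses stay below ~4 — and configurable); (5) at most
⌈√N⌉ terms (23 stations → 5). Among admissible candidates the highest
adjusted R² wins; ties break to lower max-VIF, then catalogue order.
The full trace (every candidate at every step with the rule that
rejected it) is stored in the model JSON so the constraints can be
audited after the fact. If no candidate is admissible at step one the
intercept-only model is returned with its trace rather than an error.
Residual normality (Shapiro–Wilk, alpha 0.05) flags but does not reject
a final model. RMSE is reported on the ppb scale after inverting the
response transform.

Per-predictor linearization picks, per variable, the transform from
{identity, log, x^0.1, x^0.5, x^2} maximizing |Pearson r| with the
transformed response (ties to identity; zero-variance predictors are
excluded). The log transform is exact ln(x) when all values are
positive and offsets by the smallest positive value only when zeros
occur. The power set includes 0.1 because such mild powers do occur in
fitted nitrogen-oxide models.

A note on post-selection inference, relevant to the recovery study: once
stepwise selection has added a spurious term, the OLS residual variance
— and with it every reported standard error — is optimistically small.
In 200 seeded recovery replicates the true-predictor regression is
perfectly calibrated (all |z| < 3), while the selected-model
coefficients exceed the 3-SE band in ~6% of replicates with |z| barely
above 3. The recovery criterion therefore checks identification
(selection returns a superset of the true actives with correct signs)
and coefficient recovery in the regression on the true predictors; the
stricter selected-model rate is reported alongside it.

## Diagnostics

Leave-one-out coefficient stability reports min, max and CV = sd/|mean|
per coefficient over the N refits; a model is sign-consistent when no
coefficient's min/max straddle zero. Global Moran's I uses row-
standardized inverse-distance weights by default (k-nearest-neighbour
optional; no weight scheme is canonical for ~23 irregular stations), the
randomization-assumption variance, and a two-sided normal p-value, with
a permutation p available for small n. The tests verify the vectorized
statistic against the textbook double sum to 1e-12 and its null
calibration (mean ≈ −1/(n−1), rejection ≈ alpha).

## Mapping and seasonal comparison

Surfaces are evaluated cell-wise on the transformed scale and inverted
to ppb. Floor = (minimum observed of the matching period)/√2 — the
quantification-limit convention — and ceiling = 1.2 × maximum observed;
enlarged/truncated fractions are counted before clipping, and
non-invertible cells count as enlarged. Clipping is idempotent and the
enlarged/truncated/untouched counts partition the grid exactly.

Seasonal comparison samples cell centres uniformly without replacement
(n = 1000 by default; no minimum separation is enforced) and correlates
surfaces pairwise with Pearson when both series pass Shapiro–Wilk at
alpha 0.05, Spearman otherwise. In the package's contrast experiment a
cooler-only local population source (residential heating) next to a
damped traffic gradient drives the cooler–warmer surface correlation
from ≈1.0 (season-invariant sources) down to ≈0.3–0.5 — the qualitative
signature of season-dependent spatial patterns. An early version used a
2500 m population kernel for the seasonal source; on a 2 km domain that
kernel is a central dome nearly collinear with distance-to-centre, and
the contrast vanished — the 500 m kernel keeps the source spatially
distinct, which is the point of the experiment.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale configurations chosen to
exercise every code path at full statistical fidelity: 2 km cities at
20 m cells (10⁴ cells; the cell-count formula extent/cell² is what
scales to production grids), 23–40 stations, full 8760-hour years,
50-replicate recovery studies, 10-run imputation at 4 stations (EM cost
grows with the number of distinct missingness patterns, i.e. with
2^stations under MCAR). The pipeline demo uses 10 stations for the same
reason. Every stage is a pure function of (config, seed); one master
seed is expanded per stage as (master × 1000003 + stage) mod 2³¹, and
re-running a pipeline with the same config is bit-identical.

## Known limitations

* The generator's concentration model is the estimator's own assumption
  (log-linear, iid log-normal hourly noise); recovery results do not
  speak to dispersion physics or correlated measurement error.
* The EM treats month indicators as jointly normal — standard practice
  for this imputation protocol, but a model approximation.
* Stepwise-selected models inherit the usual post-selection caveats;
  reported p-values and SEs are conditional on the selected model.
* Raster distances are centre-to-centre (matching the GIS straight-line
  tool), not vector-exact; focal neighbourhoods are circular by centre
  inclusion.
* No geographic CRS, geodesy, or reprojection: all geometry is planar
  metres.
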