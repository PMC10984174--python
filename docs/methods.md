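# Methods

`roamkit` implements the full analysis chain for GPS collar data from
owned outdoor cats: trajectory cleaning, home-range estimation, covariate
construction, gamma-GLM modelling of home-range size with two-stage AICc
selection, resource selection functions (RSF) for habitat use, and the
equivalent-circle buffer rule used to size cat-exclusion zones. A
synthetic-data module generates landscapes and trajectories with known
movement and selection parameters, so every stage can be validated
against ground truth. This note records the models, the defaults and the
choices made where the design was genuinely open.

## Coordinate and time conventions

All geometry lives in a single projected CRS in metres (default UTM zone
17N / WGS84, EPSG 32617), because every threshold in the pipeline —
speeds in m/min, radii in m — is metric. Geographic input is projected
once at ingestion with an in-package transverse-Mercator implementation
(Snyder ellipsoidal series; error well under a centimetre inside a zone,
i.e. three orders of magnitude below GPS error). The test suite carries
an independent Krüger-series implementation as a cross-check. An
explicit EPSG code is required; the loader never guesses a datum.

Timestamps are naive local-clock times. The day/night split
(06:00–17:59 day, complement night) encodes owner household schedules,
so converting to UTC would be wrong.

## Trajectory cleaning

Five passes, in order; coordinates are never altered, only removed:

1. **Blocklist** — configurable circular exclusion zones (a reproducible
   replacement for manual removal of known-bad locations).
2. **Speed** — fixes implying a sustained speed over 100 m/min (faster
   than a cat's trot can be held between fixes 2–60 min apart) are
   impossible. "Speed" is the arriving speed, distance/Δt to the
   previous retained fix. The pass keeps the *largest* subsequence of
   fixes whose every bridged speed is ≤ the ceiling, found by a
   longest-valid-subsequence dynamic program (O(n²), exact). A greedy
   remove-the-fastest loop is not equivalent: when two consecutive fixes
   are displaced together, the huge bridged speed is blamed on the next
   clean fix, which gets removed too. Ties between equally small removal
   sets resolve to the lexicographically earliest survivor sequence.
   The boundary is strict: exactly 100 m/min is retained.
3. **Spikes** — an interior fix whose two legs are both ≥ 15 m/min with
   a turn angle in [165°, 180°] (a near-perfect out-and-back) is a
   satellite artifact; the apex alone is removed, in a left-to-right
   scan with metrics recomputed after each removal (the scan steps back
   one fix after a removal because the predecessor's outgoing leg has
   changed). The turn angle is the angle between the incoming and
   outgoing displacement vectors, so 180° is a full reversal. The spike
   speed is inclusive (≥ 15), the ceiling exclusive (> 100), following
   the wording of the thresholds.
4. **Between-removed** — a surviving fix whose immediate neighbours in
   the *original* sequence were both removed has no reliable context and
   is removed; labels do not cascade.
5. **Stationary collapse** — maximal runs of successively coincident
   fixes (≤ 1e-9 m apart, i.e. bit-identical after parsing; configurable)
   collapse to their first member. These runs are produced by collars
   left on indoors.

The pipeline is idempotent: rerunning it on its own output removes
nothing. Filter reports account for every input fix exactly once.

## Home ranges

**MCP** — the convex hull of all retained fixes ("100 % MCP"); for
levels below 100 the fixes farthest from the centroid are dropped first.
Areas are planar polygon areas in hectares.

**Kernel isopleths** — a bivariate Gaussian KDE evaluated on a square
grid (default 200×200) covering the fixes padded by three bandwidths;
the *p* % isopleth is the smallest set of grid cells containing *p* % of
the estimated mass (cells ranked by density — the classic
utilisation-distribution volume contour). Area is cell count × cell
area; a contour outline is attached for mapping only. The default
bandwidth is the reference rule href = σ̂·n^(−1/6) with
σ̂² = (var(x)+var(y))/2, the ad hoc default of mainstream home-range
software; analyses that need rule-independence should pin the bandwidth
explicitly (all closed-form checks in the tests do). Isopleth mass is
normalised over the padded grid; with 3-bandwidth padding the truncated
tail mass is negligible at the grid sizes used. Grid resolution is a
convergence knob: at 200 cells/axis the 95 % isopleth of 10⁴ Gaussian
draws matches the π σ² χ²₂ closed form within ~1.5 %.

The day/night split is clock-based and inclusive of the boundary
minutes (17:59:59 is day; 18:00:00 is night). Day/night KDE bandwidths
are computed per subset, not jointly.

**Asymptote diagnostic** — MCP area versus chronologically accumulated
fix count; the curve is non-decreasing by construction. Instead of
visual inspection, a plateau flag is set when the final 20 % of the
curve grows the area by < 5 % (both knobs configurable).

**Buffer rule** — a home range of *A* hectares has equivalent-circle
diameter d = 2·√(A·10⁴/π); the management buffer is d·(1+margin), with a
20 % default margin, both reported to the nearest 10 m (the resolution
at which such guidance is quoted): 38.45 ha → 700 m → 840 m.

**Paired and spread tests** — the Wilcoxon signed-rank statistic is the
sum of positive-difference ranks, zeros dropped, average ranks on ties;
p-values are exact by full sign enumeration up to 12 non-zero pairs and
use the tie-corrected, continuity-corrected normal approximation beyond.
The Brown–Forsythe test is a one-way ANOVA on |x − group median|.

## Covariates

Road density is the summed length of road inside a disc centred on the
animal's mean coordinates. Clipping is exact (quadratic line–circle
intersection per segment), and the disc is closed — length on the
boundary counts. The radius is standardised across animals by inverting
the median 95 % KDE area to a circle radius (1.3685 ha → 66 m). The
major-road flag is 1 iff any major-class road intersects the animal's
100 % MCP polygon (closed-set intersection; a tangent at a vertex
counts) — an operationalisation of "near the home range".

Neuroticism comes from a 43-item, 7-point owner questionnaire (the
Feline Five inventory); the raw score is the mean of the 13 neuroticism
items and the reported score is z-standardised across the study's
animals (raw scores are always recoverable). Which items map to
neuroticism is survey-specific, so the item→domain map is a required
input, never hard-coded. Internal consistency is summarised by
Cronbach's alpha with sample (n−1) variances.

## Home-range inference

Candidate models are gamma GLMs with log link — areas are strictly
positive and right-skewed, and covariate effects are naturally
multiplicative. Coefficients come from IRLS (statsmodels); if IRLS ends
in a shallow deviance limit cycle, a quasi-Newton polish from the IRLS
iterate completes the fit. The gamma shape is then re-estimated by
profile maximum likelihood (solving log k − ψ(k) + 1 + mean(log(y/μ) −
y/μ) = 0), so that log-likelihoods — and hence AICc = −2logL + 2k +
2k(k+1)/(n−k−1) — are coherent across candidates. The parameter count k
includes the intercept, the slopes and the shape (null model k=2,
one-predictor models k=3). Wald standard errors use the Pearson
dispersion, the convention of mainstream GLM software; this is a known
divergence risk against software that defaults to other dispersion
estimators.

Selection is two-stage all-subsets: all 2³ subsets of the intrinsic
predictors (sex, age, neuroticism) first; predictors supported there are
carried into *every* stage-2 candidate (that is what "carried forward"
implies), where all 2³ subsets of the extrinsic predictors (road
density, major-road flag, ordinal start date) are fitted. A predictor is
retained when it appears in at least one model within ΔAICc < 2 *and*
its Wald CI in the best model containing it excludes zero. CIs use 85 %
(z = 1.4395) because 95 % intervals discard variables that AIC itself
supports. Coefficients are combined over the ΔAICc < 2 window by full
(zero-substitution) averaging with renormalised Akaike weights and
Buckland unconditional standard errors
(se = Σ wᵢ·√(seᵢ² + (βᵢ − β̄)²)); conditional averaging is available by
flag.

A caveat that matters when interpreting simulation studies of this
procedure: an 85 % CI retains a truly null predictor ~15 % of the time
by construction, so with three null intrinsic predictors the probability
that *none* survives stage 1 is only ≈ 0.85³ ≈ 0.61 per dataset (a
falsely carried predictor must also survive the stage-2 check, which
raises the final-inference rate to ≈ 0.75). This is a property of the
published selection rule itself, not of the implementation.

## Resource selection functions

Two third-order designs per animal: a 300 m disc around the owner's home
and the animal's own 100 % MCP. Used points are the cleaned fixes inside
the boundary; available points are drawn uniformly inside the boundary
by rejection sampling at 10 available per used point. Points in
undifferentiated or water cover are dropped from both sets, and
availables are re-drawn so the 10:1 ratio holds exactly. Category
lookup is raster-cell membership (half-open cells).

Selection for each habitat is a logistic regression of the
used/available indicator on a single in-habitat dummy — one model per
habitat, because a joint model over exhaustive categories plus an
intercept is not identifiable — with a per-animal random intercept. The
mixed likelihood is maximised by adaptive Gauss–Hermite quadrature
(15 nodes, Laplace-centred per animal, Newton inner loop), standard
errors from a finite-difference Hessian at the optimum. When the
random-intercept variance collapses to the zero boundary the fit reduces
exactly to plain logistic regression (and is reported from it); a
fixed-effects fit with cluster-robust (by animal) standard errors is
available by flag. Any empty cell of the 2×2 use/habitat table is
rejected as separation before fitting. The test suite cross-checks the
mixed fit against lme4's `glmer` on a generated fixture.

Note that the fixed-count ratio design pins each animal's intercept
almost completely (the 10:1 ratio self-normalises baseline use), so
genuine random-intercept variance arises only from point-level
heterogeneity, and a zero variance estimate on such designs is expected
rather than pathological.

## Synthetic data

The generator emulates the study conditions: a four-category landscape
(impervious 66 %, road 26 %, greenspace 6 %, agriculture 2 %), irregular
2–60 min fix intervals, isotropic Gaussian GPS error of 4.8 m (open-sky
collar accuracy), and 20-day campaigns.

**Landscape** — seeded region growing to exact per-category cell
quotas: contiguous patches, not i.i.d. noise, because availability in
urban RSFs comes from contiguous land-cover blocks. The default plants
one seed per ~500 cells (mean patch ≈ 5 ha at a 10 m cell — urban-block
scale). Roads also exist as vector lines (a jittered rectilinear grid
with every fifth street major) for the covariate stage; the raster road
category and the vector network are deliberately independent layers.

**Movement** — a step-selection walk: at each fix time, K = 20
candidate displacements are proposed (von Mises turning angles around
the previous heading, exponential step lengths of mean 25 m, plus a
deterministic pull of strength 0.15 toward home), and one is chosen with
probability proportional to the selection weight of its land cover. This
is the simplest generative model under which a point-level logistic RSF
is well specified. Displacements are capped so true speeds stay strictly
below 100 m/min — any fix the speed filter removes from synthetic data
is therefore a known artifact. Walks are reflected at the landscape
boundary. Default weights (impervious 1.45, road 0.80, greenspace 0.60,
agriculture 0.25) mirror the qualitative selection pattern observed in
urban pet cats. Day/night behaviour is identical by default (field
studies find no difference), with an optional nocturnal step-scale
multiplier for power studies. With these defaults, simulated 100 % MCP
ranges land at a median of ~5 ha — the observed order of magnitude
(0.3–40 ha) — which is all the defaults aim to reproduce.

**Degradation** — Gaussian noise plus labelled artifacts at 2 %
per-fix rates each: outliers displaced far enough that the arriving
speed exceeds the ceiling; spikes inserted midway between two clean
fixes, offset perpendicular to the chord so both legs are 15–95 m/min
with a turn angle in the 165–180° band (verified against the cleaning
pipeline's own predicate; geometrically infeasible gaps are skipped);
stationary runs of 2–4 fixes pinned to one coordinate. Labels ride along
with the observed fixes.

Two realism limits worth keeping in mind. First, the realized selection
contrast of a tethered step-selection walk is attenuated relative to the
log weight ratios — the tether forces the animal through whatever cover
surrounds its home — so parameter-recovery checks for the RSF are run
either on the exactly-specified tilted point-process design (for
coverage) or as rank recovery on fine-grained landscapes (for ordering).
Second, the walk's stationary density is concentrated toward home
*within* its own MCP even under uniform weights, so raw used-counts
comparisons against uniform MCP availability are biased by design;
neutrality under uniform weights is checked on the fitted coefficient
(centred on zero across campaigns), not on count tables. Real GPS data
additionally contain behaviours the generator does not attempt:
road-following movement, repeated commuting routes, fix-rate dependence
on behaviour, and non-isotropic multipath error near buildings. Passing
the synthetic checks validates the estimators' correctness, not these
aspects of field realism.

## Numerical choices and degenerate inputs

- MCP requires ≥ 3 non-collinear fixes; collinear input is a
  "degenerate hull" error. KDE requires ≥ 5 fixes and positive spread.
- Gamma-GLM responses must be strictly positive; intercept-only models
  use the closed-form ML fit (μ̂ = ȳ).
- AICc requires n > k + 1 and errors otherwise.
- The Wilcoxon test warns and returns p = 1 when every difference is
  zero; Brown–Forsythe handles zero-spread groups (F = 0 when both
  groups are identical).
- Rejection sampling for availability caps its batch count and drops an
  animal (with a warning) if the boundary has essentially no usable
  area after exclusions.
- All simulations and designs are deterministic given a seed; seeds
  derived from a master seed stay below 2³¹.

## Problem sizes in the validation suite

The statistical checks run at sizes chosen to make their Monte-Carlo
noise small relative to the asserted margins: 100 one-animal campaigns
for filter recall/precision, 10⁴ draws for the kernel closed form, 200
replicates for RSF CI coverage, 20 sixteen-animal campaigns for rank
recovery, and 100 replicates of the n = 29 two-stage GLM. The same
computations, at the same or slightly reduced replication, are what
`scripts/acceptance.py` re-measures.
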