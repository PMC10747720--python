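# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of the `rbai` pipeline.

## Growth quantities

Stem circumference *c* (cm, at breast height) gives basal area
BA = c²/(4π) (cm²) and DBH = c/π. The increment attributed to calendar
year *t* is BAI_t = BA_t − BA_{t−1}, computed only for consecutive survey
years; mid-series gaps yield no increment rather than a multi-year average,
so every increment is a true annual change. RBAI_t = 100 · BAI_t / BA_t
uses the basal area of the measurement year *t* in the denominator (the
literal reading of "relative to the basal area in the year of
measurement"); a previous-year denominator is available via
`denominator="previous"` — the difference is second-order for the 1–4%
annual increments typical here. Negative increments (shrinkage, bark loss,
observer error) are retained and flagged, never truncated: truncation
would bias trends upward.

## Stratified bootstrap chronology

Long-running networks accumulate large trees, so the records available in a
given year drift toward big stems. The chronology removes this
size-sampling bias by resampling equitably across 5 cm circumference
classes (half-open bins, `floor(c/5)`). Classes thinner than
`min_class_count = 5` records within a species × year group are folded into
their nearest neighbouring class, so the effective number of classes adapts
to each species' size spread. One bootstrap replicate draws
`n_per_class = 5` records *with replacement* from every non-empty class and
averages all draws (equal weight per class); the representative mean
averages `n_reps = 20` replicates. Defaults mirror the monitoring protocol
being emulated; 20 replicates make a coarse percentile interval, so
`n_reps = 2000` is recommended when the confidence band itself matters, and
a mean ± t·SE band over the replicates is emitted alongside the percentile
band. Class values are sorted before resampling so the chronology is
invariant to record order, and every (species, year) cell draws from its
own child stream of the master seed — adding a species or year never
perturbs other cells.

A percentile interval's width converges to the true 2.5–97.5 quantile range
as replicates grow; it does not shrink. The substantive property, verified
by simulation, is coverage: at `n_reps = 2000` the interval covers the true
class-balanced mean in ≈95% of synthetic replicates. No tree-level blocking
is applied across years (the bootstrap is independent per year), which
understates serial dependence of the band — a limitation inherited from the
resampling design.

## Climate interpolation and dry years

Each plot receives, per variable and year, the inverse-distance-weighted
(power 1, great-circle distances) mean of the 4 nearest grid points, each
first corrected from grid-point to plot elevation: temperature −0.7 °C per
+100 m; precipitation +40 mm per +100 m applied to the annual total and
scaled onto the JJA total by its share of the annual total. Correcting each
point before averaging (rather than correcting the average once) keeps the
result exact when a plot coincides with a grid point. Corrected
precipitation is floored at zero with a warning. A year is a drought
pointer year when its JJA total falls below the plot's 1950–2021 arithmetic
mean (the conventional climate normal; the median is not used) at
*strictly* more than 90% of plots — exactly 90% does not qualify. A fixed
dry-year list can override the detector (`dry_years_override`) when the
pointer set is prescribed externally.

## Trend tests and cohort curves

Species trends are ordinary least squares of the chronology's mean RBAI on
year with a two-sided t-test on the slope and the usual significance stars.
The linear model is deliberately simple: it is a monitoring summary, not a
causal model, and drought dips enter it as noise.

Absolute growth is modelled as a smooth surface BAI ~ f(DBH, year) with a
Gamma family and log link (BAI is positive and right-skewed), using a
tensor product of cubic regression splines with 4 basis functions per
margin (the `k = 4` is read per margin; 16 coefficients total). With a
basis this small the fit is a regression spline, and an explicit smoothness
penalty with REML/GCV selection would be inert; none is applied, which also
keeps the fit exactly deterministic. Records with BAI ≤ 0 are excluded from
this model only (Gamma support) with the count logged; they stay in the
chronologies. Confidence bands are computed on the link scale
(fit ± 1.96 SE from the coefficient covariance) and exponentiated, so they
are positive and asymmetric; they do not include basis-choice uncertainty.
Evaluating the surface at constant DBH 20/30/40 cm over 1990–2021,
2000–2021 and 2010–2021 yields cohort curves — the trajectory of a
hypothetical tree holding that diameter in every year.

## Dry-year ordination

Rows are (plot, species) pairs; the profile is the mean RBAI of that
species' trees on that plot in each selected dry year; rows missing any
selected year are dropped (complete case, logged). PCA standardises columns
by default (correlation PCA): the dry-year columns share units but their
variances differ across decades, and scaling matches common practice for
"PCA regression". Scores and loadings come from the SVD of the standardised
matrix; the largest-magnitude element of each loading vector is made
positive for a deterministic sign. Species centroids are score means;
ellipses are bivariate-normal 95% probability regions at the χ²₂ quantile of
the species' score covariance (the common reading of a "95% ellipse"); a
literal per-axis percentile rectangle is available via `method="rect"`.

Vector fitting regresses each site variable on (PC1, PC2) by least squares;
R² (reported ×100) measures alignment with the ordination plane, and the
p-value is a permutation test over rows with the estimator
p = (1 + #{R²_perm ≥ R²_obs}) / (1 + 999). Plot-level covariates are
duplicated across species sharing a plot, pooling species into one table as
a network-wide analysis does. Missing values are handled case-wise per
variable; constant variables get R² = 0, p = 1.

## Synthetic study conditions

The generator emulates a Western-Carpathian-like Level I network and is the
test bed for every stage. Defaults, chosen once as the emulated conditions:

* 115 plots on a 17–22° E × 48.3–49.6° N extent over a smooth 200–1400 m
  terrain; species occupancy proportional to a mix derived from the
  published per-species individual counts; 4 trees per present species.
* Years 1988–2023; expected RBAI linear per species with baselines
  FS 3.0 / AA 2.5 / QP 2.2 / PA 1.8 / PS 1.5 % and trends FS −0.029
  (the steepest published decline), PS −0.020, QP −0.012, PA −0.008,
  AA 0.0 %/yr.
* Twelve injected drought years (1990, 1992, 1993, 1994, 2000, 2003, 2012,
  2013, 2015, 2017, 2019, 2022) multiply expected RBAI by 0.6 times a
  plot response factor q_p with 15% spread, correlated 0.5 with
  standardized elevation (higher plots suffer less).
* Noise: lognormal, unit mean — per tree-year sd 0.15 and a site-level
  per-(plot, year) factor sd 0.30 shared by all trees of a plot. The site
  factor represents local weather/stand effects; without it the dry-year
  profile matrix is nearly rank one and PC1 explains ~90% of variance,
  far from the ~50% regime a real network shows. With it, PC1 lands near
  50% and the pooled elevation vector fit near the few-percent R² regime.
* Climate: 0.1° grid, 1950–2023; temperature follows the −0.7 °C/100 m
  lapse exactly plus a shared annual anomaly; JJA precipitation is a point
  climatology times a shared year factor — uniform(0.45, 0.70) in drought
  years, uniform(1.05, 1.40) otherwise — times lognormal spatial jitter
  (sd 0.25). Non-drought factors are bounded above the long-term normal so
  that only injected deficits are network-synchronous; this gives the
  detector a clean separation margin and makes exact recovery of the
  injected set the expected outcome, which is a property of the emulated
  phenomenon (drought pointer years *are* network-synchronous deficits),
  not of the detector.

Growth is generated on the RBAI scale and converted through the basal-area
recursion BA_t = BA_{t−1}/(1 − RBAI_t/100), so realized increments are
strictly positive and circumference series strictly increase. Ground-truth
tables (species × year expectations, per-plot response factors, per-year
climate factors) are emitted with the data.

What the generator does **not** emulate: tree mortality and recruitment
(survivorship bias is absent; an entry hook exists but defaults off),
measurement error and relocation bookkeeping, serial correlation of growth
beyond the site-year factor, size-dependent *relative* growth (expected
RBAI is size-independent by construction, so stratification corrects
sampling imbalance in tests built for that purpose, not in the default
stream), and daily weather. Passing tests therefore demonstrate that the
pipeline recovers the structures the generator encodes at realistic noise
levels — not that real monitoring data are this well behaved.

## Problem sizes used in tests

The suite verifies stochastic properties at sizes chosen to keep a full run
in the low tens of seconds: trend recovery averages 50 seeds of a
200-tree single-species network; CI coverage uses 200 replicates at
`n_reps = 2000`; dry-year recovery uses 10 seeded replicates on a 0.25°
grid (finer spacing approaches the 0.1° product; coarser grids leave too
few independent grid points and plots' below-normal indicators become
correlated); envfit null uniformity uses 200 replicates at 199
permutations; elevation recovery 30 replicates at the default 115 plots;
the cohort drought-dip sign test 20 seeds with a contiguous 2007–2012
drought block (a 16-function spline surface cannot resolve isolated
single-year dips — a resolution limit of the k = 4 basis, shared with any
equally smooth fit).

## Numerical conventions

Haversine distances on a 6371 km sphere; ties in nearest-neighbour
selection broken by stable sort order; a zero-distance grid point takes the
whole weight. CSV output uses `%.12g` floats, making repeated runs
byte-identical under a fixed seed. Master seeds fan out to stages via
`numpy.random.SeedSequence` spawning; (species, year) cells key their
streams by a CRC32 of the species code and the year.
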