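# rbai — radial-growth trends for long-term forest monitoring networks

`rbai` analyses three decades of annual stem-circumference records from a
permanent forest-monitoring network (ICP Forests Level I style: a regular
grid of plots, five major temperate species — *Fagus sylvatica* (FS),
*Picea abies* (PA), *Abies alba* (AA), *Quercus petraea* (QP),
*Pinus sylvestris* (PS)). It answers two questions a monitoring programme
asks of such data: **are the species' radial growth trends declining**, and
**which site factors align with growth in drought years**.

## The statistics at its core

* **Relative basal area increment.** With stem circumference *c* (cm),
  basal area is BA = c²/(4π) and the annual increment BAI_t = BA_t −
  BA_{t−1}. Growth is expressed relative to the basal area in the year of
  measurement, RBAI_t = 100 · BAI_t / BA_t (%), which removes the
  absolute-size effect.
* **Stratified-bootstrap detrendization.** Increment records are binned
  into 5 cm circumference classes; the representative species mean for each
  year averages 20 bootstrap replicates, each drawing 5 records with
  replacement from every class. Equal class weights remove size-sampling
  bias from the chronology; the 2.5/97.5 percentiles of the replicate means
  give the 95% confidence band.
* **Drought pointer years.** Gridded climate is interpolated to plots from
  the 4 nearest grid points (inverse-distance weights) after elevation
  lapse corrections of −0.7 °C and +40 mm per +100 m; a year is *dry* when
  its June–August precipitation total falls below the 1950–2021 plot normal
  at strictly more than 90% of plots.
* **Trend tests and cohort curves.** Species trends are OLS fits
  RBAI ~ YEAR with a t-test on the slope; absolute growth is modelled as
  BAI ~ te(DBH, year, k = 4) with a Gamma log-link and cubic regression
  splines, evaluated at constant DBH 20/30/40 cm over 1990–2021, 2000–2021
  and 2010–2021.
* **Dry-year ordination.** (plot, species) profiles of mean RBAI over the
  dry years enter a correlation PCA; species centroids and 95%
  bivariate-normal ellipses summarise drought responses, and environmental
  vectors (elevation, soil chemistry/texture, richness, climate normals)
  are fitted onto the PC1–PC2 plane with permutation-test p-values
  (`envfit` sense: R² of v ~ PC1 + PC2).

Because real network exports are access-restricted, the package ships a
first-class synthetic generator (`rbai.synthetic`) that emulates the
structure of such a network — including a configurable linear RBAI trend
per species, multiplicative growth dips in twelve injected drought years,
and an elevation-coupled drought response — with ground-truth tables that
make every stage's expected output checkable.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the library; outputs accumulate under `results/`):

```sh
python analysis/01_simulate_network.py
python analysis/02_dry_years.py
python analysis/03_chronologies_trends.py
python analysis/04_cohort_curves.py
python analysis/05_dry_year_ordination.py
```

Step 02 prints the detected drought pointer years, which under the default
generator match the injected set exactly:

```
detected dry years: [1990, 1992, 1993, 1994, 2000, 2003, 2012, 2013, 2015, 2017, 2019, 2022]
injected drought years: [1990, 1992, 1993, 1994, 2000, 2003, 2012, 2013, 2015, 2017, 2019, 2022]
exact match
```

Step 03 prints the species trend table:

```
species   slope  intercept  p_value  r_squared stars
     AA -0.0006     3.3979   0.9309     0.0002
     FS -0.0224    47.1727   0.0103     0.1832     *
     PA -0.0058    13.0712   0.3070     0.0316
     PS -0.0159    32.8909   0.0007     0.2967   ***
     QP -0.0077    17.2653   0.2307     0.0432
```

The slope column is the change in mean RBAI in %-points per year: beech
(FS) and pine (PS) decline significantly, fir (AA) is flat — the pattern
the generator encodes (the fitted FS slope is shallower than the configured
−0.029 base trend because the twelve drought-year dips are not part of the
linear signal). Step 05 reports the ordination:

```
PC1 explains 50.48%, PC2 7.18% of dry-year RBAI variation (215 plot-species rows)
     variable  r2_pct  p_value mark
  elevation_m 13.6716    0.001    *
```

with elevation the dominant significant fitted vector (alongside the annual
temperature and precipitation normals that the lapse rates tie to it).

The same stages are available as one reproducible command over any input
tables (`rbai run --config pipeline.yaml`), with a manifest of input
checksums and the seed; identical configurations give byte-identical
outputs.

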