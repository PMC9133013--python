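# Methods

## Problem and model

`nrloss` builds a gridded inventory of reactive-nitrogen (Nr) loss from
fertilized wheat in five pathways (NO, N2O, NH3, NO3- leaching,
dissolved runoff). The causal chain is: paired field experiments give
pathway emission factors `EF = (E_treatment − E_control) / N_applied`
(a fraction of applied N, with the zero-N control subtracting
background loss); environmental covariates explain EF variation;
per-pathway regression models transfer EFs to grid cells; surveyed
county-mean application rates, kriged to cell centers, supply
`N_applied'`; and per-cell losses are `E_ij = N_applied'_j · EF_ij`,
summed over the five pathways into the total. The total is defined as
the sum of exactly five pathway terms; one published statement of the
sum also lists a sixth term, which we treat as a typographical slip
since the pathway index is defined as 1–5 throughout.

EFs are stored as fractions everywhere inside the package and rendered
as percent only at reporting boundaries, because summaries mix EF (%)
with losses (kg N ha⁻¹).

Negative EFs (control loss exceeding treatment loss) are retained by
default: the estimator is signed and clipping would bias small EFs
upward. A `clip_negative` policy flag exists for workflows that require
nonnegative factors. Model predictions are likewise not clipped; being
leaf-mean averages they are automatically bounded by the training-EF
extremes.

## Screening and imputation

Four exclusion criteria are applied in a fixed order (partial-season
experiments; greenhouse/laboratory experiments; missing zero-N control;
manure, controlled-release fertilizer or inhibitor treatments), and a
rejection names the first failing criterion so reports are
deterministic. Records with missing metadata are rejected as
"unscreenable". Missing covariates can be filled by source precedence —
weather from a climate lookup, SOC and total N from a soil-fertility
lookup, the remaining soil properties from a soil-survey lookup — with
imputed fields flagged; a field absent from both record and lookup is a
hard error naming the field. Multiple N-rate treatments within one
study yield one record per treatment (observations, not studies, are
the unit).

## Redundancy analysis and factor selection

Each pathway's response is its single EF column (the per-pathway
datasets have different rows, so a joint multi-response ordination is
impossible); RDA then reduces to regressing the centered response on
the standardized covariates and reading explained variance off the
fitted values, which for one response equals the multiple-regression
R². Explanatory columns are standardized because units are mixed (%,
mm, °C, g kg⁻¹). Marginal rates use one factor alone; conditional rates
come from greedy forward selection with ties broken by the canonical
covariate order, and they sum to the all-factor explained variance.
Selection stops when the added conditional rate falls below 1% — the
shipped preset ensembles have total explanatory rates of 97.8–100%, so
near-saturation is the expected regime. Because texture triplets sum to
100%, the full candidate set is nearly collinear; the selection path
therefore tolerates rank deficiency (minimum-norm least squares), while
a direct `RDA.fit` on collinear data raises and names the dependent
columns. The frozen per-pathway preset ensembles can bypass selection
entirely; the published ensemble for NO3- leaching lists "rainfall"
twice under two spellings, which we deduplicate.

## EF models

The regression forest is implemented in-package from its three-step
description: per node, draw k of the m candidate factors and take the
best variance-reducing split; grow n trees on bootstrap resamples;
evaluate on held-out data. Defaults are n_trees = 500, k = ⌊m/3⌋
(floor 1), min_leaf = 5 — the conventional defaults for regression
forests. The randomness protocol (one generator per fit; per tree the
bootstrap indices, then node feature subsets depth-first, left before
right) is part of the API so that an exhaustive-search oracle can
replay a fit exactly; a scikit-learn forest serves as an independent
cross-check in the tests, not as the implementation.

Data are shuffled into 10 near-equal parts (remainder spread over the
first parts), 7 train / 3 test; repeated runs re-partition and re-train
with seed = base_seed + run index, and performance is the mean over
runs (full scale: 500 runs). The per-record spread of predictions
across runs is exported as the EF uncertainty source. The deployed
model per pathway is refit on the full table with a documented seed,
maximizing training data for grid prediction. EFs are fit
untransformed.

## Survey, variogram and kriging

Raw survey rows aggregate to county means (sample sd, n−1 denominator;
single-farmer counties carry a missing sd). The semivariogram uses the
Matheron moment estimator in 15 equal-width bins up to half the maximum
separation, fitted by pair-count-weighted least squares; the default
family is exponential (the interpolation method is prescribed only as
"kriging", and the exponential family is the common default for
regionalized agronomic rates). Ordinary kriging solves the standard
system with the unit-sum weight constraint per target, using the 16
nearest counties (a dense all-point solve is available and is the
oracle in tests); the kriging variance is returned alongside. Negative
interpolated rates are floored at zero with a logged count. Covariates
are sampled at cell centers; grids are north-up with cell-center
registration, and rasters round-trip bit-exactly through the ASCII
format (17 significant digits).

## Monte Carlo uncertainty

Grid-level N rates and EFs are drawn from normal distributions around
their point estimates — rate sd = CV × rate with CV defaulting to
0.258 (the grid-level CV of the emulated bottom-up survey), EF sd from
the repeated-run prediction spread (or a fixed CV). Draws are truncated
at zero by default because negative rates and EFs are unphysical; the
untruncated option preserves the normality assumption exactly, and is
what the closed-form product-CV check uses
(`cv² = cv₁² + cv₂² + cv₁²cv₂²` for a product of independents). Cell
errors are drawn independently (no spatial error correlation is
modeled). Two statistics are emitted because aggregation order is
genuinely ambiguous: the CV across draws of the grid-mean loss (which
shrinks roughly as 1/√n_cells under independence) and the mean per-cell
loss CV (which stays at the input-CV scale, 20–35% under defaults).

## Synthetic generator

The generator emulates three sources with known truth:

* **Corpus** — default per-pathway counts 121/383/185/188/64 (941
  records). Covariates are drawn region-conditionally for four
  agroecological zones (drier, alkaline north; humid, acid south);
  texture triplets are renormalized to 100 ± 0.5. Truth EF functions
  are smooth and monotone in their drivers — a weighted sum of
  standardized covariates through a logistic squashed into a per-pathway
  range bracketing published EF ranges (e.g. NO in [0.2%, 2.2%]);
  weights encode expected directions (NH3 rises with pH and
  temperature, leaching with rainfall and sand). Observation noise
  defaults to sd = 5% of the range width, a signal-to-noise chosen at
  design time so that well-specified models land in the reported
  0.66–0.80 R² performance band; `E_treatment` is reconstructed by
  inverting the EF equation and truncated at `E_control` unless
  negative EFs are explicitly enabled.
* **Survey** — 1,050 county centroids by default; rates are a
  transformed (log-normal) Gaussian random field with exponential
  covariance, guaranteeing positivity with mean 200 kg N ha⁻¹,
  between-county sd 40 and range 30 cells; the rate distribution is a
  configuration choice, not a claim about any real survey. Farmer
  counts follow a 3–10 villages × 30–120 farmers design.
* **Grid** — default 100 × 100 cells (a desk-scale stand-in for a
  ~230k-cell national 1-km mask), quadrant region partition, covariate
  layers = region mean + smooth random field + cell noise, and a mask
  activating exactly `round(0.7 · n_cells)` cells.

What the generator does **not** emulate: real geography and county
shapes, survey microdata and non-normal rate distributions, covariate
measurement error, spatially correlated EF residuals, and
pathway-correlated losses. Passing recovery tests therefore shows the
pipeline is self-consistent and statistically sound at realistic
signal-to-noise, not that real-world inventory values are reproduced.

## Numerical choices and problem sizes

* Split candidates are midpoints between distinct sorted values with
  both children ≥ min_leaf; ties favor the first drawn feature and the
  lowest threshold (1e-12 comparison slack).
* The kriging system adds no jitter by default; duplicate data
  locations raise unless `on_duplicates="jitter"` is chosen.
* Every generator and fit is seed-deterministic; pipeline stages log
  seed and config hash, and reruns with identical configs are
  byte-identical for deterministic stages.
* Standard desk-scale settings used by the test suite and
  `scripts/acceptance.py`: the full 941-record corpus, 20–50 repeated
  runs of 120-tree forests, a 40 × 40 grid with 200 counties, and 500
  Monte Carlo draws (10⁵ draws for the closed-form CV check). Full-scale
  settings (500 runs, 500 trees, 100 × 100 grid, 1,050 counties) are the
  package defaults.

## Known limitations

* Neighborhood kriging (n_max = 16) is exact only up to neighborhood
  truncation; the dense solve is available where exactness matters.
* The forest is pure Python/numpy; it is fast at corpus scale
  (hundreds of rows) but not tuned for millions of training rows.
* Summary means are unweighted cell means (every cell has equal area);
  area- or production-weighted summaries are out of scope, as are map
  figures and national totals in Gg.
* The explanatory-rate convention (share of total vs. constrained
  variance) is reported as share of total response variance; both
  coincide for single-response RDA up to normalization, but published
  "total explanatory rates" may follow either convention.
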