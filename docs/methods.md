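# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order the pipeline runs them.

## Data model

A *sample* is a station × depth-stratum × size-fraction triple; a *site*
is a station × depth pair. Read counts are clade × sample integer
matrices in two layers (metatranscriptome, metagenome), each carrying
per-clade covered gene length in kb and per-sample total diatom-mapped
reads. Environmental variables live at the site level: chlorophyll *a*
(mg/m³), iron (nmol/l), PAR, NH₄⁺, NO₂⁻+NO₃⁻, NO₃⁻ (µmol/l),
temperature (°C), nitracline depth (m), and the sampling-depth category
(0 = surface, 1 = DCM).

## Normalization and presence

Occurrence is read density per sequencing depth:
`occ = (reads / kb_covered) / diatom_total`. Zero reads map to zero
occurrence regardless of coverage; nonzero reads with zero covered
length are an error (undefined density). "kb covered" is read as the
covered length of the clade's genes in that sample and is emitted
directly by the synthetic layer; using total gene length instead is a
drop-in substitution of the `kb_covered` metadata column. Presence at
a site requires occurrence > 0 in at least one available size fraction;
since normalization preserves zeros, presence from raw and normalized
tables is identical (tested as an exact contract).

## Richness and family contrasts

Richness is the per-site count of present clades per family. The
cross-family association is a Pearson correlation per depth plus the
least-squares line of NRT2 richness on AMT1 richness. Depth contrasts
use *paired* one-tail t-tests over stations sampled at both depths
(pairing is the natural reading of a per-station comparison; an
unpaired variant is deliberately not offered). Degenerate paired
differences are handled by convention: all-zero differences give
t = 0, p = 0.5; a constant nonzero difference gives p = 0 in the
favored direction and 1 against it. The AMT1:NRT2 transcript ratio
sums each family over clades and size fractions per site and is masked
(not imputed) where the denominator family is absent; masked-site
counts are reported.

## Zero-adjusted dissimilarity

Bray–Curtis is computed after appending a dummy feature with a fixed
positive value to every sample: `d(x,y) = Σ|xᵢ−yᵢ| / (Σ(xᵢ+yᵢ) + 2·dummy)`.
This makes two all-zero samples identical (distance 0) rather than
undefined and damps distances among near-empty samples. The Sørensen
variant binarizes first (Bray–Curtis on presence–absence equals one
minus the Sørensen similarity). The dummy defaults to 1 on the
presence scale (a dummy clade present everywhere) and to the smallest
nonzero entry on the abundance scale; both are configurable since the
coefficient is used in the literature without a canonical constant.
Triangle inequality is not asserted anywhere — Bray–Curtis is not a
metric; symmetry, zero diagonal and the [0, 1] bound are.

## Clustering and BIOENV

Ward linkage is applied to the dissimilarity matrix via the standard
squared-distance update (the "Ward.D2"-style generalization, scipy's
`linkage(..., 'ward')`), which is the defensible Ward extension to
non-Euclidean input. The cut level is chosen by mean silhouette width
over a candidate range, ties broken toward smaller k (parsimony);
cluster labels are renumbered in order of first appearance so the
solution is deterministic. BIOENV exhaustively searches all non-empty
subsets of the candidate variables (constants excluded up front;
subset size capped at 12 with a warning beyond that — the standard
candidate set here is 9, so the search is exhaustive in practice),
scoring each by the Spearman correlation between Euclidean distances
on the z-standardized subset and the community dissimilarity. The
implementation is cross-checked against scikit-bio's independent
BIOENV in the test suite. PCA operates on the standardized subset with
a full SVD solver.

## Screens and exact tests

Correlation screens (Spearman by default) adjust raw p-values by
Benjamini–Hochberg across the whole screen and flag pairs by the dual
rule: adjusted p < 0.05 AND |coefficient| > 0.30 (a reported "> 30"
is read as a ×100-scaled coefficient; the threshold is configurable). Pairs
with < 4 paired observations or a constant member are reported with a
reason code, never silently dropped. The diatom–prokaryote screen is
deliberately *unadjusted* (masking at raw p ≥ 0.05 only), matching the
criterion it implements; it is anticonservative by design and documented as
such — under independence ≈ 5% of pairs stay unmasked. Diatom
responses come from the 20–180 µm fraction. Fisher's 2×2 test reports
the conditional maximum-likelihood odds ratio and the exact two-sided
p by minimum-likelihood summation; a zero margin gives p = 1 by
convention. A one-sided variant exists because the sidedness behind a
reported localization-proportion comparison is generally not
recoverable from rounded percentages (25% of 109 vs 13% of 107 round
to 27/109 and 14/107); the test is therefore validated against a full
hypergeometric enumeration oracle rather than any single reported p.

## Boosted regression trees

Stagewise stochastic gradient boosting of shallow least-squares
regression trees, written from scratch (numba-compiled split search
and routing):

- **Losses.** Bernoulli for presence–absence: init at the logit of the
  base rate, residual y − p, terminal values by a one-step Newton
  update Σ(y−p)/Σp(1−p) with the denominator clamped at 1e-4. Laplace
  for abundance: init at the median, residual sign(y − f), terminal
  value the in-bag leaf median of residuals. Occurrence is modeled
  directly (log1p is a caller-side transform if wanted).
- **Trees.** Tree complexity 5 means at most 6 terminal nodes, grown
  best-first (always splitting the leaf with the largest improvement).
  Minimum 10 observations per leaf. Split ties break to the lowest
  variable index, then the lowest threshold, making fits
  bit-reproducible given (data, config, seed); folds, bagging draws
  and all other randomness derive from one seed via named substreams.
- **Defaults.** learning_rate 0.005 (the conventional slow-learning range is
  0.001–0.005; the Elith-style heuristic — the largest rate yielding
  at least ~1000 selected trees — guides per-model choice),
  bag_fraction 0.5, 10 folds (stratified by class for Bernoulli),
  trees added in blocks of 50 up to max_trees 10,000, stopping early
  once the mean held-out deviance has not improved for 5 blocks.
  The selected tree count minimizes mean held-out deviance; the final
  model is refit on all rows at that count.
- **Relative influence** accumulates each split's squared-error
  improvement on its variable over all trees and rescales to 100.
  **Partial dependence** is the clamped-average construction (set the
  variable to g in every training row, average the link-scale
  prediction). **Simplification** drops the lowest-influence predictor
  while the reduced model's best mean CV deviance stays within one
  standard error (across folds) of the full model's.
- **Validation.** Bernoulli models: AUC of the cross-validated
  held-out predictions (rank statistic, ties at ½), pass cut 0.7.
  Laplace models: observed responses binned into quartiles and the
  Pearson correlation of bin index with the prediction, pass cuts
  p < 0.05 and |r| > 0.35. Binning the *observed* values is the
  adopted reading of "classed in quartiles"; the inverse reading is a
  one-line change at the call site.
- **Numerical caveat.** Training deviance is nonincreasing per stage
  up to a tolerance of 1e-5: with bagging, the Laplace leaf median is
  computed on in-bag rows only, so out-of-bag rows can raise the full
  training deviance by a sub-learning-rate amount (observed once in 20
  seeds at ~1e-6). Exact monotonicity would require abandoning either
  bagging or the median update.
- Rows with missing predictor values are excluded per fit and counted.

## Thresholding and warming projection

The MaxSens+Spec threshold maximizes sensitivity + specificity over
the midpoints of consecutive distinct predicted values plus the
extremes, under the strict rule "present iff p > t"; ties break to the
smallest threshold, and uninformative (constant) predictions return
the low extreme with a warning. Thresholds are computed on in-sample
full-refit predictions, matching a workflow that projects at the
sampled stations; CV-based thresholding is a flag away. Scenario
projection adds each increment (0, 0.5, …, 3.0 °C) to the temperature
column only, holding all other variables at observed values, and
reports the percentage of sites predicted present. Temperatures beyond
the training range are not clipped: tree ensembles plateau past their
outermost splits, which is the intended extrapolation behavior.

## Synthetic scenario generator

The generator emulates the statistical structure of the real design,
not its geography:

- **Design.** 65 stations, surface everywhere, DCM at 42 of 65 (a
  seeded station subset), four size fractions, 11 AMT1 + 12 NRT2
  clades. All defaults are configurable.
- **Environment.** A Gaussian copula over a latent per-station
  "latitude" axis: each continuous variable loads on the axis
  (temperature and PAR positively, macronutrients and chlorophyll
  negatively) and is mapped to its marginal range linearly or
  log-linearly. Planted latent correlations are products of loadings
  and stay ≤ 0.44, under the 0.6 selection cap used for the real
  predictors; the realized correlation matrix is checked after
  generation (hard error at n ≥ 100 rows, warning below, where
  exceedances are sampling noise). DCM rows get latent-scale offsets
  (colder, darker, more nutrient-rich, higher chlorophyll).
- **Counts.** Expected mRNA count = library size × expression scale
  (1e-6) × clade copy intensity (geometric spread 0.5–2) × niche
  response × the clade's Dirichlet-drawn size-fraction profile.
  Niche responses are logistic (up/down), Gaussian, or flat, cycling
  over drivers and kinds by default. The DNA layer replaces the niche
  response with its 0.25 power — gene copies track niches far more
  weakly than transcription. Counts are negative-binomial with size
  k = 1 (variance μ + μ²; Poisson available as the infinite-k limit).
  Library sizes are uniform on 2×10⁵–2×10⁶ diatom-mapped reads. The
  expression scale was set so that site-level presence spans roughly
  40–95% across clades, i.e. per-family richness varies over the site
  set the way observed richness maps do, and detection at the lower
  tail is genuinely stochastic.
- **KO tables.** Prokaryotic nitrogen-metabolism KO abundances per
  site: configured KOs share a driver (an environmental variable or a
  named clade's response surface, enabling exact planted
  cross-correlations), the rest are lognormal noise.
- **Truth.** The realized environment, expected-count surfaces, niche
  and copy parameters, and a presence map (expected site-level reads
  above 1) are recorded for recovery tests; regeneration from
  (config, seed) is bit-identical.

What the generator does *not* emulate: spatial autocorrelation, basin
structure, taxonomic composition below the clade level, compositional
coupling between clades, or the count distribution of the real
catalog (no public account of it exists; negative-binomial is the
standard overdispersed stand-in, and its choice is flagged here).
Passing recovery tests therefore demonstrates that the estimators
recover planted structure under realistic sparsity and overdispersion —
not that the real data meet these assumptions.

## Problem sizes used in tests and the acceptance script

Recovery experiments run at the design scale stated above: cluster
recovery on 60 stations (3 planted groups, 20 seeds), BIOENV on 100
sites with 9 candidates (20 seeds), boosted-tree driver recovery at
n = 300 with 9 predictors, learning rate 0.005, 10-fold CV and up to
1000 trees (20 seeds), warming projections on 80-station surface-only
scenarios (20 seeds). The end-to-end determinism check uses a
16-station scenario with two clades modeled. These sizes keep each
experiment's Monte-Carlo error comfortably inside the asserted margins
while the full suite stays desk-runnable.

## Known limitations

- The clade is the atomic unit: no per-unigene resolution, no
  sequence-level stages (identification, alignment, phylogenetics,
  localization prediction are upstream of this package's inputs).
- Warming scenarios perturb temperature alone; no multi-variable
  climate fields, no spatial autocorrelation correction, no BRT
  replicate ensembles.
- The cross-kingdom screen's lack of multiplicity control is faithful
  to the screening rule it implements but anticonservative; treat its unmasked
  entries as candidates, not discoveries.
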