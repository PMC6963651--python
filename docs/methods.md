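# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
known limitations.

## Abundance and biomass

A plot's community vector can be built on two bases: **stem count** (the
default — the minimal-information reading of "relative abundance") or
**basal area** (stems weighted by π·DBH²/4). Nothing downstream assumes
one or the other; the basis is recorded in the run metadata because CWM
and FDis values are only comparable within one basis.

Stem biomass uses the power law AGB = a·(DBH²·H)^b with DBH in cm and H
in m. Parameters are supplied per species, with an optional
plantation-level fallback row; no built-in constants are shipped, because
allometric parameters are site- and taxon-specific. The output mass unit
is whatever the parameter table implies and is treated as opaque. Stems
shorter than 1.50 m are measured at mid-height rather than breast height;
they go through the same functional form with their recorded diameter and
are counted in `n_mid_height` per plot so users can judge their weight.
Plot totals divide by the plot area (default 100 m², the 10 m × 10 m
design).

## Diversity indices

* **CWM**: Σ pᵢTᵢ. Bounded by the trait range; exact arithmetic, no
  tunables.
* **Single-trait dispersion**: Σ pᵢ|Tᵢ − CWM| / Σ |Tᵢ − CWM|. The
  denominator is the *unweighted* sum of absolute deviations, which makes
  the index equal exactly 1/n under equal abundances — a property the
  tests exploit. When the denominator is zero (one species, or all
  present species share the value) the index is defined as 0. Note the
  denominator convention is unusual relative to an abundance-weighted
  mean absolute deviation; it is implemented as stated and tested against
  hand evaluation.
* **FDis**: abundance-weighted centroid c = ΣAⱼxⱼ/ΣAⱼ, species distances
  zⱼ = ‖xⱼ − c‖₂, FDis = ΣAⱼzⱼ/ΣAⱼ. Traits are z-scored across the
  species pool first (toggleable; pool global by default, per-plantation
  selectable) because the 15 traits carry incommensurable units and raw
  Euclidean distance would be dominated by the large-unit traits.
  Distances are Euclidean only; Gower-distance variants are out of scope.
  FDis is invariant to splitting a species' abundance across duplicate
  rows and scales linearly with the (unstandardised) trait scale; both
  are property-tested against a brute-force loop implementation at 1e-12.

## Block compression

Correlation-matrix PCA is the default for both the soil and CWM blocks
(mixed units); covariance-matrix PCA is selectable. Eigenvector sign is
fixed by orienting each axis so its largest-magnitude loading is
positive — otherwise downstream path coefficients would flip sign across
linear-algebra backends. Axis retention uses Horn's parallel analysis:
1000 standard-normal tables of the observed shape by default, retaining
leading axes whose eigenvalue exceeds the simulated mean (95th percentile
selectable). Retention stops at the first failing axis.

## The path model

The model is recursive: a DAG over observed variables with mutually
uncorrelated residuals. For this class, maximum-likelihood estimation
decomposes into one least-squares regression per endogenous variable on
its parents, so the estimator here is closed-form equation-wise OLS on
z-scored columns — no iterative SEM optimizer. This is exact for the
implemented model class and is documented as a deliberate limitation:
latent variables, correlated residuals and non-recursive graphs are not
supported.

The model-implied covariance is Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ with B the path
matrix and Ψ holding the exogenous (co)variances and the residual
variances (divisor n−1, matching the sample covariance S, so a saturated
model reproduces S exactly and χ² = 0). Fit statistics:

* χ² = (n−1)·F_ML with F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − v;
* degrees of freedom = v(v+1)/2 − (paths + exogenous (co)variances +
  residual variances);
* GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²];
* CFI against the diagonal (independence) baseline;
* SRMR on the correlation scale over the lower triangle including the
  diagonal;
* AIC in two labelled conventions — χ² + 2k and −2logL + 2k — because
  software packages differ and the absolute value is data-dependent.

Per-path p-values come from the equation-wise t-tests. Effect
decomposition enumerates every directed chain from source to target;
each indirect contribution is the product of the coefficients along one
mediating chain, and the total is the sum over all chains including the
direct edge. This chain enumeration is property-tested against the
reduced-form oracle (I−B)⁻¹ − I on random DAGs. Standard errors for
indirect and total effects use the delta method with a block-diagonal
coefficient covariance (per-equation OLS covariance; coefficients from
different equations treated as independent, which is the standard
Sobel-type approximation for recursive models). These p-values are one
defensible convention among several and are labelled as such. No
multiplicity correction is applied to reported p-values; a
Benjamini–Hochberg flag exists in the bivariate layer for users who want
it.

## Random-forest importance

The ensemble is a bagging loop over unpruned CART regression trees
(variance-reduction splits, `min_leaf = 5`, `mtry = ⌈p/3⌉` predictors per
split — common regression-forest defaults), with the bootstrap and
out-of-bag (OOB) bookkeeping done explicitly. Defaults are 5000 trees and
500 response permutations; test and demonstration runs use reduced
ensembles (tens to hundreds of trees, 99 permutations), which is the
package's own choice of problem size for quick iteration.

**%IncMSE** permutes predictor j within each tree's OOB rows, records the
increase in that tree's OOB MSE, averages the increase over trees, and
expresses it as a percentage of the forest-level OOB MSE. This differs
from the z-score-scaled variant some packages print; the unscaled mean
increase is the more interpretable quantity and the ranking is what
matters downstream.

**Significance** permutes the response (the global null "no predictor
matters"), re-grows the full forest per permutation, and uses the add-one
estimator p = (1 + #{null ≥ observed})/(n_perm + 1), which cannot be
zero. Per-predictor conditional permutation schemes are out of scope.
The OOB pseudo-R² (1 − OOB MSE / var y) is reported separately from
importance and is not conflated with it.

## Synthetic generators

**Structural generator.** Draws rows of (soil, FD, SR, CWM, AGB) from
the standardised recursive model with default coefficients
soil→FD 0.52, soil→SR −0.18, soil→CWM 0.17, soil→AGB 0.20, FD→AGB 0.49,
SR→AGB 0.40, CWM→AGB 0.26. Residual variances are derived from the
DAG-implied covariance of each variable's parents (not from an
independence assumption), so every column has unit population variance
and the generated R² matches the model-implied value (≈ 0.58 for AGB
under the defaults). Coefficients implying R² ≥ 1 are rejected. The
closed-form implied covariance is exposed for tests.

**Community generator.** Emulates the inventory design: 4 plantation
types × 3 slope positions × 3 plots = 36 plots and a pool of 20 dominant
species. Species traits are log-normal with a shared "economics axis"
loading, producing the positive correlation block among SLA, LN, LP,
SRL, RN and RP that a leaf/root economic spectrum implies. A latent plot
fertility (plantation mean + slope offset + noise) drives soil chemistry
(log-normal, shared loadings so PC1 captures fertility), species
richness, and abundance evenness (the Dirichlet concentration rises with
fertility). Stem diameters are log-normal with a plot growth term that
increases with fertility, with the realized multi-trait dispersion of the
community (measured in the same z-scored trait space the pipeline uses),
and with richness — so the FD→AGB and SR→AGB relationships are positive
*by construction*. Heights follow an allometric log-log relation with
noise; stems below 1.50 m are flagged as mid-height measurements.

What the generator does **not** emulate: real species identities or
measured trait values; spatial autocorrelation among plots; measurement
error structure of field instruments; the negative soil→richness
relationship a particular site may show. Passing pipeline tests on
generated data therefore demonstrates the *machinery* (indices, fits,
decompositions, importance) under a known truth, not any claim about a
real landscape.

## Numerical choices and degenerate inputs

* All randomness flows from a single seed through explicit
  `numpy.random.Generator` objects; no global seeding; identical seeds
  give bit-identical outputs, including the forests.
* Constant trait columns are left centred (sd treated as 1) in
  standardisation rather than producing NaNs; constant columns under
  correlation PCA raise a degeneracy error naming the column.
* The 0/0 single-trait dispersion case returns 0; zero total abundance
  raises.
* Singular sample covariance, constant responses, and groups with fewer
  than two points raise typed errors that the CLI maps to exit code 3
  (degeneracy) or 2 (validation).
* Reported coefficients are rounded to a configured number of decimals
  (default 2) only at the reporting layer; all computation is full
  precision.

## Limitations

Plots within a plantation are pseudo-replicated; the models here (like
the bivariate layer's ANCOVA) do not model that dependence — a
mixed-effects extension would. The path model treats richness as
continuous. ANCOVA uses Type II sums of squares (a documented choice
where conventions differ). Bootstrap confidence intervals for indirect
effects are a noted possible extension; only delta-method intervals are
provided.
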