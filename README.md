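# forestbef

Trait-based biodiversity–ecosystem-functioning (BEF) analysis for forest
plot inventories. The package takes stem-level inventory tables, species ×
trait tables and plot-level soil chemistry and asks the classic BEF
question for a restored forest landscape: how much of the variation in
aboveground biomass (AGB) is carried by *functional diversity* (niche
complementarity), how much by *community-weighted mean traits* (the
mass-ratio hypothesis), how much by species richness, and how much by soil
fertility directly?

It is written for community ecologists who have plot data of the common
design — a few plantation types × slope positions × replicate plots — and
want the full chain from raw stems to a fitted structural model, with
every intermediate quantity inspectable as a CSV.

## What it computes

1. **Allometric biomass** — stem AGB = a·(DBH²·H)^b summed per plot, with
   species-level parameters and a plantation-level fallback.
2. **Community-weighted means** — CWM(t) = Σᵢ pᵢ Tᵢ for each of 15 leaf
   and root traits, with relative abundance pᵢ on a stem-count or
   basal-area basis.
3. **Functional dispersion** — single-trait dispersion
   Σᵢ pᵢ|Tᵢ − CWM| / Σᵢ|Tᵢ − CWM| ∈ [0, 1], and the multi-trait FDis:
   the abundance-weighted mean Euclidean distance of species to the
   abundance-weighted centroid **c** = ΣAⱼxⱼ/ΣAⱼ in z-scored trait space.
4. **Block compression** — correlation-matrix PCA of the soil block (SOC,
   TN, TP, TK) and the 15-trait CWM block, with Horn's parallel analysis
   deciding how many axes to keep.
5. **Recursive path model** — the five-variable model
   soil → {FD, SR, CWM, AGB}, {FD, SR, CWM} → AGB, fit by equation-wise
   least squares (exact ML for recursive models with uncorrelated
   residuals), with χ², GFI, CFI, SRMR, AIC, per-equation R², and the
   standardised direct/indirect/total effect decomposition with
   delta-method standard errors.
6. **Random-forest importance** — %IncMSE of each CWM trait for AGB from
   a bagged CART ensemble with per-tree out-of-bag permutation, plus
   permutation-based p-values from forests re-grown on shuffled responses.
7. **Bivariate layer** — OLS with R²/F, Type-II ANCOVA for plantation
   effects, one-way ANOVA for slope effects, Pearson correlations.

Because field data of this kind are rarely deposited, a synthetic-data
module generates (a) structural-level draws from the standardised path
model and (b) full community datasets with the study design — 4
plantation types × 3 slopes × 3 plots (36 plots), 20 dominant species
with correlated leaf/root economic-spectrum traits — so the whole
pipeline runs end-to-end without any download.

## Worked example

Simulate a 36-plot community and run every stage (a TOML config can scale
the forest down for a quick look):

```sh
cat > run.toml <<'EOF'
rf_n_trees = 500
rf_n_perm = 99
parallel_n_sim = 500
seed = 11
EOF
forestbef all --config run.toml --out outputs/
```

The run report (`outputs/report.json`) ends with the headline numbers;
with the config above it prints:

```json
"path_coefficients": {
  "soil->FD": 0.3,  "soil->SR": 0.69, "soil->CWM": -0.14,
  "soil->AGB": 0.24, "FD->AGB": 0.72, "SR->AGB": 0.16, "CWM->AGB": 0.07
},
"fit_indices": { "chi2": 4.09, "df": 3, "p": 0.252,
                 "gfi": 0.957, "cfi": 0.987, "srmr": 0.078 },
"r2": { "FD": 0.09, "SR": 0.47, "CWM": 0.02, "AGB": 0.83 },
"soil_pc1_pct": 65.7, "soil_axes_retained": 1,
"cwm_pc1_pct": 57.1,  "cwm_axes_retained": 1
```

Read this as: on this simulated landscape the model is not rejected
(χ² = 4.09 on 3 df, p = 0.25; SRMR < 0.08; GFI > 0.95), soil fertility's
first principal component explains 66% of the soil block, one axis is
retained for each block, and functional dispersion carries the strongest
standardised path into biomass (0.72), with the model explaining 83% of
AGB variance. `sem_effects.csv` decomposes every soil→AGB route
(direct, via FD, via SR, via CWM, total), and `rf_importance.csv` ranks
the CWM traits by %IncMSE with permutation p-values.

Each stage is also available as its own subcommand (`simulate`,
`biomass`, `diversity`, `pca`, `sem`, `rf`, `stats`) given its stage
inputs, and everything is importable as a library (`forestbef.pathmodel`,
`forestbef.diversity`, ...).

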