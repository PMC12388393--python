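# Methods

This note records the models, numerical conventions and design choices
behind `bloomnet`, in the order the pipeline runs them. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing
is quoted from elsewhere.

## Synthetic survey generator (`bloomnet.simulate`)

### Design being emulated

A two-region coastal survey: a bloom region (BR, 6 sites) and a non-bloom
region (NR, 9 sites), each sampled at surface/middle/bottom (S/M/B), i.e.
45 samples, with paired 16S (prokaryote) and 18S (microeukaryote) ASV
tables, a taxonomy table, and per-sample environmental metadata
(T, Sal, Depth, pH, DO, Chl-a, NO3, NO2, NH4, PO4, SiO3).

### Count model

Species abundances follow a log-normal rank model: taxon baselines
`mu_i` are sorted draws from N(0, `sab_sigma`=1.2), per-sample log
abundances add N(0, `sample_noise_sigma`=0.6) noise, and counts are drawn
Dirichlet-multinomially — proportions are Dirichlet-resampled at
concentration `dispersion`=2000 before multinomial sampling at a
log-normally jittered library size (`depth_per_sample`=50,000,
sigma=0.2). Row sums therefore equal the drawn per-sample depths exactly,
and tables are long-tailed and overdispersed relative to a plain
multinomial (a taxon at relative abundance p has Dirichlet pseudo-count
p·2000, so rare taxa are strongly overdispersed). The concentration was
chosen, together with the module calibration below, so that planted
rank-correlations survive counting noise; lower values (a few hundred)
wash out Spearman structure among sub-percent taxa.

### Bloom taxon

One eukaryote ASV (genus *Noctiluca*) receives an expected relative
abundance per region×layer cell: `bloom_taxon_fraction_surface`=0.96 in BR
surface, decaying by `bloom_layer_decay`=(1.0, 0.40, 0.34) with depth
(≈96% → 38% → 33%), and `nr_bloom_fraction`=0.20 in all NR layers. The
realized per-sample fraction is logit-normal around the cell expectation
(sigma 0.25); the non-bloom community is renormalised to the remaining
mass rather than deleted, so rarefaction behaviour stays realistic.
Measured over 20 seeds, the mean BR-surface fraction is ≈0.96
(test: within [0.90, 0.99]).

### Planted modules

`n_modules`=4 modules of `module_size`=8 prokaryote taxa share a latent
per-sample factor: member log-abundance = rank baseline + λ·g_m + ε with
ε ~ N(0, 0.25). λ is set from the target Spearman correlation
`module_rho` through the bivariate-normal link ρ_s = (6/π)·asin(ρ_p/2),
with the latent Pearson correlation pushed above the inverted target
(fraction 0.94 of the remaining gap) to absorb counting-noise attenuation.
Three further conventions matter and were calibrated jointly:

- members sit at moderate abundance ranks (offset 10) — high enough that
  counts carry the correlation, low enough not to dominate the table;
- the member baseline is recentred by 0.35 of the full log-normal mean
  correction: full mean-matching starves the median sample of counts
  (rank noise at the bottom of the abundance swing), no compensation lets
  surging modules take over the composition and anti-correlate modules
  with each other through closure;
- member idiosyncratic noise is small (0.25) so λ stays moderate.

Measured at 15 samples over 20 seeds: mean within-module Spearman ≈ 0.91
at `module_rho`=0.9, and within-module minus between-module mean ρ ≈ 0.9
(test: ≥ 0.5). The bloom taxon never belongs to a module.

### Regional richness deficit

A fraction `richness_deficit_br`=0.3 of each marker's taxa (excluding the
bloom taxon and module members) is given zero expectation in all BR
samples. Suppressed taxa are sampled with square-root abundance weighting:
bloom regions lose dominant shared taxa, not only rare ones, and it is the
loss of abundant taxa that moves abundance-weighted dissimilarities.
With uniform sampling the between-region Bray–Curtis contrast was weak and
seed-dependent (region PERMANOVA p between 0.001 and 0.03 on the
prokaryote table); with weighted sampling it sits at the permutation floor
across seeds, matching the clearly separated communities the design calls
for. BR-surface Shannon is stochastically below NR-surface (one-sided
Wilcoxon over 50 replicate simulations, p < 0.01). Note the deficit does
not by itself depress Pielou evenness of the prokaryote table — removing
taxa at random directions can even raise it; the strong planted evenness
signal is the eukaryote bloom dominance.

### Environment

Each variable has a per-region×layer baseline (the generator ships a
coastal bloom survey's observed cell means: e.g. surface NH4 851.8 vs
130.2 mg/L, PO4 72.8 vs 27.2 mg/L) and responds to the realized bloom
fraction multiplicatively:

    value = baseline · exp(beta · (bloom − center)) · exp(N(0, 0.08))

so concentrations stay positive and the driver is linear on the
analysis's log10 scale. An earlier additive response produced negative
concentrations that clipped at zero and destroyed the log-linearity.

The centering has two modes (`env_response_reference`):
- `"cell"` (default): the baselines are observational — the bloom's
  signature is already in them — so the response is centred on each
  cell's expected bloom fraction and only tracks within-cell residuals.
  This preserves the baselines' printed fold changes (surface NH4 ≈ 6.5×,
  PO4 ≈ 2.7× across seeds).
- `"global"`: baselines are treated as pre-bloom references and the
  response carries the full between-cell bloom signal; `flat_env_baseline`
  (all cells share the grand mean) implies this mode. This is the regime
  for driver-recovery experiments with a single planted driver.

Default `env_effect` is {NH4: 1.0, PO4: 0.6}; the keys with non-zero
effect are recorded as `true_env_drivers` in the ground truth. A fraction
`env_missing_frac`=0.05 of nutrient cells is set missing at random to
exercise mean imputation; region/layer are never missing.

### Taxonomy and fixtures

Lineages are drawn from small marine-taxon pools (Rhodobacteraceae,
Flavobacteriaceae, dinoflagellates, …); ~4% of low-abundance taxa are
organellar (16S) or metazoan/plant (18S) contaminants and ~3% are
phylum-unclassified, exercising every cleanup rule. `write_fixture`
writes five TSVs (two count tables, taxonomy with `d__…;g__…` lineages,
metadata, tidy ground truth) plus a SHA-256 manifest; `verify_manifest`
detects corruption.

## Preprocessing (`bloomnet.preprocess`)

Taxonomy filtering matches whole rank tokens case-insensitively (so
"Chloroplastida" is not a chloroplast hit) and is idempotent. Rarefaction
draws each row from a multivariate hypergeometric at the minimum row sum
(sampling without replacement); per-ASV means over 1,000 seeds match the
hypergeometric expectation. Venn-style shared-ASV counts use presence
(≥ 1 read) after filtering but before rarefaction, so totals do not
depend on the rarefaction seed; percentages are rounded to one decimal.
The red-tide classifier uses strict exceedance of 3×10³ cells/L —
boundary equality is `no_bloom`.

## Diversity (`bloomnet.diversity`)

Shannon uses natural logarithms so Pielou J = H/ln S is internally
consistent; J is reported missing for single-taxon samples. The rank-sum
test uses the exact null for pooled n ≤ 20 without ties, otherwise the
tie- and continuity-corrected normal approximation (both routes agree
with exhaustive enumeration in the tests; null rejection rate 0.05 ± 0.02
over 1,000 replicates). PCoA reports raw eigenvalues by default — no
Cailliez/Lingoes correction; percent explained divides by the positive
eigenvalue sum only, and a Lingoes correction is available by flag.
PERMANOVA uses the within/between partition of squared distances
(pseudo-F), seeded label permutations, and the add-one permutation
p-value, whose floor at 999 permutations is 0.001; the statistic is
cross-checked against scikit-bio's implementation. Fold changes in the
region×layer environmental comparison are ratios of arithmetic means with
pairwise-complete observations, rounded to one decimal.

## Constrained ordination (`bloomnet.ordination`)

Mean imputation strictly precedes the log10(x+1) transform, and every
imputed cell is flagged. All environmental variables are transformed
uniformly (including T, Sal, pH) rather than special-casing units. The
VIF screen removes the worst variable (first index on ties) until all
VIF ≤ 10, warning when n ≤ p. RDA centres response and predictors, takes
the SVD of the fitted values of the multivariate least-squares fit, and
reports R² = constrained/total inertia with the Ezekiel adjustment.

Forward selection implements the double stopping rule: the best
adjusted-R² candidate is admitted only if its marginal permutation p ≤ α
(residuals of the reduced model permuted, 999 by default) and the
cumulative adjusted R² does not exceed the full-model adjusted R². A
consequence worth knowing: when every non-selected candidate is pure
noise, the full-model adjusted R² sits at chance level relative to the
best single-variable model, and selection legitimately returns empty
roughly half the time — the reference R implementation behaves
identically (verified against vegan's `ordiR2step` on exported data).
Driver-recovery experiments therefore run in the `"global"` response
regime where the planted driver carries its full signal; there a single
planted NH4 driver at effect 2.0 is selected first in ≥ 95 of 100 seeded
runs.

## Networks (`bloomnet.network`)

Networks are built per region from surface samples only (BR n=6, NR n=9
by default), on the concatenation of the separately row-normalised
prokaryote and eukaryote relative-abundance matrices (16S and 18S depths
are not comparable). Abundance/prevalence filters and both edge gates are
strict inequalities. p-values come from the t approximation
t = ρ√((n−2)/(1−ρ²)); |ρ| = 1 maps to p = 0. No multiple-testing
correction by default (Benjamini–Hochberg behind a flag). At these sample
sizes the attainable Spearman grid is coarse: at n=6 the p < 0.05 gate
binds at |ρ| ≥ 0.829 and at n=9 at |ρ| ≈ 0.68, and the null edge rate is
of order 5% — so small-n networks are dense and noisy by construction,
node counts (driven by the richness deficit) are the robust BR-vs-NR
contrast, and edge counts fluctuate.

Community detection is Clauset–Newman–Moore greedy modularity
maximisation on |ρ| weights — signs annotate edges but do not enter the
objective, since modularity is undefined for negative weights. Isolated
nodes are removed before reporting, so node counts are connected nodes.
The greedy partition matches the exhaustive modularity optimum on a
bridged-clique benchmark, and recovers planted modules at mean adjusted
Rand index ≈ 0.99 over seeds; the known resolution limit of modularity
means a single spurious bridge edge occasionally (≈1 seed in 25) merges
two 8-node modules in a dense background, so recovery is assessed as a
mean over seeds, not per seed. Average path length averages over
connected ordered pairs only; the diameter is the maximum component
eccentricity; the clustering coefficient averages nodes of degree ≥ 2;
mean betweenness is pair-normalised, while keystone tables report raw
betweenness (ties broken by degree, then id) and never include
zero-betweenness nodes. Module reports extract the largest module with a
negative edge, the largest all-prokaryote module with a negative edge,
and every module containing the focal genus with the focal ASVs'
neighbours and edge signs.

## Pipeline (`bloomnet.pipeline`, `bloomnet.cli`)

One seed fans out to per-stage child seeds via `numpy.random.SeedSequence`
spawning, so a run is a pure function of (inputs, config, seed) and
stages can be re-run in isolation; repeated runs produce byte-identical
tables. Stage failures abort with the stage name, leave a `FAILED` marker
and keep partial outputs. Genus-level aggregation for RDA bins ASVs by
family;genus so unclassified genera in different families stay distinct.
Reports are plain TSV plus a text summary; no plotting dependency.

## Problem sizes in tests

The test suite runs the generator at its default design (45 samples,
300+150 taxa, depth 50,000) for recovery checks, a reduced design
(150+60 taxa, depth 8,000–10,000) for the 20-seed end-to-end loop, and
null calibrations at 1,000 replicates (12-sample PERMANOVA with 99
permutations; 10+10 rank-sum). These sizes were chosen to estimate each
rate to within its test tolerance.

## Known limitations

- The generator plants independent module factors and a single bloom
  latent; it does not emulate phylogenetic correlation, spatial
  autocorrelation between neighbouring sites, temporal succession, or
  sequencing artefacts (chimeras, denoising error). Passing recovery
  tests therefore demonstrates correctness of the estimators on data with
  the assumed structure, not robustness to every property of real reads.
- Compositional closure is a real feature of the generator (suppressing
  taxa inflates the rest), and co-occurrence edges inherit the usual
  caveat that relative-abundance correlations are not interaction
  estimates; compositionality-aware inference (SparCC-style) is out of
  scope.
- With 6 surface samples per bloom region, edge-level network quantities
  are dominated by the coarse attainable p-grid; treat them as
  descriptive, and prefer node-level and module-level contrasts.
- PCoA axes are reported against the positive-inertia denominator;
  strongly non-Euclidean dissimilarities (large negative eigenvalues)
  deserve the Lingoes flag.
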