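# bloomnet

Comparative microbial-community analysis for dinoflagellate-bloom amplicon
surveys. `bloomnet` is aimed at microbial ecologists who have paired
16S/18S ASV tables from a bloom-impacted region (BR) and a non-bloom
reference region (NR) and want the full comparative workflow as tested,
reusable code rather than a pile of one-off R scripts: taxonomic cleanup
and depth normalisation, α/β-diversity statistics, environment-constrained
ordination with forward selection, and signed Spearman co-occurrence
networks with module detection and keystone identification.

A first-class synthetic-survey generator emulates the study design of a
*Noctiluca scintillans* bloom survey — two regions (6 + 9 sites), three
depth layers, a bloom taxon at ~96% surface relative abundance that decays
with depth, elevated ammonium and phosphate tracking bloom abundance,
planted correlated taxon modules, and a bloom-region richness deficit —
and returns the planted parameters as a ground truth, so every downstream
stage is testable without any sequence download.

## Methods at a glance

- **Cleanup** (16S): drop ASVs with Chloroplast or Mitochondria at any rank;
  (18S): drop Metazoa and plant lineages (Rhodophyta, Streptophyta,
  Trebouxiophyceae, Ulvophyceae); both: drop phylum-unclassified ASVs.
  Libraries are rarefied without replacement to the minimum depth.
- **α-diversity**: observed richness S, Shannon H = −Σ pᵢ ln pᵢ, Pielou
  J = H / ln S; two-group contrasts by the Wilcoxon rank-sum test
  (exact null when n ≤ 20 without ties).
- **β-diversity**: Bray–Curtis d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), classical
  PCoA (Gower double-centering), and one-way PERMANOVA with
  p = (1 + #{F* ≥ F}) / (1 + n_perm) over seeded label permutations.
- **Constrained ordination**: Hellinger-transformed abundances
  (y = √(x/row sum)) against mean-imputed, log10(x+1)-transformed
  environmental data; VIF > 10 predictors removed iteratively; RDA with
  adjusted R² = 1 − (1−R²)(n−1)/(n−p−1); forward selection with the
  ordiR2step double stopping rule (marginal permutation p ≤ α and
  cumulative adjusted R² bounded by the full model's).
- **Networks**: per-region surface samples; ASVs kept at mean relative
  abundance > 0.01% and prevalence > 20%; edges where Spearman |ρ| > 0.6
  and p < 0.05 (both strict); Clauset–Newman–Moore greedy modularity on
  |ρ| weights; keystones ranked by betweenness centrality (zero-betweenness
  nodes are never keystones); GraphML export with module affiliations.

## Worked example

Run the whole pipeline on a synthetic survey (the defaults reproduce the
reference design) either from Python or the CLI:

```bash
bloomnet run config.yaml        # or: python -m bloomnet.cli run config.yaml
```

```python
from bloomnet import RunConfig, run_pipeline
from bloomnet.simulate import SimConfig

config = RunConfig(seed=42, output_dir="demo", simulate=SimConfig(),
                   n_perm=999, bloom_density_cells_per_l=2.8e4)
report = run_pipeline(config)
```

`demo/summary.txt` then contains (excerpt from this exact run):

```
Bloom classification at 28000 cells/L: bloom

Environmental comparison (BR vs NR per layer):
                mean_br  mean_nr  fold_change  p_value
S     NH4       845.875  130.871          6.5    0.000
      PO4        75.113   26.541          2.8    0.001

Alpha-diversity region tests:
                     mean_br   mean_nr  br_lower  p_value
prokaryote sobs     174.4444  242.3704      True   0.0000
eukaryote  shannon    2.1650    3.8535      True   0.0000

PERMANOVA (region):
            pseudo_f  p_value
prokaryote   11.9040    0.001
eukaryote    33.6364    0.001

Forward-selected drivers (eukaryote): NH4, NO3
  explained variation: R2 = 0.709, adjusted R2 = 0.696

Network comparison (surface, per region):
              br      nr  direction
n_nodes      257     414   BR_lower
n_edges     3824    4935   BR_lower
```

Reading this: the surface bloom region shows the planted 6.5-fold ammonium
enrichment, significantly lower richness in both markers, collapsed
eukaryote evenness under the bloom taxon's dominance, clearly separated
community composition (PERMANOVA at the permutation floor p = 0.001 for
999 permutations), ammonium recovered as an environmental driver of the
eukaryote community, and a smaller bloom-region co-occurrence network.
Per-stage TSV tables, keystone lists, focal-genus module reports and
Gephi-ready GraphML files are written next to the summary.

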