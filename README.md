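# cazymag

Genome-centric analysis of carbohydrate-active enzymes (CAZymes) in
collections of metagenome-assembled genomes (MAGs), built for surveys of
lignocellulose-degrading gut communities such as those of lower (LT) and
higher (HT) termites. The package takes pre-computed annotation tables —
MAG metadata with GTDB-style taxonomy and CheckM-style quality estimates, a
dbCAN-overview-style domain-call table, and signal-peptide predictions from
two predictors — and turns them into quality-filtered, threshold-validated,
functionally classified gene catalogs with the statistics needed to compare
lineages and hosts.

## What it computes

**Filtering and validation.** MAGs are retained when completeness ≥ 50%
and contamination < 10%; phyla with fewer than 5 MAGs are removed. A CAZyme
domain call is accepted when its HMM hit has e-value < 1e-15, score > 100
and coverage > 0.35 (all strict), optionally confirmed by a DIAMOND best
hit with e-value < 1e-15 and identity > 50%.

**Rule-based classification.** An activity-rule table maps each CAZyme
(sub)family to activity terms and a functional category (cellulase,
hemicellulase, ligninase, pectinase, chitinase). Subfamily rules override
family rules; any hemicellulolytic activity wins over co-occurring
endo-β-1,4-glucanase activity; GH3 is excluded outright and CE4 is excluded
unless its predicted substrates include acetylxylan; carbohydrate-binding
modules (CBMs) count only when linked to a categorized catalytic domain on
the same gene.

**Statistics.**

- Gene density `GD = 100 · g / N` (genes of a category per MAG, normalized
  by the MAG's N predicted genes) and genes-per-genome `GPG` per lineage.
- Differential family selection: per-family Kruskal–Wallis across phyla
  (midrank ties, Tukey-fence outlier removal within family × phylum cells),
  Bonferroni correction across families, adjusted p < 1e-4, intersected
  with the lignocellulolytic rule categories.
- Ordination: square-root transform, Wisconsin double standardization,
  Bray–Curtis dissimilarity, ANOSIM `R` and PERMANOVA (ADONIS) pseudo-`F` /
  `R²` with label-permutation p-values (add-one estimator; exhaustive
  enumeration for small n), centered PCA, and an optional UMAP adapter.
- Host-group comparisons: two-sample Wilcoxon rank-sum with effect size
  `r = |Z|/√n`; Spearman ϱ for GD–abundance relationships.
- Phylogenetic signal: Abouheif proximity matrix (product of inverse
  direct-descendant counts along the nodal path), global Moran's I /
  Abouheif permutation test, and per-tip local Moran indicators (lipaMoran)
  with conditional-permutation p-values.

**Synthetic communities.** `cazymag.simulate` generates MAG collections,
gene tables, rule tables and trees with planted, known structure
(negative-binomial family counts with phylum-specific fold changes, planted
QC failures and rare phyla, a planted LT/HT effect size, Gaussian-copula
GD–abundance correlation, planted trait clades), so every stage can be
verified against ground truth.

## Worked example

```python
from cazymag.simulate import SyntheticConfig, write_fixture_bundle
from cazymag.pipeline import RunConfig, run_pipeline

write_fixture_bundle(SyntheticConfig(seed=7, n_phyla=3, mags_per_phylum=12,
                                     family_pool_size=40, n_differential=5),
                     "bundle")
manifest = run_pipeline(RunConfig(
    mag_metadata="bundle/mag_metadata.tsv", overview="bundle/overview.tsv",
    signalp="bundle/signalp.tsv", phobius="bundle/phobius.tsv",
    rules="bundle/rules.tsv", tree="bundle/tree.nwk",
    output_dir="out", seed=3, n_permutations=99,
))
print([s["name"] for s in manifest["stages"]])
```

prints

```
['ingest_qc', 'classify', 'count_matrices', 'family_selection',
 'density_stats', 'ordination', 'phylo_signal', 'report']
```

and `out/report.json` records 32 retained MAGs for this bundle (36
generated, 4 planted to fail the completeness/contamination filter), the
per-family Kruskal–Wallis table, and the ANOSIM/PERMANOVA results on the
Bray–Curtis distances. The same stages are available as shell subcommands
(`cazymag simulate | qc | classify | densities | select | ordinate |
signal | report | analyze | run`).

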