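# Methods

This note documents the models, conventions and numerical choices behind
`cazymag`, and what the synthetic-data verification does and does not show.

## Inputs and filtering

The package consumes tables, not sequences. Gene prediction, HMM searches,
DIAMOND alignment, signal-peptide prediction, taxonomy assignment and tree
inference all happen upstream; their outputs define the input formats
(tab-delimited, UTF-8, one header row, `#` comments). Taxonomy strings are
GTDB-style with exactly seven rank slots; unknown extra columns are carried
through untouched.

Genome retention follows the standard survey policy with the boundary
semantics taken literally: completeness ≥ 50% (inclusive), contamination
< 10% (strict), and phyla with < 5 MAGs (strict) dropped. Because some
metadata tables are published post-filter, the quality filter can be
skipped (`skip_quality_filter`); the rare-phylum filter always recomputes
tallies from its input, which makes both filters idempotent.

Domain-call validation applies the dbCAN-style thresholds — e-value
< 1e-15, score > 100, coverage > 0.35 — as strict inequalities, matching
the symbols in which such thresholds are conventionally printed, as does
the DIAMOND confirmation (e-value < 1e-15, identity > 50%).

## Classification rules

Categories are driven by an activity-rule table (TSV: key, activities,
substrates, category) rather than hard-coded family lists, so users can
substitute their own curation. The engine's precedence order:

1. subfamily keys override family keys (GH5_4 vs GH5 — subfamilies of one
   family can carry different functions);
2. GH3 is always excluded: its β-glucosidases have too broad a substrate
   range to count as cellulases or hemicellulases;
3. CE4 is excluded unless the predicted substrates include acetylxylan, in
   which case it counts as a hemicellulase (acetylxylan esterase);
4. any hemicellulolytic activity ⇒ hemicellulase, even when
   endo-β-1,4-glucanase activity co-occurs (broad-specificity endoglucanases
   that also cleave xyloglucan act on hemicellulose in vivo);
5. an activity set consisting solely of classically cellulolytic activities
   (endo/exo-β-1,4-glucanase, cellobiohydrolase, cellodextrin/cellobiose
   phosphorylase, LPMO, β-1,3-glucanase) ⇒ cellulase;
6. laccase / peroxidase / aryl-alcohol-oxidase ⇒ ligninase; pectate lyase /
   pectin methyl- or acetylesterase ⇒ pectinase; chitinase / chitin
   deacetylase / acetylglucosaminosidase ⇒ chitinase;
7. anything else, including families with no rule, falls to "other"
   (logged, never a crash).

Secretion combines the two predictor flags; the combination rule is not
standardized, so it is configurable (`union` default for recall,
`intersection`, `signalp_only`). CBMs are never classified alone: they
attach to categorized catalytic calls on the same gene, and CBMs on genes
without such a call are dropped from all counts. Counting is per gene, not
per domain: a gene with two GH13 domains contributes 1 to (MAG, GH13), and
at category level a gene contributes once per distinct category.
Multifunctional genes spanning two categorized families yield one call per
family, all retained.

## Statistics

**Gene density and GPG.** GD = 100 · count / predicted genes, in percent;
it is completeness-robust because both numerator and denominator scale with
genome recovery. GPG divides a lineage's gene total by *all* of the
lineage's retained MAGs (not only carriers); a carrier-only denominator
would inflate sparse families.

**Family selection.** Counts are overdispersed and grossly non-normal
(the assumption checks — Brown–Forsythe Levene and Shapiro–Wilk on pooled
median-centered residuals — document this), so the cross-phylum test is
Kruskal–Wallis with midrank tie correction and a chi-square reference.
Outliers are removed per (family, phylum) cell with Tukey fences
(k = 1.5, linear-interpolation quartiles) — the most common convention
where "outliers were removed" is otherwise unspecified; k is configurable
and recorded in the manifest. Bonferroni multiplies by the number of
families tested in the run (the selection is per family; post-hoc pairwise
Mann–Whitney p-values are a separate, within-family matrix). The
lignocellulolytic subset keeps Bonferroni-significant families whose rule
category is cellulase, hemicellulase or ligninase; GT and PL class tokens
and CE4 are excluded (PL-based pectinases remain available through the
separate pectinase tally), and linked CBM families ride along via the
gene-level linkage.

**Ordination.** Transform order is sqrt → column (species) maximum → row
(site) total, the decostand/wisconsin convention. Bray–Curtis uses
d = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), with d = 0 for two all-zero rows
(vegan-compatible; logged). ANOSIM ranks the condensed distances with
midranks; R = (r̄_between − r̄_within)/(M/2). PERMANOVA partitions squared
distances by Huygens' theorem (SS_total = Σ d²/n; within-group sums per
group size), equivalent to the Gower-centered inner-product partition;
pseudo-F = (SS_B/(g−1))/(SS_W/(n−g)). Permutation p-values permute labels
with a mandatory seed and use the add-one estimator
p = (1 + #{≥ observed})/(1 + n_perm), so p is never 0; an exhaustive mode
enumerates all n! index permutations, under which p is exact. Both
statistics are verified against scikit-bio on shared distances. PCA is
centered, unscaled SVD with a deterministic sign convention (largest
loading positive). UMAP is a thin adapter over `umap-learn` (15 neighbors,
500 epochs by default); when absent the pipeline warns and continues.

**Host-group comparison.** LT and HT MAG sets are independent samples, so
the comparison is the two-sample rank-sum (Mann–Whitney) test — a
signed-rank test needs pairing, which genome sets do not have; a `paired`
flag exists for genuinely paired designs. Z uses midrank tie correction
and a continuity correction; the effect size is r = |Z|/√(n₁+n₂), the
`wilcox_effsize` convention. Spearman ϱ uses midranks with the two-sided t
approximation.

**Phylogenetic signal.** The Abouheif proximity is
W[i,j] = Π 1/ndd(node) over the internal nodes on the nodal path between
tips i and j (the oriAbouheif convention, the default in the phylosignal
ecosystem); the matrix is exported for inspection. W is row-normalized
before Moran computations (raw-W mode exists for cross-checks). Global
I = (n/S₀)·zᵀWz/zᵀz; with row-normalized W the local indicators
Iᵢ = n·zᵢ·(Wz)ᵢ/zᵀz satisfy Σᵢ Iᵢ = n·I exactly, which the tests assert to
1e-10. The Abouheif test permutes trait values across tips (one-sided,
upper tail); local p-values use conditional permutation with the focal
value held fixed. Signal can be evaluated on the global tree or per-phylum
subtrees, since reporting is usually per phylum.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes —
not sequences, reads or alignment scores:

- **Family counts** are negative-binomial (size θ = 5 by default), because
  real per-MAG CAZyme counts are overdispersed across lineages; baseline
  per-family means are lognormal around 2 genes/MAG. Differential families
  (default 20 of 200, drawn from the lignocellulolytic categories) have
  their mean multiplied by a fold change (default 4×) in one designated
  phylum.
- **Community shape**: 5 phyla × 60 MAGs by default, plus planted rare
  phyla (2 and 3 MAGs) and a planted 10% QC-failure fraction, so the
  filters have exact known targets. Gene totals are lognormal around 2,000
  genes (σ = 0.2).
- **Gene tables** emit one overview row per domain hit with e-value/score/
  coverage drawn inside the validation region; a controlled fraction of
  extra genes fails exactly one threshold and must vanish downstream.
  Secretion flags are Bernoulli (0.6) with 80% predictor agreement; some
  categorized genes carry a linked CBM, and orphan CBM-only genes are
  planted to exercise the linkage drop rule.
- **Host-group effect**: the target rank-sum effect size r is converted to
  a latent-normal shift through r = √(12·q(1−q))·(AUC−½) and
  AUC = Φ(δ/√2); cellulase totals are a monotone negative-binomial
  quantile transform of the latent variable (scaled by each MAG's gene
  total so GD stays monotone in the latent), then split across cellulase
  families multinomially. Because rank statistics are invariant under
  monotone maps, the planted AUC — hence r — carries over exactly up to
  count ties.
- **GD–abundance correlation**: a Gaussian copula couples the rank of
  cellulase GD to the lognormal abundance marginal within designated
  phyla, with the Pearson parameter set by ρ_P = 2·sin(πϱ/6) so the target
  Spearman ϱ is planted independently of the marginals.
- All randomness derives from one master seed through SHA-256-named
  substreams, so each table is reproducible in isolation and bundles are
  byte-identical across reruns; a manifest with file checksums detects
  tampering.

What passing these tests shows: the pipeline recovers planted structure of
the kind the analysis assumes (NB counts, monotone host shifts, copula
correlations, clade-elevated traits) at realistic sizes. What it does not
show: robustness to annotation error modes the generator does not emulate
(chimeric genes, miscalled families, fragmented MAGs inflating gene
counts), nor anything about compositionality of relative abundances.

A separate metadata-only roster reconstructs the phylum-tally *structure*
of a large published termite-gut survey (2,223 MAGs, 22 phyla, 19 MAGs in
7 rare phyla) so the retention replay has a fixed, survey-scale target
(2,204 MAGs in 15 phyla, including one phylum at exactly the 5-MAG
boundary); the per-phylum proportions are illustrative, the totals and
rare-phylum structure are the replay target.

## Problem sizes and determinism

Verification problem sizes were chosen so the whole suite runs in well
under a minute on one core: selection recovery at 300 MAGs × 200 families;
effect-size recovery at n = 200; correlation recovery at n = 300;
ordination at 200 MAGs; calibration with 1,000 replicates (199 permutations
per replicate for the Abouheif test, whose p-value granularity at 199
permutations places the 0.05 rejection boundary exactly). Permutation
seeds are mandatory arguments throughout; pipeline reruns with identical
config and inputs produce identical output checksums, which the manifest
records.

## Known limitations

- The activity vocabulary ships with a curated but deliberately compact
  term set; dbCAN-sub emits a wider range of free-text activities, which
  users should map onto the vocabulary (or extend the rule table) before
  classification.
- One-way ANOSIM/PERMANOVA only; no multi-factor ADONIS models or strata.
- The exhaustive permutation mode enumerates index permutations (n! up to
  n ≈ 8); beyond that, seeded Monte Carlo with the add-one estimator.
- Abouheif proximity uses topology only (no branch lengths), as the
  oriAbouheif definition prescribes; branch-length-aware alternatives
  (Pagel's λ, Blomberg's K) are out of scope.
- GPG and GD treat every retained MAG of a lineage equally; no
  completeness-based rescaling is attempted.
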