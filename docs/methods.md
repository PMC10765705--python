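# Methods

## Normalized phylogenetic profiles

The conservation matrix starts from best-BLAST-hit bitscores of each
gene against each species in a eukaryotic genome panel, plus each query
protein's self-hit bitscore. For an observed hit the value path is
`v = log2(best_hit / self_hit)`; each species column is then z-scored so
that overall phylogenetic distance to the reference proteome does not
dominate row correlations. Choices within that path:

- **z-score denominator.** Sample standard deviation (n−1), the
  convention of standard scaling routines; recorded in the matrix
  metadata (`zscore_ddof`). The column-invariant tests check mean 0 and
  sd 1 under this convention at 1e-9.
- **Ratios above 1.** A database hit can out-score the self-hit (e.g.
  low-complexity artifacts). The ratio is clipped at 1 (log2 value 0)
  and the count reported in metadata.
- **Missing hits.** An absent ortholog must sort below every observed
  one, so imputation happens before z-scoring: `floor_epsilon`
  (default) fills with the column minimum of the log2 values minus 1;
  `column_min` fills with the column minimum itself. A column with no
  observed hit, or zero variance after imputation, is an error naming
  the species.

## Clade-wise co-evolution

Co-evolution between two genes is the Pearson correlation of their
matrix rows. Correlations are computed over all species ("Eukaryota")
and within named clades of the eukaryotic tree (the canonical 16-clade
panel is provided; user-supplied clade tables are accepted), because
functional linkage often leaves a correlation signal only in part of
the tree. Per query gene and clade the top *k* partners are retrieved
(default k = 50, a tuned retrieval depth; the synthetic benchmark uses
k = 10 to match its module size) and the per-clade lists are merged,
keeping each unique partner's best (lowest) rank and the clade
achieving it.

Open choices resolved here:

- **Ortholog presence.** A clade participates when the query has an
  observed best hit in at least `min_species` of its species, default
  `max(3, ceil(0.10 · clade size))` — Pearson needs ≥ 3 points, and the
  10% floor guards against spurious single-hit clades.
- **Column set for correlation.** Full clade columns of the fixed
  imputed matrix (not pairwise-complete observations), so every
  correlation refers to the same matrix.
- **Ties.** Equal correlations break lexicographically by gene id;
  equal best ranks across clades break by clade-name order. This makes
  rankings reproducible across platforms, and top-k lists are prefixes
  of larger-k lists.

## Phenotype semantic similarity

Information content is annotation-frequency based with ancestor
propagation: `IC(t) = −ln(n_t / N)` where `n_t` counts genes annotated
to `t` or any descendant, in natural log. Terms annotating no gene get
the maximum observed IC by default (configurable to exclusion). The
ontology is read from OBO via obonet, using is_a edges only; alt_ids
resolve to primary ids at load and unresolvable terms are errors, never
silently dropped.

Term-pair similarity is Lin's measure through the most-informative
common ancestor; set similarity is the best-match average, symmetrized
by averaging both directions so the (patient, gene) order is
irrelevant. Scores are in [0, 1] and the entire annotated universe is
always ranked — in practice there is no defensible score threshold
separating "phenotype-related" from unrelated genes, and the downstream
enrichment test consumes the whole distribution. A Resnik-based product
scorer (each query term's best-match IC, max-normalized, multiplied) is
available opt-in; on toy universes it agrees with Lin/BMA on the top
gene.

## One-sided KS enrichment

With sample *i* (the candidate's co-evolved or interacting genes, their
phenotype scores restricted to the ranked universe, duplicates counted
once) and reference *j* (all ranked genes), the statistic is
`D⁻ = max(0, sup_x [Fj(x) − Fi(x)])`, evaluated over the pooled unique
score values with right-continuous ECDFs — the sup of a step-function
difference is attained there, and ties are handled by the discrete
evaluation. `D⁻` is invariant under strictly increasing transforms of
the scores.

Two p-value routes:

- **Asymptotic** (default for pooled sizes above 16):
  `p = exp(−2 D⁻² nm / (n+m))`, the standard one-sided two-sample tail
  bound and the formula R's `ks.test` applies for one-sided two-sample
  alternatives. It is mildly conservative at moderate sizes because
  `D⁻` is discrete; the calibration test (sample of 30 drawn from a
  500-value universe, 1,000 replicates) observes a type-I rate of about
  0.035 at the 0.05 level.
- **Exact permutation** (pooled size ≤ 16, or forced): full enumeration
  of all `C(n+m, n)` label assignments, vectorized; this is the
  reference the asymptotic route is tested against.

Per candidate, a source with fewer than `min_overlap = 3` genes in the
ranked universe is skipped (the combination adapts its degrees of
freedom); a candidate with no usable source is flagged `no_evidence`
and placed last with p = 1 rather than dropped.

## Combining p-values and ranking

Fisher's method: `X²₍₂ₖ₎ = −2 Σ ln pᵢ` against chi-square with 2k df.
Component p-values are floored at 1e-300 (with a warning) before the
log; p = 0 input is an error. For k = 1 the combination is the identity
— the df = 2 survival of `−2 ln p` is exactly p — which anchors the
closed-form tests. Simes' rule `min_i k·p₍ᵢ₎/i` is available as an
alternative combiner. Candidates are ranked by raw combined p-value
ascending (ties lexicographic); no multiple-testing correction enters
the ranking, though a Benjamini–Hochberg column is emitted alongside.

## Variant filtering

Class, frequency, and deleteriousness rules under an inheritance mode
(see the module docstring for the full rule set). Notable decisions:

- **SIFT cutoff 0.5.** Implemented as stated in the filtering rule set;
  the conventional deleterious cutoff is 0.05, so `--sift-cutoff` (and
  the `sift_cutoff=` argument) can override it.
- **Missing scores pass.** Truncating variants carry no missense
  predictions; a variant is excluded only when affirmatively predicted
  benign, and a variant with no frequency record is treated as novel.
  When several frequency sources are present, all must pass.
- **Compound het without phase.** Two or more distinct passing
  heterozygous variants in one gene qualify it under the recessive
  model (single-proband practice; no trio phasing).

The filter is monotone — relaxing any threshold can only add genes —
and every surviving gene's supporting variants individually pass all
three predicates; both are property-tested.

## Interaction networks

STRING-style `(gene1, gene2, combined_score)` TSVs; the 0–1000 integer
dialect is auto-detected (any score > 1) and divided by 1000. Default
threshold 0.5 = medium confidence, threshold filtering is monotone,
duplicate edges keep the maximum score, self-edges are dropped, and an
optional alias table maps protein ids to gene symbols (unmapped edges
dropped with a count). Only the combined score is modeled, not the
individual evidence channels.

## Synthetic data and the spike-in benchmark

The generator emulates the statistical structure the method relies on,
not the biology of real inputs:

- **Matrix.** Background log2 ratios are i.i.d. `N(−4, 1)` clipped at
  0; module genes share a latent per-species factor
  (`√ρ·f_s + √(1−ρ)·ε`) within their clades, giving pairwise
  correlation ρ. With clade-restricted modules the member genes have no
  hits outside their clades, emulating clade-restricted gene families.
  Per-column z-scoring slightly attenuates planted correlation when the
  module is a sizable fraction of the gene universe (the column mean
  absorbs part of the shared factor); at realistic module fractions the
  attenuation is within the Monte-Carlo tolerance, and the generator's
  construction is verified on the raw log2 ratios.
- **Ontology.** A layered random DAG (single root, 1–2 parents per
  term); genes draw 2–4 terms, and one designated leaf annotates
  exactly one gene so realized ICs span 0 to ln(n_genes).
- **Patient.** One planted passing variant in the causal gene, one
  passing variant per decoy, and filter fodder engineered to fail the
  class, frequency, and deleteriousness rules in equal parts. The HPO
  query is the term set carried by the annotated fraction of the
  causal gene's module partners; the same fraction of partners links to
  the causal gene in the synthetic network.

Default scenario scale — 320 genes × 120 species, 4 clades plus
Eukaryota, 240-gene annotated universe, module of 10 restricted to two
clades, 20 decoys, k = 10 — was chosen once as the study condition: it
keeps one scenario near 0.1 s so hundreds run inside a routine test
session while leaving every stage (filtering, ranking, clade merging,
both KS sources, combination) non-degenerate. The benchmark metric is
the percentage of scenarios ranking the planted gene top-1/3/5/10 among
the surviving candidates; the null configuration (ρ = 0, overlap 0)
checks that the top-1 rate stays at the uniform 1/(n_candidates)
baseline.

What passing synthetic tests does **not** show: robustness to real
bitscore distributions (heavy tails, lineage-specific duplications),
real HPO term depth and annotation bias, correlated decoy structure in
real exomes, or identifier-mapping noise between network and gene
namespaces.

## Known limitations

- The asymptotic one-sided KS p-value is conservative for small
  samples; the exact mode covers only small pooled sizes (enumeration
  grows combinatorially).
- Fisher's method assumes independent components; co-evolution and
  network evidence overlap for well-studied genes, making combined
  p-values optimistic in that regime (the ranking, not the absolute
  p-value, is the intended output).
- Compound-het detection is unphased and will count two variants on the
  same haplotype.
- IC values depend on the annotation corpus supplied; rankings from
  different corpora are not comparable.
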