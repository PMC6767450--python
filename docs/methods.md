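# Methods

This note documents the models, algorithms and design choices behind
`triovar`, and what the synthetic data used in its tests does and does not
establish.

## Problem setting

Rare Mendelian disease diagnostics from whole-exome sequencing of a family
or parent–child trio. Inputs are a multisample VCF with per-sample GT, DP,
GQ and AD; a 6-column PED pedigree; a per-variant annotation table; and
optionally a set of patient HPO terms plus a gene↔HPO map and ontology.
Output is a ranked candidate list of putatively causal variants.

## Variant representation

Coordinates are 1-based as in VCF; indels keep the VCF anchor base; a
variant's identity is the 4-tuple (chrom, pos, ref, alt) with `chr`
prefixes stripped. Multi-allelic records are decomposed into one record
per alternative allele before any analysis. When a sample carries a
*different* alternative allele at a decomposed site its genotype is
recoded hom-ref for that record and flagged `other_alt`, preserving the
information for compound-het reasoning. Half-missing genotypes (`0/.`)
are mapped to missing. Missing DP/GQ/AD are explicit `None` sentinels and
fail any enabled minimum-threshold filter; they are never silently zero.

## Pathogenicity classifier

A random forest of 1000 trees (scikit-learn `RandomForestClassifier`)
over an ordered 11-feature vector:

| # | feature | range | missing-value policy |
|---|---------|-------|----------------------|
| 1 | max population AF (1000G, gnomAD) | [0,1] | 0 (novel) |
| 2–3 | PhastCons primates / mammals | [0,1] | neutral median |
| 4–5 | PhyloP primates / mammals | ℝ | neutral median |
| 6 | Condel | [0,1] | neutral median |
| 7 | CADD (Phred) | ≥0 | neutral median |
| 8 | Eigen | ℝ | neutral median |
| 9 | Mutation Assessor | ℝ | neutral median |
| 10 | segmental-duplication likelihood | [0,1] | neutral median |
| 11 | ABB score | [0,1] | neutral median |

Neutral reference values are the per-feature medians of the *negative*
training pool's present values — the expectation for a selectively
neutral variant — recomputed at training time and persisted inside the
model file, so imputation at prediction time is always consistent with
training. Frequency is the one exception: absence from every population
database means the variant has never been observed, hence AF = 0.

Tree hyperparameters beyond the ensemble size follow the classic
random-forest defaults (⌊√11⌋ = 3 features per split, unlimited depth,
leaf size 1). Training uses stratified 5-fold cross-validation for the
reported out-of-fold AUC, then refits on all rows; class imbalance is
left unweighted by default (an optional `class_weight` is exposed). ROC
and AUC use the trapezoidal rule over all distinct thresholds. All
randomness flows from a single integer seed; two runs with the same seed
produce identical models, predictions and reports.

The default training design samples 15,000 pathogenic positives, 15,000
curated benign negatives and 100,000 random population variants (random
negatives sharing a key with a positive are excluded before sampling);
the synthetic pools used in tests are smaller (2,000/1,000/1,000) purely
as a matter of problem sizing.

## Segregation semantics

The five inheritance hypotheses are evaluated per variant over all
pedigree members (exhaustively pinned against an independent brute-force
enumerator in the test suite):

* **dominant de novo** — affected members het or hom-alt; unaffected
  members hom-ref; each affected member's in-pedigree parents hom-ref
  *with depth ≥ min_dp* (confident absence). Requires at least one
  affected member with both parents in the pedigree.
* **dominant inherited** — affected carry ≥ 1 alt allele; no unaffected
  member carries any.
* **recessive homozygous** — affected hom-alt; unaffected never hom-alt;
  each in-pedigree parent of an affected member is het (obligate
  carrier).
* **compound heterozygous** — a variant survives iff it participates in
  at least one *trans* pair in its gene: for every affected child with
  both parents present, the child is het at both sites, one site is
  inherited from the father only (father carries it, mother confidently
  hom-ref) and the other from the mother only. Cis pairs are rejected;
  variants in different genes never pair; de novo het calls (neither
  parent carries) have no assignable origin and do not pair.
* **X-linked** — chromosome X only; affected males hom-alt (hemizygous
  calls are represented as hom-alt) with het mother and hom-ref father
  when present; affected females hom-alt; unaffected males hom-ref;
  unaffected females not hom-alt. An affected member of unknown sex is an
  error.

A missing genotype in any member fails segregation by default (a variant
whose segregation cannot be established is not a safe candidate);
`tolerate_missing` relaxes missing calls to wildcards, and for
compound-het leaves both parental origins open for the missing parent.

## Quality/population filter

Lenient defaults, each independently disableable: max AF 0.01, per-member
DP ≥ 6 and GQ ≥ 20, excluded consequence classes {synonymous, intronic,
intergenic, 5'/3' UTR} after normalization to a closed refGene-style
vocabulary, segmental duplication ≤ 0.95, ABB threshold disabled. Every
removal is recorded with a reason (population frequency, consequence,
coverage, genotype quality, segmental duplication, ABB) and logged at
debug level. Relaxing any single threshold can only grow the surviving
set (tested as a monotonicity property).

## Phenotype relevance

For ontology DAG `O` (is-a edges), gene annotation corpus `G` and term
closure `anc(t)` (the term plus its transitive parents):

    IC(t)       = -log( |{g : t ∈ anc(terms(g))}| / |G| )
    score(Q, g) = Σ_{t ∈ anc(Q) ∩ anc(terms(g))} IC(t)
                / Σ_{t ∈ anc(Q) ∪ anc(terms(g))} IC(t)

The root is annotated to every gene, so IC(root) = 0 and two sets sharing
only the root score 0; identical closures score 1. Terms annotated to no
gene get the IC of a singleton annotation (-log(1/|G|)) rather than an
infinite value. Unknown query terms are dropped with a warning; an empty
query is an error; unmapped genes score 0. By default HPO acts as a soft
tier — matched genes sort above unmatched at any score — while
`--hpo-strict` drops unmatched genes entirely, trading recall for
precision.

## Ranking

Sort key: HPO tier (when a query is given and not strict), then
pathogenicity score descending, then max population AF ascending, then
(chrom, pos, ref, alt) with numeric chromosome order. Ranks are 1..n with
no gaps. "Run all modes" executes the five hypotheses, skips (with a
warning) any mode structurally inapplicable to the pedigree, and merges
candidates, recording every compatible mode per variant.

## Semisynthetic benchmark

Three trio modes are simulated — recessive homozygous, compound
heterozygous, dominant de novo — as these dominate trio diagnostics; the
other two filters are exercised by the enumeration tests instead.
Injection genotypes per mode: recessive child 1/1 with het parents; de
novo child 0/1 with hom-ref, zero-alt-read parents; compound het child
het at both sites with one het parent each, the carrier of the first site
chosen by a fair coin so trans phase is unbiased.

Read support: het alt reads ~ Binomial(dp, 0.5); hom-alt VAF ~
Beta(α, β) with α = 90, β = 10 by default (mean 0.9, mimicking the
reference-bias shift of real hom-alt calls; the distribution family is
standard for this purpose, the parameters are this package's choice and
configurable). Injected depths copy the nearest background variant on the
same chromosome (fallback 40×); clean simulated calls carry GQ 99.

The synthetic background trio draws founder genotypes from Hardy–Weinberg
at each variant's generated population frequency and lets children
inherit one allele per parent; sites where no member carries the
alternative allele are redrawn. An optional Mendelian-error rate writes
always-violating configurations (hom-ref parents, alt-carrying child) so
the realized violation count is exactly binomial at the configured rate.

The class-conditional feature generator encodes the qualitative contrasts
between pathogenic and benign coding variants: benign variants are common
to rare with a frequency floor of 10⁻³ and overlapping low-to-moderate
impact and conservation scores; pathogenic variants are novel (70%) or
ultra-rare (≤ 10⁻⁴) with upward-shifted conservation and impact scores.
Population frequency is by construction the cleanest signal, so the
trained forest ranks it first in importance, with the impact predictors
following. Per-cell missingness is 10% (benign) / 5% (pathogenic) on
non-frequency features.

## Evaluation metrics

Per mode: recall = fraction of cases whose causal variant appears in the
candidate list; mean false positives = average count of non-causal
candidates (both variants of a causal compound-het pair count as hits; a
gene-level toggle counts distinct non-causal genes instead); causal rank
= the better rank of the causal pair, excluded from summaries when the
case is missed. Medians/quartiles use the lower-value convention so every
reported quantile is an observed rank.

## Problem sizes and numerical choices

Tests and the acceptance script use 2,000 pathogenic + 2,000 benign
training rows, a 1,000-variant background, 100 spike-in cases per mode,
and 10,000 read-simulation draws — sizes chosen so the full suite runs in
minutes on one CPU while keeping every statistical check well-powered.
The permuted-label control compares the out-of-fold AUC with the analytic
Mann–Whitney null standard deviation √((n₊+n₋+1)/(12 n₊ n₋)). KS
comparisons of simulated VAFs add a ±1/(2·dp) uniform jitter to undo the
read-count discretization before comparing against the Beta cdf.

## What the synthetic data does not show

The generator reproduces directional class contrasts, not the empirical
joint distribution of real annotation databases: features are sampled
independently within class, so real-world correlations (CADD with
conservation, Condel with Mutation Assessor) are absent, and the
near-separable frequency contrast makes classification easier than on
curated clinical sets. Perfect recall and rank-1 medians on the synthetic
benchmark therefore validate the *mechanics* (segregation logic,
filtering, scoring, ranking, truth bookkeeping), not clinical
performance. The background trio is also idealized: uniform depth ~40×,
GQ 99, no genotyping error unless requested, and no linkage structure.

## Known limitations

* No structural/copy-number variants; SNVs and small indels only.
* X-linked logic ignores pseudoautosomal regions and X-inactivation
  skew; hemizygous male calls must be encoded as hom-alt.
* The compound-het origin rule requires informative parental genotypes;
  a truly de novo second hit never pairs.
* The HPO score substitutes a documented IC-weighted Jaccard for
  published gene–phenotype association methods; scores are comparable
  within one corpus, not across corpora.
* The annotation join is a local table; no live database lookups.
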