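# Methods

## Scope and data model

`genescape` implements two prioritization models over a shared gene
universe plus their comparison. All inputs are plain text (TSV edge lists
and evidence tables, GMT gene sets, YAML configs). No external databases
are downloaded; the synthetic module generates every input with known
ground truth, and a deterministic fixture reproduces the published
cardinalities of the ALS funnel and industry-target overlap using
synthetic gene symbols (`G0001`…) that carry no biological meaning.

## Evidence funnel

`compile_input_genes` unions per-study gene lists, retaining `(study,
data_type)` provenance per gene. `assign_colors` applies an ordered rule
cascade; a gene takes the earliest matching color:

1. ≥2 distinct evidence types → dark green;
2. gene-based GWAS association only, or a familial mutation → light green;
3. remaining single-evidence genes differentially expressed in disease
   tissue → yellow;
4. remaining genes with ≥ `k_min` (default 5) **distinct partners** in the
   rule-1–3 core set → blue (partner count, not edge count: parallel edges
   between a pair count once);
5. designated non-genetic additions → grey; everything else is excluded.

A grey designee carrying genetic evidence is an error, since grey is
defined as "not genetically associated". Differential expression is a
single boolean with provenance; tissue-resolved DE sets are an input
detail, not part of the rule.

`finalize_landscape` drops dark-green/light-green/yellow genes with no
interaction to another retained candidate and no shared-function group
membership (function groups are an explicit GMT input, not inferred);
grey genes likewise need ≥1 interaction; blue genes are retained by
construction. Removal iterates to a fixed point, so a gene whose only
partners were themselves removed is also removed and the operation is
idempotent. Stage sets are nested by construction:
core ⊆ candidate ⊆ candidate+grey ⊇ landscape.

Upstream-regulator enrichment is a generic hypergeometric upper tail
(`P(X ≥ k)` for overlap `k` of a regulator's target set with the input
list in a declared universe), Benjamini–Hochberg adjusted.

## Gene-based association test

For SNP Z-statistics `z` in a gene, `T = Σ z_i²`. Under the null
`z ~ N(0, R)` with `R` the LD correlation matrix, `T ~ Σ λ_i χ²₁` over the
eigenvalues of `R`. The default p-value inverts the characteristic
function of this mixture numerically (Imhof's formula, adaptive
quadrature, `epsabs 1e-10`); a single positive eigenvalue short-circuits
to the exact scaled chi-square. Satterthwaite moment matching
(`scale = Σλ²/Σλ`, `df = (Σλ)²/Σλ²`) is retained as a fast approximation:
it was measured to deviate from a Monte-Carlo oracle by tens of percent in
the far tail on random PSD matrices, which is why it is not the default —
the characteristic-function route stays within Monte-Carlo noise of the
oracle across p ∈ [1e-4, 0.5]. A seeded Monte-Carlo mode (add-one tail
estimate over draws of the eigenvalue mixture) provides an independent
refinement.

SNP→gene mapping uses 1-based closed intervals with a configurable
symmetric flank (default 0 kb: strictly within the gene). Multiplicity
control is Bonferroni `α/n_genes` by default — at `α = 0.05` over 19,427
protein-coding genes this is 2.57e-06 — with Benjamini–Hochberg as an
explicit alternative; the printed threshold arithmetic is Bonferroni even
where the source literature labels it FDR. P-to-|z| conversion uses the
two-sided inverse normal; the sign is unrecoverable and unused by `T`.

## Knowledge-graph scoring

Four direct channels per gene and subtype, each in [0, 1]:
`genetic_common = min(1, −log10 p / −log10 p_ref)` anchored at the
genome-wide threshold `p_ref`; `genetic_rare` = familial-mutation
membership; `transcriptomic = min(1, |effect|/cap)` for significant DE
(cap 5 standardized units); `aggregation` = membership in the subtype's
aggregate composition set. Mendelian-randomization evidence, when
available, folds into the common-genetics channel rather than forming a
ninth channel.

Diffusion is random walk with restart over the undirected
confidence-weighted gene–gene layer (rna–protein edges included with a
configurable weight multiplier, default 1): restart 0.5 by default, L1
convergence tolerance 1e-10, cap 10,000 iterations. Columns with zero
weight (dangling nodes under a confidence cutoff) teleport their outflow
back to the seed distribution so output mass is exactly 1 per seeded
component. Each channel's diffusion vector is max-normalized to [0, 1] so
the biorelevance mean (of the eight direct + diffused channels) is not
dominated by un-normalized walk mass. The identity of the eight channels
and the diffusion conventions are declared package choices; the governing
idea is the disease-module principle (disease genes cluster in interaction
networks, so network neighbors of evidence-bearing genes inherit
relevance).

Edge filtering: for each candidate confidence cutoff, leave-one-out over
the known disease genes — seed the remainder, diffuse, score the held-out
gene's AUROC against non-seed background genes (ties count half) — and
pick the cutoff with the highest mean AUROC, breaking ties toward the
stricter cutoff. A cutoff that removes every edge scores 0.5 with a
warning.

## Cross-model comparison

Scores merge by outer join over a declared universe; the default policy
zero-fills missing landscape scores so a genome-scale correlation is
defined (both policies are exposed). Correlation is Pearson with the
two-sided t-transform p-value. Group comparisons use two-sided
Mann–Whitney U — scores are bounded and non-normal — with exact
full-permutation enumeration when the smaller group has ≤8 observations
and the enumeration stays under 2×10⁵ splits (the permutation distribution
is computed from observed midranks, so ties are handled exactly), and the
tie-corrected normal approximation otherwise; Benjamini–Hochberg across
contrasts with star codes at 0.05/0.01/0.001/0.0001. The overlap analysis
reports all seven Venn regions of landscape/kg-top/industry, per-region
active-development proportions, and a Fisher exact test of active status
in the triple intersection versus industry-only targets. Development phase
is carried as an ordinal label without modeling.

## Synthetic data and benchmarks

* **Evidence lists**: per-study gene lists with controlled overlap
  fractions; the default panel is GWAS-dominant with four follow-up data
  types re-sampling 20% of earlier hits, sizes scaling with the universe.
* **SNP statistics**: per-gene Z-vectors are multivariate normal with
  block-exchangeable correlation `R = (1−ρ)I + ρJ` per block. The
  exchangeable (rather than autoregressive) choice gives closed-form
  eigenvalues `1+(m−1)ρ` and `1−ρ`, making the null analytically
  checkable. A per-gene non-centrality `ncp` shifts each SNP mean by
  `√(ncp/n)` so `E[T]` exceeds the null mean by exactly `ncp`.
* **Interaction networks**: a stochastic block model with a planted module
  (defaults 600 genes, 30-gene module, within-module edge probability
  0.3 vs 0.01 background). Edge confidences are Beta-distributed with the
  shape pair swapped inside the module (background Beta(2,8), module
  Beta(8,2)), mirroring database confidence semantics and giving the
  confidence filter a recoverable signal.
* **Module-recovery benchmark**: seeding 10 of the 30 module genes and
  diffusing at restart 0.5 must retrieve the remaining 20 with mean AUROC
  above 0.9 over 20 seeds, on the default network.
* **Confidence-filter benchmark**: the cutoff-selection check uses a
  sparser module in a denser, low-confidence background (300 genes,
  module 30, p_in 0.2, p_out 0.15, confidences Beta(1,9)/Beta(9,1), all
  module genes known). This is the regime where pruning has signal: at the
  default benchmark's 0.01 background density, unfiltered
  confidence-weighted diffusion is already near-perfect and cutoff choice
  is decided by noise.

All randomness flows from one root seed through named CRC-keyed
substreams, so identical configurations reproduce byte-identical outputs
across processes.

What the synthetic data does **not** emulate: real LD structure from a
reference panel (haplotype blocks of varying size and strength), realistic
degree distributions of curated interaction databases (scale-free tails,
study bias), literature-curation noise, or any biological identity of
genes. Passing benchmarks therefore demonstrate algorithmic correctness
and calibration under controlled conditions, not performance on real
cohorts.

## The deterministic fixture

Published work in this design reports only aggregate stage counts, so the
fixture pins exactly those: 753 input genes composed of 57 multi-evidence,
110 association/mutation-only, 77 DE-supported single-evidence, 82
interaction-rescued, 427 excluded, plus 14 grey additions; isolated genes
(11 dark green, 24 light green, 12 yellow) carry no edges and are removed
at finalization, leaving 293. The per-data-type composition of the 753 and
the identity of every gene are unconstrained by the source counts and are
fixed arbitrarily but deterministically. Scoring annotations are laid out
so exactly 49 landscape genes clear the default score threshold of 5, two
of which sit on the exclusion list (analogues of a too-generic hub and an
already-established gene), leaving 47 top targets; the exact weighting
behind the original 47-gene list is not recoverable from published
information, so only the threshold semantics and exclusion policy are
faithful. The overlap fixture likewise pins the published intersection
cardinalities (217/27/15/10); regions not constrained by those numbers
(e.g. the 90-gene landscape∩kg-only region) are deterministic free
choices.

## Known limitations

* The landscape scoring scheme (component definitions, unit weights,
  connectivity bands at degree 5 and 10) and the molecular-specificity
  thresholds (≥2 themes, ≥3 interactions) are declared defaults for an
  under-specified published procedure; all are overridable in config.
* The Mann–Whitney exact mode bounds enumeration size; a tiny group paired
  with a very large one falls back to the asymptotic mode.
* Diffusion treats the gene–gene layer as undirected; directed regulatory
  semantics are kept as annotations only.
* The gene-based test consumes provided LD matrices; it does not estimate
  LD from genotypes or a reference panel.
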