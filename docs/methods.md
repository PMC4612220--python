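# Methods

This note documents the statistical model, its assumptions, the tunable
parameters, the design decisions taken where the method leaves choices
open, and what the synthetic data generator does and does not emulate.

## Coordinates

All intervals are stored 0-based half-open internally. Every file
interface converts to the format's native convention: GFF3 and Circos
files are 1-based inclusive, BED is 0-based half-open. The region
distance `dist(r_i, r_j) = max{0, max(s_i, s_j) − min(e_i, e_j)}` is
evaluated in 1-based inclusive coordinates, so two regions separated by
a gap of g bases have distance g + 1, adjacent regions have distance 1
and overlapping regions distance 0. This distance is symmetric and
non-negative but is **not** a metric (no triangle inequality), which is
acceptable because single linkage only consults pairwise distances.

## From annotation to hits

Exons are taken from CDS features when present (CDS phase becomes the
frame offset), else from exon features with frame 0; only coding
sequence is translated, UTR-bearing exon features are used as-is when no
CDS exists. Features shared by several mRNAs are deduplicated by
(interval, strand, frame). Minus-strand exons are reverse-complemented
before translation; a trailing partial codon is dropped and internal
stop codons are kept as `*` — whether two peptides are homologous is the
aligner's judgement, not the parser's.

A bi-directional hit requires the exon pair to be reported in **both**
query directions with aligned intervals overlapping by at least one
peptide position on each exon. The merged footprint per exon is the
intersection of the two directions' intervals, and the merged e-value is
the maximum of the two — the conservative combination. Pairs seen in
only one direction are discarded (counted in the log). Multiple
reciprocal alignment pairs between one exon pair yield multiple hits;
one exon can therefore participate in several hits, several clusters
and several dendrograms, which is what makes duplications visible.
Hits with e-value ≥ 1 have quality 0 but are retained: they still
occupy the hit universe and can be the (zero-scoring) best hit of an
unaccounted exon.

## Clustering

Hits are bucketed by scaffold pair; each bucket gets a single-linkage
dendrogram under the summed region-gap distance. The linkage step is
delegated to `scipy.cluster.hierarchy.linkage(method="single")` on hits
pre-sorted by hit id, which makes construction deterministic for fixed
input; hit ids themselves are assigned in (scaffold, start) sort order.
Ties between equal-distance merges are resolved by the linkage
algorithm's deterministic order; merge heights and the flat clustering
at any height — the quantities the rest of the pipeline consumes — are
independent of tie-breaking for single linkage, and the test suite
checks both against a naive O(n³) reconstruction.

## Scoring

`s(C) = 2·Σ_{h∈C} K(h) − Σ_{e∈U} max_{h∈H_e} K(h)`, with
`U = U_Cβ ∪ U_Cγ` the unaccounted exons. Two definitional choices:

* **"Located within"** means the exon interval is fully contained in
  the cluster's span on its organism. Exons straddling the span
  boundary are excluded — counting partial overlaps would penalize
  every cluster at both ends regardless of content.
* **"Touched"** means at least one hit of C has the exon as its β- or
  γ-exon, regardless of coverage fraction; membership, not coverage,
  defines accounting.

The penalty for an unaccounted exon is its best hit quality **anywhere
in the genome-wide hit universe** (0 if it has none): an exon whose best
match lies elsewhere is evidence against the cluster, an exon with no
match anywhere is not. `n_Cχ` counts only the unaccounted exons that
have a hit somewhere, and the conservation ratio is
`τ_C = (n_C + 1)/(n_Cβ + n_Cγ + 1)`.

Evaluations are cached per node; trees are immutable after construction
so the cache never invalidates.

## The permutation null

For a cluster with counts (n_C, n_Cβ, n_Cγ) a permuted score is

    s_p = 2·Σ_{k≤n_C} P_k − (Σ_{k≤n_Cβ} P*β_k + Σ_{k≤n_Cγ} P*γ_k)

with P a shuffled copy of all hit qualities and P*χ a shuffled copy of
the per-exon best qualities of organism χ; each sum draws without
replacement from its own, independently shuffled pool. A request
exceeding a pool size is truncated to an exhaustive draw. The p-value is
the add-one estimator (exceedances + 1)/(draws + 1).

**Early stopping.** Drawing stops once `early_stop_k` (default 10)
exceedances have accrued: the estimate is then far above any corrected
threshold and more draws can only confirm non-significance. Stopping is
sequential-exact: within a vectorized block the stopping draw is located
by cumulative count, so results equal a draw-by-draw loop.

**Normal approximation.** When every nonzero draw count is at least
`clt_min_n` (default 30), the null is approximated as normal with

    mean = 2·n_C·μ_all − n_Cβ·μ*β − n_Cγ·μ*γ
    var  = 4·n_C·σ²_all·f_all + n_Cβ·σ²*β·f_β + n_Cγ·σ²*γ·f_γ

where μ, σ² are exact pool moments (population variance) and
`f = (N − n)/(N − 1)` the finite-population correction of sampling
without replacement; the three pools are treated as independent. This
is a modeling choice — the pools overlap in content — validated
empirically: across cluster sizes 30–100 on pools of 5000 the
analytical and permutation p-values agree within 0.004 over a ±4 SD
grid (the suite enforces ≤ 0.01). A zero draw count contributes a
constant and imposes no size requirement. A fully drawn pool has f = 0
and contributes no variance; if the total variance is zero the p-value
degenerates to 1 for s ≤ mean and 0 above.

## The dynamic cut and its correction

Nodes containing fewer than two distinct genes **on either organism**
are never tested — synteny is a statement beyond single-gene homology,
so both sides must contribute at least two genes. This rule is monotone
(children contain subsets of hits), so failing nodes prune their whole
subtree.

Starting at each root, a node is reported when (i) it passes the
two-gene rule, (ii) τ_C ≥ τ, (iii) its raw p-value times the current
correction factor is ≤ α, and (iv) no child that itself satisfies τ has
a strictly lower p-value. Otherwise the walk descends to both children.
On a p-value tie between parent and child the parent wins: the larger
syntenic context is preferred, and the rule is deterministic. A
consequence is that reported spans may absorb stray background hits
adjacent to a strong block.

The Bonferroni factor is a single global counter across all
scaffold-pair trees (they share one α budget): it starts at 1 and is
incremented once per distinct descent edge, never on re-visits. Because
every internal node has two children and each tree over m hits has
m − 1 internal nodes, the factor is structurally bounded by 2|H|. The
walk is repeated in rounds: a node cut at a smaller factor is revisited
once the factor has grown, reusing its earlier permutation draws
(per-node resumable random substreams derived from (seed, node id)) and
extending them only as far as the current resolution target
`min(max_perms, ⌈10·factor/α⌉)`. Rounds repeat until neither the factor
nor the cut set changes; monotonicity of the factor guarantees
termination.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | family-wise significance threshold |
| `tau` | 1.0 | minimum conservation ratio; 2 for very similar strains |
| `clt_min_n` | 30 | smallest draw count for the normal approximation |
| `early_stop_k` | 10 | exceedances that trigger early stopping (None disables) |
| `max_perms` | ⌈10·2\|H\|/α⌉, capped at 200 000 | permutation budget per test |
| `seed` | 0 | master seed; fixed seed ⇒ byte-identical outputs |

## The synthetic data generator

The generator emulates the structures the method is designed to detect:
runs of gene pairs with reciprocal full-coverage hits at a chosen
e-value (planted blocks), uniform random exon-pair hits with
Beta(1, 5)-distributed qualities (background noise: mostly weak, a thin
strong tail), γ-side scaffold splits, fusions and inversions, and
tandem or scattered block duplications. Planted peptides are copied
verbatim between organisms, so a real aligner reproduces the planted
hits; the generator also writes both per-direction tabular files and
re-merging them reconstructs the in-memory hit set exactly.

Default study conditions: 2 scaffolds per organism, 50 genes per
scaffold, 2–5 exons per gene of 60–240 bp (codon-aligned), introns
50–150 bp, intergenic gaps 200–600 bp, 200 noise hits where noise is
used, blocks of 6 gene pairs at e-value 0. Genome *structure* is a
deterministic function of the structural spec fields; the seed moves
only sequence content and noise, so different seeds give identical
topology with different data — which is what the replicate-based error
and recovery properties need.

What it does **not** emulate: sequence evolution (no substitutions or
indels — planted homologs are identical, so alignment sensitivity is
not exercised), alternative splicing, overlapping genes, assembly gaps,
compositional biases, or any correlation structure among noise hits.
Passing tests therefore demonstrate the statistical machinery — error
control, recovery, invariances — under a clean null and clean signal,
not robustness to the full messiness of real annotations.

Problem sizes in the test suite and acceptance script are desk-scale by
design: hit universes of a few hundred, 100 noise replicates for the
type-I property, 20 replicates × 3 blocks for recovery, 10⁵ draws for
the null-engine cross-validation.

## Known limitations

* The cluster score ignores exon order within a cluster; order enters
  only through the clustering distance. This is deliberate (the target
  regime is fast-evolving microbes with frequent shuffling) but makes
  the method indifferent to inversions inside a cluster.
* The null assumes no relationship between the organisms beyond the
  observed quality pools; for genuinely related genomes it is
  conservative in shape but liberal in ignoring block structure. A
  gene-block shuffling null would be more faithful but breaks both the
  early-stopping argument and the normal approximation.
* Exons without any hit widen clustering distances but never penalize
  scores; heavily annotated but poorly matching regions can therefore
  bridge clusters.
* The two directional e-values are combined by maximum, and only
  strictly reciprocal pairs are kept; one-sided homologies are
  invisible.
* Rendering is delegated: the package emits Circos data files and a
  minimal static fallback plot, not publication figures.
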