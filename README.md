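# synclust

Detection of statistically significant syntenic clusters between two
annotated genomes, at the level of translated exons.

## Who this is for

Comparative genomicists working with diverged microbial or fungal
genomes, where codon usage has drifted and gene order, gene content and
even exon content have been shuffled. Classical collinearity tools that
demand conserved gene order break down in this regime; `synclust` works
at the amino-acid level and clusters homologous *exon* matches purely by
genomic proximity, disregarding order, then asks whether each candidate
cluster is statistically surprising.

## The method

1. **Mapping.** Every annotated coding exon of organisms β and γ is
   translated; an all-vs-all protein alignment (external BLASTp, or any
   precomputed 12-column tabular hit set) in both query directions is
   merged into bi-directional hits `h = (r_β, r_γ)` — one genomic region
   on each organism. Each hit carries a quality score

   ```
   K(h) = (1 − min(1, E(h))) · (‖r_β‖ + ‖r_γ‖) / (‖x_β‖ + ‖x_γ‖)
   ```

   where `x_χ` is the exon the hit touches on organism χ and `E` the
   e-value; `K ∈ [0, 1]`.

2. **Clustering.** Hits are grouped per scaffold pair and clustered by
   single linkage under the distance
   `d(h_i, h_j) = dist(r_iβ, r_jβ) + dist(r_iγ, r_jγ)`, with
   `dist(r_i, r_j) = max{0, max(s_i, s_j) − min(e_i, e_j)}` — the gap
   between the regions, zero when they overlap. Each dendrogram node is
   a candidate cluster `C`.

3. **Scoring.** A cluster accumulates its hit qualities but is
   penalized by *unaccounted* exons — exons inside its genomic span that
   none of its hits touch:

   ```
   s(C) = 2·Σ_{h∈C} K(h) − Σ_{e∈U_Cβ ∪ U_Cγ} max_{h∈H_e} K(h)
   ```

   An unaccounted exon with no hit anywhere contributes nothing. The
   conservation ratio `τ_C = (n_C + 1)/(n_Cβ + n_Cγ + 1)` (hits vs
   penalized gaps) must exceed a user threshold τ.

4. **Significance.** The null permutes hit qualities while keeping the
   clustering fixed: a permuted score draws `n_C` values without
   replacement from all qualities and subtracts draws from the per-exon
   best-quality pools. p-values come from sequential Monte Carlo with
   early stopping, or from a normal approximation with finite-population
   variance corrections when the cluster is large. A greedy depth-first
   cut reports a node when it satisfies τ, is significant under the
   current Bonferroni factor, and neither child is more significant; the
   factor starts at 1 and grows only on actual descents, never beyond
   the worst case of 2|H| tests.

Reported clusters come with spans on both genomes, gene lists, scores,
conservation ratios and corrected p-values, plus Circos-ready data files
for chromosome-level (one ribbon per cluster) and region-level (one
ribbon per hit, intensity ∝ K) visualization.

## Worked example

The built-in generator plants syntenic blocks into random toy genomes,
so the whole pipeline runs without any downloads:

```python
from synclust import build_forest, build_null_model, dynamic_cut, SignificanceConfig
from synclust.synthetic import BlockSpec, SyntheticSpec, generate

spec = SyntheticSpec(
    seed=1, n_noise=200,
    blocks=(BlockSpec(0, 5, 0, 5, 6),     # 6 gene pairs, scaffold b1 <-> g1
            BlockSpec(0, 20, 1, 10, 6),   # 6 gene pairs, b1 <-> g2
            BlockSpec(1, 8, 1, 30, 6)),   # 6 gene pairs, b2 <-> g2
)
res = generate(spec)
forest = build_forest(res.hitset)
null = build_null_model(res.hitset, seed=1)
clusters, ledger = dynamic_cut(
    forest, res.annotation_beta, res.annotation_gamma, res.hitset, null,
    SignificanceConfig(alpha=0.05, tau=1.0), seed=1,
)
print(f"{len(res.hitset)} hits -> {len(clusters)} significant clusters")
for c in clusters:
    print(f"cluster {c.cluster_id}: {c.span_beta.scaffold}:{c.span_beta.start1}-{c.span_beta.end1}"
          f" <-> {c.span_gamma.scaffold}:{c.span_gamma.start1}-{c.span_gamma.end1}"
          f"  n_hits={c.n_hits} s(C)={c.score:.2f} tau={c.conservation_ratio:.2f}"
          f" p_corrected={c.p_corrected:.2e}")
```

prints

```
260 hits -> 3 significant clusters
cluster 1: b1:6248-18637 <-> g1:721-13939  n_hits=22 s(C)=32.28 tau=1.44 p_corrected=5.00e-03
cluster 2: b1:14173-34906 <-> g2:8147-21215  n_hits=31 s(C)=41.19 tau=1.52 p_corrected=5.00e-03
cluster 3: b2:9380-26836 <-> g2:29091-58670  n_hits=31 s(C)=40.39 tau=1.10 p_corrected=5.00e-03
```

Each planted block is recovered as one significant cluster (a handful of
background noise hits are absorbed into the spans, which is why
`n_hits` exceeds the planted counts); the 200 uniform noise hits produce
no clusters of their own. `p_corrected` is the raw permutation p-value
times the final dynamic correction factor.

The same pipeline runs from the shell:

```sh
synclust synth --spec myspec.json --out fixture/
synclust run  --beta-fasta fixture/beta.fasta --beta-gff3 fixture/beta.gff3 \
              --gamma-fasta fixture/gamma.fasta --gamma-gff3 fixture/gamma.gff3 \
              --hits-beta-gamma fixture/hits_beta_gamma.tsv \
              --hits-gamma-beta fixture/hits_gamma_beta.tsv \
              --out run/ --seed 1
synclust viz  --run-dir run/ --out run/viz --scaffold b1
```

`run` checkpoints the merged hit table (`run/hits.tsv`), so re-runs skip
alignment and merging. Use τ = 1 for divergent genomes; τ = 2 is a
sensible preset for very similar strains.

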