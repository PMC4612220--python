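"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from synclust.genome_model import Exon, Gene, GenomeAnnotation, Region
from synclust.hits import Hit, make_hit
from synclust.clustering import hit_distance

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# --------------------------------------------------------------------------
# hand-built annotation / hit construction helpers


def build_annotation(
    organism_id: str,
    scaffold_lengths: dict[str, int],
    genes: list[tuple[str, str, str, list[tuple[int, int]]]],
    sequences: dict[str, str] | None = None,
) -> GenomeAnnotation:
    """Annotation from compact tuples (gene_id, scaffold, strand, [(s1,e1)]).

    Exon intervals are 1-based inclusive, exon lengths should be multiples
    of 3; peptides are filled with placeholder residues unless real
    sequences are supplied.
    """
    if sequences is None:
        sequences = {name: "A" * n for name, n in scaffold_lengths.items()}
    gene_objs = []
    for gene_id, scaffold, strand, intervals in genes:
        exons = []
        ordered = sorted(intervals, reverse=(strand == "-"))
        for i, (s1, e1) in enumerate(ordered):
            region = Region.from_1based(scaffold, s1, e1)
            exon = Exon(f"{gene_id}.e{i + 1}", gene_id, scaffold, strand, region, 0)
            exon.peptide = "X" * (region.length // 3)
            exons.append(exon)
        gene_objs.append(Gene(gene_id, scaffold, strand, exons))
    gene_objs.sort(key=lambda g: (g.scaffold, g.span.start, g.gene_id))
    return GenomeAnnotation(organism_id, sequences, gene_objs)


def full_hit(ann_beta, ann_gamma, exon_beta: str, exon_gamma: str, evalue: float = 0.0) -> Hit:
    eb, eg = ann_beta.exon(exon_beta), ann_gamma.exon(exon_gamma)
    return make_hit(eb, eg, (1, len(eb.peptide)), (1, len(eg.peptide)), evalue)


@pytest.fixture
def toy_pair():
    """Two 4-gene toy organisms with 60-bp single-exon genes at known spots."""
    layout = [(101, 160), (301, 360), (601, 660), (1001, 1060)]
    ann_beta = build_annotation(
        "beta",
        {"b1": 2000},
        [(f"bg{i + 1}", "b1", "+", [iv]) for i, iv in enumerate(layout)],
    )
    ann_gamma = build_annotation(
        "gamma",
        {"g1": 2000},
        [(f"gg{i + 1}", "g1", "+", [iv]) for i, iv in enumerate(layout)],
    )
    return ann_beta, ann_gamma


# --------------------------------------------------------------------------
# independent single-linkage oracle (naive O(n^3), full distance matrix)


def distance_matrix(hits: list[Hit]) -> np.ndarray:
    n = len(hits)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = hit_distance(hits[i], hits[j])
    return D


def naive_single_linkage_heights(D: np.ndarray) -> list[float]:
    """Merge heights by repeated minimum search over cluster pairs."""
    n = len(D)
    clusters: list[set[int]] = [{i} for i in range(n)]
    heights: list[float] = []
    while len(clusters) > 1:
        best = (np.inf, -1, -1)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(D[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(float(d))
        clusters[a] |= clusters[b]
        del clusters[b]
    return heights


def flat_clusters_at(D: np.ndarray, height: float) -> frozenset[frozenset[int]]:
    """Connected components of the graph with edges of distance <= height."""
    n = len(D)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= height:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


# --------------------------------------------------------------------------
# exhaustive permutation-null oracle (tiny pools only)


def exact_permutation_p(
    pool_all: np.ndarray,
    pool_beta: np.ndarray,
    pool_gamma: np.ndarray,
    n_c: int,
    n_cb: int,
    n_cg: int,
    s_obs: float,
) -> float:
    """Exact P(s_p >= s_obs) by enumerating all draw combinations."""
    from itertools import combinations

    def subset_sums(pool: np.ndarray, k: int) -> list[float]:
        if k <= 0:
            return [0.0]
        k = min(k, len(pool))
        return [sum(c) for c in combinations(pool, k)]

    total = 0
    exceed = 0
    for a in subset_sums(pool_all, n_c):
        for b in subset_sums(pool_beta, n_cb):
            for g in subset_sums(pool_gamma, n_cg):
                total += 1
                if 2 * a - (b + g) >= s_obs:
                    exceed += 1
    return exceed / total
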