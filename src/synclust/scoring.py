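"""Cluster score s(C), unaccounted exons and the conservation ratio τ_C.

A cluster C (a dendrogram node) accumulates its member hit qualities but
is penalized by exons that lie inside the genomic span it covers yet are
touched by none of its hits (the *unaccounted* exons U_C):

    s(C) = 2·Σ_{h∈C} K(h) − Σ_{e ∈ U_Cβ ∪ U_Cγ} max_{h∈H_e} K(h)

where H_e are all bi-directional hits genome-wide touching exon e.  An
unaccounted exon with no hit anywhere contributes nothing: without a
better home elsewhere it is no evidence against the cluster.

The conservation ratio

    τ_C = (n_C + 1) / (n_Cβ + n_Cγ + 1)

relates the number of hits in C to the number of unaccounted exons that
*do* have a hit elsewhere (n_Cχ); a user threshold τ rejects clusters
whose spans are riddled with exons that belong somewhere else.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .clustering import DendrogramNode
from .genome_model import GenomeAnnotation, Region
from .hits import HitSet

__all__ = [
    "ClusterEvaluation",
    "ClusterScorer",
    "unaccounted_exons",
    "cluster_score",
    "conservation_ratio",
]


@dataclass(frozen=True)
class ClusterEvaluation:
    node_id: str
    n_hits: int
    score: float
    unaccounted_beta: tuple[str, ...]
    unaccounted_gamma: tuple[str, ...]
    n_penalized_beta: int
    n_penalized_gamma: int
    conservation_ratio: float


def conservation_ratio(n_hits: int, n_penalized_beta: int, n_penalized_gamma: int) -> float:
    return (n_hits + 1) / (n_penalized_beta + n_penalized_gamma + 1)


class _ContainmentIndex:
    """Per-scaffold exon lists sorted by start, for span containment queries."""

    def __init__(self, annotation: GenomeAnnotation):
        self._by_scaffold: dict[str, tuple[list[int], list[int], list[str]]] = {}
        tmp: dict[str, list[tuple[int, int, str]]] = {}
        for exon in annotation.exons():
            tmp.setdefault(exon.scaffold, []).append(
                (exon.region.start, exon.region.end, exon.exon_id)
            )
        for scaffold, rows in tmp.items():
            rows.sort()
            self._by_scaffold[scaffold] = (
                [r[0] for r in rows],
                [r[1] for r in rows],
                [r[2] for r in rows],
            )

    def contained(self, span: Region) -> list[str]:
        """Exons fully contained in the span (boundary-overlappers excluded)."""
        entry = self._by_scaffold.get(span.scaffold)
        if entry is None:
            return []
        starts, ends, ids = entry
        lo = bisect.bisect_left(starts, span.start)
        out = []
        for i in range(lo, len(starts)):
            if starts[i] >= span.end:
                break
            if ends[i] <= span.end:
                out.append(ids[i])
        return out


class ClusterScorer:
    """Evaluates dendrogram nodes against a fixed annotation pair + HitSet.

    Evaluations are cached by node_id; the tree is immutable after build
    so the cache is never invalidated.
    """

    def __init__(
        self,
        annotation_beta: GenomeAnnotation,
        annotation_gamma: GenomeAnnotation,
        hitset: HitSet,
    ):
        self.annotation_beta = annotation_beta
        self.annotation_gamma = annotation_gamma
        self.hitset = hitset
        self._index_beta = _ContainmentIndex(annotation_beta)
        self._index_gamma = _ContainmentIndex(annotation_gamma)
        self._cache: dict[str, ClusterEvaluation] = {}

    def unaccounted_exons(self, node: DendrogramNode) -> tuple[list[str], list[str]]:
        """U_Cβ, U_Cγ: exons inside the spans untouched by any hit of C."""
        touched_beta = {h.exon_beta for h in node.hits}
        touched_gamma = {h.exon_gamma for h in node.hits}
        u_beta = [
            e for e in self._index_beta.contained(node.span_beta) if e not in touched_beta
        ]
        u_gamma = [
            e for e in self._index_gamma.contained(node.span_gamma) if e not in touched_gamma
        ]
        return u_beta, u_gamma

    def evaluate(self, node: DendrogramNode) -> ClusterEvaluation:
        cached = self._cache.get(node.node_id)
        if cached is not None:
            return cached
        u_beta, u_gamma = self.unaccounted_exons(node)
        gain = 2.0 * sum(h.quality for h in node.hits)
        penalty = sum(self.hitset.best_quality("beta", e) for e in u_beta) + sum(
            self.hitset.best_quality("gamma", e) for e in u_gamma
        )
        n_pen_beta = sum(1 for e in u_beta if self.hitset.has_hit("beta", e))
        n_pen_gamma = sum(1 for e in u_gamma if self.hitset.has_hit("gamma", e))
        evaluation = ClusterEvaluation(
            node_id=node.node_id,
            n_hits=node.n_hits,
            score=gain - penalty,
            unaccounted_beta=tuple(u_beta),
            unaccounted_gamma=tuple(u_gamma),
            n_penalized_beta=n_pen_beta,
            n_penalized_gamma=n_pen_gamma,
            conservation_ratio=conservation_ratio(node.n_hits, n_pen_beta, n_pen_gamma),
        )
        self._cache[node.node_id] = evaluation
        return evaluation


def unaccounted_exons(
    node: DendrogramNode,
    annotations: tuple[GenomeAnnotation, GenomeAnnotation],
    hitset: HitSet,
) -> tuple[list[str], list[str]]:
    return ClusterScorer(annotations[0], annotations[1], hitset).unaccounted_exons(node)


def cluster_score(
    node: DendrogramNode,
    annotations: tuple[GenomeAnnotation, GenomeAnnotation],
    hitset: HitSet,
) -> ClusterEvaluation:
    return ClusterScorer(annotations[0], annotations[1], hitset).evaluate(node)
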