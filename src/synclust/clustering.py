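"""Genomic hit distance and per-scaffold-pair single-linkage dendrograms.

The distance between two regions on the same scaffold is the gap between
them (0 when they overlap):

    dist(r_i, r_j) = max{0, max(s_i, s_j) − min(e_i, e_j)}     (1-based)

and the distance between two hits is the sum of the region gaps on the two
organisms.  This is purely positional — strand never enters — and is not a
metric (no triangle inequality is assumed); single linkage only needs
symmetry and non-negativity.

Hits are first bucketed by the scaffold pair they connect; one dendrogram
is built per non-empty pair.  Because hits (not exons) are clustered, an
exon with hits on several partner scaffolds appears in several trees,
which is how duplications are handled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genome_model import Region
from .hits import Hit, HitSet

log = logging.getLogger(__name__)

__all__ = [
    "region_distance",
    "hit_distance",
    "DendrogramNode",
    "build_dendrogram",
    "build_forest",
    "to_newick",
]


def region_distance(r1: Region, r2: Region) -> int:
    """Gap in bp between two regions on the same scaffold (0 if overlapping)."""
    if r1.scaffold != r2.scaffold:
        raise ValueError(
            f"region_distance across scaffolds {r1.scaffold!r} vs {r2.scaffold!r}"
        )
    # max(s1,s2) − min(e1,e2) in 1-based inclusive coordinates
    return max(0, max(r1.start1, r2.start1) - min(r1.end1, r2.end1))


def hit_distance(h1: Hit, h2: Hit) -> int:
    """Sum of the β-side and γ-side region gaps between two hits."""
    if (
        h1.region_beta.scaffold != h2.region_beta.scaffold
        or h1.region_gamma.scaffold != h2.region_gamma.scaffold
    ):
        raise ValueError("hit_distance across different scaffold pairs")
    return region_distance(h1.region_beta, h2.region_beta) + region_distance(
        h1.region_gamma, h2.region_gamma
    )


@dataclass
class DendrogramNode:
    """A candidate cluster: a set of hits merged at some linkage height."""

    node_id: str
    height: float
    children: tuple["DendrogramNode", ...]
    hits: tuple[Hit, ...]
    span_beta: Region
    span_gamma: Region

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def hit_ids(self) -> frozenset[int]:
        return frozenset(h.hit_id for h in self.hits)

    def walk(self) -> Iterator["DendrogramNode"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> Iterator["DendrogramNode"]:
        for node in self.walk():
            if node.is_leaf:
                yield node

    def cut_at(self, height: float) -> list["DendrogramNode"]:
        """Maximal nodes whose merge height is ≤ the given height."""
        if self.height <= height:
            return [self]
        out: list[DendrogramNode] = []
        for child in self.children:
            out.extend(child.cut_at(height))
        return out


def _spans(hits: tuple[Hit, ...]) -> tuple[Region, Region]:
    sb = Region(
        hits[0].region_beta.scaffold,
        min(h.region_beta.start for h in hits),
        max(h.region_beta.end for h in hits),
    )
    sg = Region(
        hits[0].region_gamma.scaffold,
        min(h.region_gamma.start for h in hits),
        max(h.region_gamma.end for h in hits),
    )
    return sb, sg


def condensed_distances(hits: list[Hit]) -> np.ndarray:
    """Condensed pairwise hit-distance matrix (float64, exact for bp ints)."""
    n = len(hits)
    sb = np.array([h.region_beta.start1 for h in hits], dtype=np.float64)
    eb = np.array([h.region_beta.end1 for h in hits], dtype=np.float64)
    sg = np.array([h.region_gamma.start1 for h in hits], dtype=np.float64)
    eg = np.array([h.region_gamma.end1 for h in hits], dtype=np.float64)
    db = np.maximum(0.0, np.maximum.outer(sb, sb) - np.minimum.outer(eb, eb))
    dg = np.maximum(0.0, np.maximum.outer(sg, sg) - np.minimum.outer(eg, eg))
    return squareform(db + dg, checks=False)


def build_dendrogram(hits_for_pair: list[Hit], pair_label: str = "") -> DendrogramNode:
    """Single-linkage merge tree over the hits of one scaffold pair.

    Node heights are the linkage distances; leaves have height 0.  Input
    hits are sorted by hit_id first so the construction is deterministic
    regardless of caller order.
    """
    if not hits_for_pair:
        raise ValueError("cannot build a dendrogram from zero hits")
    hits = sorted(hits_for_pair, key=lambda h: h.hit_id)
    prefix = pair_label or f"{hits[0].region_beta.scaffold}~{hits[0].region_gamma.scaffold}"
    nodes: list[DendrogramNode] = []
    for i, h in enumerate(hits):
        sb, sg = _spans((h,))
        nodes.append(DendrogramNode(f"{prefix}~L{i}", 0.0, (), (h,), sb, sg))
    if len(hits) == 1:
        return nodes[0]
    Z = linkage(condensed_distances(hits), method="single")
    for k, row in enumerate(Z):
        a, b = nodes[int(row[0])], nodes[int(row[1])]
        children = tuple(sorted((a, b), key=lambda nd: min(nd.hit_ids)))
        merged = tuple(sorted(a.hits + b.hits, key=lambda h: h.hit_id))
        height = max(float(row[2]), a.height, b.height)  # monotone by construction
        sb, sg = _spans(merged)
        nodes.append(DendrogramNode(f"{prefix}~N{k}", height, children, merged, sb, sg))
    return nodes[-1]


def build_forest(hitset: HitSet) -> dict[tuple[str, str], DendrogramNode]:
    """One dendrogram per non-empty scaffold pair."""
    forest = {
        pair: build_dendrogram(pair_hits, pair_label=f"{pair[0]}~{pair[1]}")
        for pair, pair_hits in sorted(hitset.by_scaffold_pair.items())
    }
    log.info("forest: %d scaffold-pair trees over %d hits", len(forest), len(hitset))
    return forest


def to_newick(node: DendrogramNode) -> str:
    """Debug dump: Newick with heights as branch lengths, leaves = hit_ids."""

    def render(nd: DendrogramNode, parent_height: float) -> str:
        branch = parent_height - nd.height
        if nd.is_leaf:
            return f"h{nd.hits[0].hit_id}:{branch:g}"
        inner = ",".join(render(c, nd.height) for c in nd.children)
        return f"({inner}):{branch:g}"

    return render(node, node.height) + ";"
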