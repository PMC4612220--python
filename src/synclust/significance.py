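"""Permutation significance of cluster scores and the dynamic tree cut.

The null keeps the clustering fixed and permutes hit qualities: for a
cluster with n_C hits and n_Cβ/n_Cγ penalized unaccounted exons, one
permuted score is

    s_p = 2·Σ_{k=1..n_C} P_k − (Σ_{k=1..n_Cβ} P*βk + Σ_{k=1..n_Cγ} P*γk)

where P is a freshly shuffled list of all hit qualities in H and P*χ a
shuffled list of the per-exon best-hit qualities of organism χ; every sum
draws without replacement from its own pool.  The p-value is the add-one
Monte-Carlo estimator (n_exceed + 1)/(n_draws + 1), with sequential early
stopping once enough exceedances make significance impossible, and a
normal (CLT) approximation with finite-population variance corrections
when every nonzero draw count is large.

Multiple testing over the dendrograms uses a *dynamic* Bonferroni factor:
it starts at 1 and grows only when the greedy cut actually descends to a
child node; nodes previously called significant are revisited whenever
the factor has grown (reusing their earlier permutations) until a fixed
point is reached.  The factor can never exceed the worst case of 2|H|
tests.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.stats import norm

from .clustering import DendrogramNode
from .genome_model import GenomeAnnotation, Region
from .hits import HitSet
from .scoring import ClusterEvaluation, ClusterScorer

log = logging.getLogger(__name__)

__all__ = [
    "SignificanceConfig",
    "NullModel",
    "TestRecord",
    "SyntenicCluster",
    "build_null_model",
    "permuted_score",
    "p_value_permutation",
    "p_value_clt",
    "passes_two_gene_rule",
    "worst_case_correction",
    "dynamic_cut",
    "write_cluster_table",
    "write_ledger",
]


@dataclass(frozen=True)
class SignificanceConfig:
    """Tunable statistical parameters.

    alpha        family-wise significance threshold (0.05).
    tau          minimum conservation ratio for a reportable cluster; 1
                 for divergent genomes, 2 is a sensible preset for very
                 close strains.
    clt_min_n    smallest draw count for which the normal approximation
                 replaces permutations (30).
    early_stop_k stop a permutation test after this many exceedances;
                 None disables early stopping.
    max_perms    hard cap on permutations per test; None derives
                 ceil(10·2|H|/alpha) capped at max_perms_cap.
    """

    alpha: float = 0.05
    tau: float = 1.0
    clt_min_n: int = 30
    early_stop_k: int | None = 10
    max_perms: int | None = None
    max_perms_cap: int = 200_000
    use_clt: bool = True
    block: int = 512

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def resolved_max_perms(self, n_hits: int) -> int:
        if self.max_perms is not None:
            return self.max_perms
        return min(self.max_perms_cap, math.ceil(10 * 2 * n_hits / self.alpha))


@dataclass
class NullModel:
    """The permutation pools and their exact moments."""

    pool_all: np.ndarray
    pool_best_beta: np.ndarray
    pool_best_gamma: np.ndarray
    rng_seed: int = 0
    mean_all: float = field(init=False)
    var_all: float = field(init=False)
    mean_best_beta: float = field(init=False)
    var_best_beta: float = field(init=False)
    mean_best_gamma: float = field(init=False)
    var_best_gamma: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("all", "best_beta", "best_gamma"):
            pool = getattr(self, f"pool_{name}")
            prefix = name if name == "all" else name
            setattr(self, f"mean_{prefix}", float(pool.mean()) if len(pool) else 0.0)
            # population variance: matches the without-replacement
            # finite-population correction n·σ²·(N−n)/(N−1)
            setattr(self, f"var_{prefix}", float(pool.var(ddof=0)) if len(pool) else 0.0)

    def pools(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.pool_all, self.pool_best_beta, self.pool_best_gamma


def build_null_model(hitset: HitSet, seed: int = 0) -> NullModel:
    if len(hitset) == 0:
        raise ValueError("cannot build a null model from an empty hit set")
    return NullModel(
        pool_all=np.array([h.quality for h in hitset.hits], dtype=np.float64),
        pool_best_beta=np.array(
            [hitset.best_beta[e].quality for e in sorted(hitset.best_beta)], dtype=np.float64
        ),
        pool_best_gamma=np.array(
            [hitset.best_gamma[e].quality for e in sorted(hitset.best_gamma)], dtype=np.float64
        ),
        rng_seed=seed,
    )


_MAX_BLOCK_ELEMENTS = 4_000_000


def _sample_sums(pool: np.ndarray, n: int, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Sums of ``n`` values drawn without replacement, for ``n_draws`` draws.

    Requests beyond the pool size are truncated to an exhaustive draw
    (sampling without replacement cannot exceed the population).
    """
    N = len(pool)
    if n <= 0 or N == 0:
        return np.zeros(n_draws)
    if n >= N:
        return np.full(n_draws, float(pool.sum()))
    out = np.empty(n_draws)
    step = max(1, _MAX_BLOCK_ELEMENTS // N)
    for lo in range(0, n_draws, step):
        b = min(step, n_draws - lo)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        out[lo : lo + b] = pool[idx].sum(axis=1)
    return out


def _permuted_scores(
    null: NullModel, n_c: int, n_cb: int, n_cg: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    a = _sample_sums(null.pool_all, n_c, n_draws, rng)
    b = _sample_sums(null.pool_best_beta, n_cb, n_draws, rng)
    g = _sample_sums(null.pool_best_gamma, n_cg, n_draws, rng)
    return 2.0 * a - (b + g)


def permuted_score(
    null: NullModel, n_c: int, n_cb: int, n_cg: int, rng: np.random.Generator
) -> float:
    """One permuted cluster score s_p."""
    return float(_permuted_scores(null, n_c, n_cb, n_cg, 1, rng)[0])


@dataclass(frozen=True)
class TestRecord:
    node_id: str
    n_draws: int
    n_exceed: int
    p_raw: float
    method: str  # "permutation" | "clt"
    correction_factor: int = 1
    decision: str = "untested"  # "significant" | "not_significant" | "untested"


class _PermState:
    """Resumable permutation test for one node: draws are never wasted."""

    def __init__(self, null: NullModel, n_c: int, n_cb: int, n_cg: int,
                 rng: np.random.Generator):
        self.null = null
        self.n_c, self.n_cb, self.n_cg = n_c, n_cb, n_cg
        self.rng = rng
        self.n_draws = 0
        self.n_exceed = 0
        self.stopped = False

    def extend(self, s_obs: float, target: int, early_stop_k: int | None, block: int) -> None:
        while self.n_draws < target and not self.stopped:
            b = min(block, target - self.n_draws)
            scores = _permuted_scores(self.null, self.n_c, self.n_cb, self.n_cg, b, self.rng)
            exceeds = scores >= s_obs
            if early_stop_k is not None:
                remaining = early_stop_k - self.n_exceed
                cum = np.cumsum(exceeds)
                if cum[-1] >= remaining:
                    # exact sequential semantics: stop at the draw where
                    # the k-th exceedance occurred
                    stop_at = int(np.searchsorted(cum, remaining)) + 1
                    self.n_draws += stop_at
                    self.n_exceed += remaining
                    self.stopped = True
                    return
            self.n_draws += b
            self.n_exceed += int(exceeds.sum())

    @property
    def p_raw(self) -> float:
        return (self.n_exceed + 1) / (self.n_draws + 1)


def p_value_permutation(
    null: NullModel,
    s_obs: float,
    n_c: int,
    n_cb: int,
    n_cg: int,
    max_perms: int,
    early_stop_k: int | None,
    rng: np.random.Generator,
    node_id: str = "",
    block: int = 512,
) -> TestRecord:
    """Sequential Monte-Carlo p-value with add-one estimator.

    Draws permuted scores until either ``early_stop_k`` exceedances have
    accrued (the cluster can never become significant with more draws) or
    ``max_perms`` draws are spent.
    """
    if max_perms < 1:
        raise ValueError("max_perms must be >= 1")
    state = _PermState(null, n_c, n_cb, n_cg, rng)
    state.extend(s_obs, max_perms, early_stop_k, block)
    return TestRecord(
        node_id=node_id,
        n_draws=state.n_draws,
        n_exceed=state.n_exceed,
        p_raw=state.p_raw,
        method="permutation",
    )


def clt_moments(null: NullModel, n_c: int, n_cb: int, n_cg: int) -> tuple[float, float]:
    """Mean and variance of s_p under independent without-replacement draws."""
    mean = 2.0 * n_c * null.mean_all - n_cb * null.mean_best_beta - n_cg * null.mean_best_gamma
    var = 0.0
    for factor, n, pool_len, sigma2 in (
        (4.0, n_c, len(null.pool_all), null.var_all),
        (1.0, n_cb, len(null.pool_best_beta), null.var_best_beta),
        (1.0, n_cg, len(null.pool_best_gamma), null.var_best_gamma),
    ):
        n_eff = min(n, pool_len)
        if n_eff <= 0 or pool_len <= 1:
            continue
        fpc = (pool_len - n_eff) / (pool_len - 1)
        var += factor * n_eff * sigma2 * fpc
    return mean, var


def clt_applicable(null: NullModel, n_c: int, n_cb: int, n_cg: int, clt_min_n: int) -> bool:
    """Normal approximation allowed when every nonzero draw count is large."""
    for n, pool_len in (
        (n_c, len(null.pool_all)),
        (n_cb, len(null.pool_best_beta)),
        (n_cg, len(null.pool_best_gamma)),
    ):
        n_eff = min(n, pool_len)
        if 0 < n_eff < clt_min_n:
            return False
    return True


def p_value_clt(
    null: NullModel,
    s_obs: float,
    n_c: int,
    n_cb: int,
    n_cg: int,
    clt_min_n: int = 30,
    node_id: str = "",
) -> TestRecord:
    """Upper-tail normal probability of the permutation null."""
    if not clt_applicable(null, n_c, n_cb, n_cg, clt_min_n):
        raise ValueError(
            "cluster too small for the CLT approximation; use the permutation path"
        )
    mean, var = clt_moments(null, n_c, n_cb, n_cg)
    if var <= 0.0:
        p = 1.0 if s_obs <= mean else 0.0
    else:
        p = float(norm.sf(s_obs, loc=mean, scale=math.sqrt(var)))
    return TestRecord(node_id=node_id, n_draws=0, n_exceed=0, p_raw=p, method="clt")


def node_genes(
    node: DendrogramNode, annotations: tuple[GenomeAnnotation, GenomeAnnotation]
) -> tuple[set[str], set[str]]:
    ann_beta, ann_gamma = annotations
    genes_beta = {ann_beta.gene_of_exon(h.exon_beta) for h in node.hits}
    genes_gamma = {ann_gamma.gene_of_exon(h.exon_gamma) for h in node.hits}
    return genes_beta, genes_gamma


def passes_two_gene_rule(
    node: DendrogramNode, annotations: tuple[GenomeAnnotation, GenomeAnnotation]
) -> bool:
    """Clusters smaller than two genes — on either organism — are not tested.

    Synteny is a statement beyond homology between single genes, so both
    sides must contribute at least two distinct genes.
    """
    genes_beta, genes_gamma = node_genes(node, annotations)
    return len(genes_beta) >= 2 and len(genes_gamma) >= 2


def worst_case_correction(hitset: HitSet) -> int:
    """Upper bound on the number of tests: 2|H| (never exceeded dynamically)."""
    return 2 * len(hitset)


@dataclass(frozen=True)
class SyntenicCluster:
    """A dendrogram node accepted by the dynamic cut — the primary output."""

    cluster_id: int
    node_id: str
    span_beta: Region
    span_gamma: Region
    hit_ids: frozenset[int]
    genes_beta: tuple[str, ...]
    genes_gamma: tuple[str, ...]
    n_hits: int
    score: float
    conservation_ratio: float
    p_raw: float
    correction_factor: int
    p_corrected: float
    method: str


def _node_rng(seed: int, node_id: str) -> np.random.Generator:
    # per-node substream: revisits resume the same deterministic stream
    sub = zlib.crc32(node_id.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(sub,)))


class _Cutter:
    def __init__(
        self,
        forest: dict[tuple[str, str], DendrogramNode],
        annotation_beta: GenomeAnnotation,
        annotation_gamma: GenomeAnnotation,
        hitset: HitSet,
        null: NullModel,
        config: SignificanceConfig,
        seed: int,
    ):
        self.forest = forest
        self.annotations = (annotation_beta, annotation_gamma)
        self.scorer = ClusterScorer(annotation_beta, annotation_gamma, hitset)
        self.hitset = hitset
        self.null = null
        self.config = config
        self.seed = seed
        self.max_perms = config.resolved_max_perms(len(hitset))
        self.correction = 1
        self.descended: set[str] = set()
        self.states: dict[str, _PermState] = {}
        self.clt_cache: dict[str, TestRecord] = {}
        self.ledger: dict[str, TestRecord] = {}
        self.two_gene_cache: dict[str, bool] = {}

    # -- single-node testing ------------------------------------------------

    def _two_gene(self, node: DendrogramNode) -> bool:
        cached = self.two_gene_cache.get(node.node_id)
        if cached is None:
            cached = passes_two_gene_rule(node, self.annotations)
            self.two_gene_cache[node.node_id] = cached
        return cached

    def _target_draws(self) -> int:
        # resolution: the floor 1/(n+1) must sit well below alpha/correction
        return min(self.max_perms, math.ceil(10 * self.correction / self.config.alpha))

    def test(self, node: DendrogramNode, evaluation: ClusterEvaluation) -> TestRecord:
        cfg = self.config
        n_c = evaluation.n_hits
        n_cb, n_cg = evaluation.n_penalized_beta, evaluation.n_penalized_gamma
        if cfg.use_clt and clt_applicable(self.null, n_c, n_cb, n_cg, cfg.clt_min_n):
            rec = self.clt_cache.get(node.node_id)
            if rec is None:
                rec = p_value_clt(
                    self.null, evaluation.score, n_c, n_cb, n_cg, cfg.clt_min_n, node.node_id
                )
                self.clt_cache[node.node_id] = rec
            return rec
        state = self.states.get(node.node_id)
        if state is None:
            state = _PermState(
                self.null, n_c, n_cb, n_cg, _node_rng(self.seed, node.node_id)
            )
            self.states[node.node_id] = state
        state.extend(evaluation.score, self._target_draws(), cfg.early_stop_k, cfg.block)
        return TestRecord(
            node_id=node.node_id,
            n_draws=state.n_draws,
            n_exceed=state.n_exceed,
            p_raw=state.p_raw,
            method="permutation",
        )

    # -- the greedy walk ----------------------------------------------------

    def _child_p_values(self, node: DendrogramNode) -> list[float]:
        """p of each testable child that satisfies the conservation ratio."""
        out = []
        for child in node.children:
            if child.is_leaf or not self._two_gene(child):
                continue
            ev = self.scorer.evaluate(child)
            if ev.conservation_ratio < self.config.tau:
                continue
            out.append(self.test(child, ev).p_raw)
        return out

    def _walk(self) -> list[tuple[DendrogramNode, TestRecord, ClusterEvaluation]]:
        cuts = []
        for pair in sorted(self.forest):
            stack = [self.forest[pair]]
            while stack:
                node = stack.pop()
                if node.is_leaf or not self._two_gene(node):
                    continue  # children can only have fewer genes: prune
                evaluation = self.scorer.evaluate(node)
                rec = self.test(node, evaluation)
                tau_ok = evaluation.conservation_ratio >= self.config.tau
                significant = tau_ok and rec.p_raw * self.correction <= self.config.alpha
                child_better = any(p < rec.p_raw for p in self._child_p_values(node))
                decision = "significant" if significant else "not_significant"
                self.ledger[node.node_id] = replace(
                    rec, correction_factor=self.correction, decision=decision
                )
                if significant and not child_better:
                    cuts.append((node, rec, evaluation))
                    continue
                for child in reversed(node.children):
                    if child.is_leaf:
                        continue
                    if child.node_id not in self.descended:
                        self.descended.add(child.node_id)
                        self.correction += 1
                    stack.append(child)
        return cuts

    def run(self) -> list[tuple[DendrogramNode, TestRecord, ClusterEvaluation]]:
        bound = worst_case_correction(self.hitset)
        previous_cut_ids: frozenset[str] | None = None
        while True:
            before = self.correction
            cuts = self._walk()
            cut_ids = frozenset(node.node_id for node, _, _ in cuts)
            if self.correction == before and cut_ids == previous_cut_ids:
                break
            previous_cut_ids = cut_ids
        if self.correction > bound:  # pragma: no cover - structural guarantee
            raise AssertionError(
                f"correction factor {self.correction} exceeded the 2|H| bound {bound}"
            )
        return cuts


def dynamic_cut(
    forest: dict[tuple[str, str], DendrogramNode],
    annotation_beta: GenomeAnnotation,
    annotation_gamma: GenomeAnnotation,
    hitset: HitSet,
    null: NullModel,
    config: SignificanceConfig | None = None,
    seed: int = 0,
) -> tuple[list[SyntenicCluster], list[TestRecord]]:
    """Greedy significance-driven tree cut with dynamic Bonferroni correction.

    Returns the reported clusters (mutually non-nested within each tree)
    and the ledger of every tested node.
    """
    config = config or SignificanceConfig()
    if not forest:
        return [], []
    cutter = _Cutter(forest, annotation_beta, annotation_gamma, hitset, null, config, seed)
    raw = cutter.run()
    correction = cutter.correction
    clusters = []
    ordered = sorted(
        raw,
        key=lambda t: (
            t[0].span_beta.scaffold,
            t[0].span_beta.start,
            t[0].span_gamma.scaffold,
            t[0].span_gamma.start,
        ),
    )
    for i, (node, rec, evaluation) in enumerate(ordered, start=1):
        genes_beta, genes_gamma = node_genes(node, cutter.annotations)
        clusters.append(
            SyntenicCluster(
                cluster_id=i,
                node_id=node.node_id,
                span_beta=node.span_beta,
                span_gamma=node.span_gamma,
                hit_ids=node.hit_ids,
                genes_beta=tuple(sorted(genes_beta)),
                genes_gamma=tuple(sorted(genes_gamma)),
                n_hits=node.n_hits,
                score=evaluation.score,
                conservation_ratio=evaluation.conservation_ratio,
                p_raw=rec.p_raw,
                correction_factor=correction,
                p_corrected=min(1.0, rec.p_raw * correction),
                method=rec.method,
            )
        )
    ledger = [cutter.ledger[k] for k in sorted(cutter.ledger)]
    log.info(
        "dynamic cut: %d clusters, final correction factor %d (bound %d), %d nodes tested",
        len(clusters),
        correction,
        worst_case_correction(hitset),
        len(ledger),
    )
    return clusters, ledger


_CLUSTER_COLUMNS = (
    "cluster_id\tscaffold_beta\tstart_beta\tend_beta\tscaffold_gamma\tstart_gamma\t"
    "end_gamma\tn_hits\tn_genes_beta\tn_genes_gamma\tscore\tconservation_ratio\t"
    "p_raw\tcorrection_factor\tp_corrected\tmethod\thit_ids\n"
)


def write_cluster_table(clusters: Iterable[SyntenicCluster], destination) -> None:
    with open(destination, "w") as fh:
        fh.write(_CLUSTER_COLUMNS)
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.span_beta.scaffold}\t{c.span_beta.start1}\t"
                f"{c.span_beta.end1}\t{c.span_gamma.scaffold}\t{c.span_gamma.start1}\t"
                f"{c.span_gamma.end1}\t{c.n_hits}\t{len(c.genes_beta)}\t"
                f"{len(c.genes_gamma)}\t{c.score:.10g}\t{c.conservation_ratio:.10g}\t"
                f"{c.p_raw:.6g}\t{c.correction_factor}\t{c.p_corrected:.6g}\t{c.method}\t"
                f"{','.join(str(i) for i in sorted(c.hit_ids))}\n"
            )


def write_ledger(records: Iterable[TestRecord], destination) -> None:
    with open(destination, "w") as fh:
        fh.write("node_id\tn_draws\tn_exceed\tp_raw\tmethod\tcorrection_factor\tdecision\n")
        for r in records:
            fh.write(
                f"{r.node_id}\t{r.n_draws}\t{r.n_exceed}\t{r.p_raw:.6g}\t{r.method}\t"
                f"{r.correction_factor}\t{r.decision}\n"
            )
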