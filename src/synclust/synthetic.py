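"""Synthetic genome pairs with planted synteny and known ground truth.

Builds toy two-organism datasets — FASTA + GFF3 annotations, a
bi-directional hit set, and the ground truth of which hits were planted —
so that every stage of the pipeline is testable without downloads.

What is emulated: syntenic blocks as runs of gene pairs whose exons carry
reciprocal full-coverage hits at a chosen e-value; background noise as
uniformly random exon pairs with mostly-weak qualities; γ-side genome
rearrangements (scaffold splits, fusions, inversions) and tandem or
scattered gene-block duplications.  Blocks are *planted*, not evolved: no
substitution or indel process acts on the sequences, so planted peptides
are exactly identical between the organisms (a real aligner reproduces
the planted hits).

Seed contract: the genome *structure* (gene counts, exon lengths, gaps,
strands, coordinates) is a deterministic function of the structural spec
fields alone; the seed moves only sequence content and noise hits.  Two
seeds therefore give identical topology with different sequences, and
noise replicate i is reproducible from (seed, i).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .genome_model import (
    Exon,
    Gene,
    GenomeAnnotation,
    Region,
    reverse_complement,
    translate_exons,
    write_genome_fasta,
    write_gff3,
)
from .hits import Hit, HitSet, make_hit, write_hit_table

log = logging.getLogger(__name__)

__all__ = [
    "BlockSpec",
    "DuplicationSpec",
    "SyntheticSpec",
    "GroundTruth",
    "GenerationResult",
    "generate",
    "generate_noise_replicates",
    "write_fixture",
    "random_hitset",
]

_STRUCTURE_ENTROPY = 0x5C1A  # structure stream is spec-determined, not seed-determined

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_SENSE_CODONS = np.array(
    [
        b1 + b2 + b3
        for b1 in "ACGT"
        for b2 in "ACGT"
        for b3 in "ACGT"
        if b1 + b2 + b3 not in ("TAA", "TAG", "TGA")
    ]
)


@dataclass(frozen=True)
class BlockSpec:
    """A planted syntenic block: n_genes consecutive gene pairs.

    Gene i of the β range is paired with gene i of the γ range; every
    exon pair carries a reciprocal full-coverage hit with the given
    e-value (so each planted hit has quality K = 1 − min(1, evalue)).
    """

    beta_scaffold: int
    beta_start: int
    gamma_scaffold: int
    gamma_start: int
    n_genes: int
    evalue: float = 0.0


@dataclass(frozen=True)
class DuplicationSpec:
    """Extra γ-side copies of a planted block's genes.

    placement "spread" appends copy c to scaffold (gamma_scaffold + c)
    mod S — each copy lands in a different dendrogram; "tandem" inserts
    the copies right after the source genes, so all copies share one
    cluster.
    """

    block: int
    n_copies: int
    placement: str = "spread"


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    scaffolds_beta: int = 2
    scaffolds_gamma: int = 2
    genes_per_scaffold: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_bp: tuple[int, int] = (60, 240)
    intron_bp: tuple[int, int] = (50, 150)
    intergenic_bp: tuple[int, int] = (200, 600)
    blocks: tuple[BlockSpec, ...] = ()
    n_noise: int = 0
    noise_beta: tuple[float, float] = (1.0, 5.0)  # Beta(1,5): mostly weak hits
    rearrangements: tuple[tuple, ...] = ()
    duplications: tuple[DuplicationSpec, ...] = ()


@dataclass
class GroundTruth:
    blocks: dict[str, frozenset[int]]
    expected_recovered: dict[str, bool]
    ops: list[tuple]


@dataclass
class GenerationResult:
    spec: SyntheticSpec
    annotation_beta: GenomeAnnotation
    annotation_gamma: GenomeAnnotation
    hitset: HitSet
    truth: GroundTruth


@dataclass
class _GeneSkel:
    gid: str
    exon_lens: list[int]  # transcription order
    strand: str
    pair: list[str] | None = None  # β exon ids, transcription order
    evalue: float = 0.0
    block_key: str | None = None


def _validate(spec: SyntheticSpec) -> None:
    for i, b in enumerate(spec.blocks):
        if not (0 <= b.beta_scaffold < spec.scaffolds_beta):
            raise ValueError(f"blocks[{i}].beta_scaffold out of range")
        if not (0 <= b.gamma_scaffold < spec.scaffolds_gamma):
            raise ValueError(f"blocks[{i}].gamma_scaffold out of range")
        if b.n_genes < 1:
            raise ValueError(f"blocks[{i}].n_genes must be >= 1")
        for side, start in (("beta", b.beta_start), ("gamma", b.gamma_start)):
            if start < 0 or start + b.n_genes > spec.genes_per_scaffold:
                raise ValueError(
                    f"blocks[{i}] exceeds the {side} gene universe "
                    f"({start}+{b.n_genes} > {spec.genes_per_scaffold})"
                )
    for side in ("beta", "gamma"):
        seen: set[tuple[int, int]] = set()
        for i, b in enumerate(spec.blocks):
            scaf = getattr(b, f"{side}_scaffold")
            start = getattr(b, f"{side}_start")
            coords = {(scaf, start + t) for t in range(b.n_genes)}
            if coords & seen:
                raise ValueError(f"blocks[{i}] overlaps another block on {side}")
            seen |= coords
    for i, d in enumerate(spec.duplications):
        if not (0 <= d.block < len(spec.blocks)):
            raise ValueError(f"duplications[{i}].block out of range")
        if d.placement not in ("spread", "tandem"):
            raise ValueError(f"duplications[{i}].placement must be spread|tandem")


def _random_bases(n: int, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_codons(n_bp: int, rng: np.random.Generator) -> str:
    assert n_bp % 3 == 0
    return "".join(_SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS), n_bp // 3)])


def _build_skeletons(
    spec: SyntheticSpec, rng_struct: np.random.Generator
) -> tuple[list[list[_GeneSkel]], list[list[_GeneSkel]], list[tuple]]:
    def org_skeleton(prefix: str, n_scaffolds: int) -> list[list[_GeneSkel]]:
        scaffolds = []
        for si in range(n_scaffolds):
            genes = []
            for j in range(spec.genes_per_scaffold):
                n_ex = int(rng_struct.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
                lens = [
                    3 * int(rng_struct.integers(spec.exon_bp[0] // 3, spec.exon_bp[1] // 3 + 1))
                    for _ in range(n_ex)
                ]
                strand = "+" if rng_struct.random() < 0.5 else "-"
                genes.append(_GeneSkel(f"{prefix}{si + 1}g{j + 1:03d}", lens, strand))
            scaffolds.append(genes)
        return scaffolds

    beta = org_skeleton("b", spec.scaffolds_beta)
    gamma = org_skeleton("g", spec.scaffolds_gamma)
    ops: list[tuple] = []

    for bi, block in enumerate(spec.blocks):
        key = f"block{bi}"
        for t in range(block.n_genes):
            src = beta[block.beta_scaffold][block.beta_start + t]
            dst = gamma[block.gamma_scaffold][block.gamma_start + t]
            dst.exon_lens = list(src.exon_lens)
            dst.pair = [f"{src.gid}.e{k + 1}" for k in range(len(src.exon_lens))]
            dst.evalue = block.evalue
            dst.block_key = key

    for di, dup in enumerate(spec.duplications):
        block = spec.blocks[dup.block]
        sources = [
            gamma[block.gamma_scaffold][block.gamma_start + t] for t in range(block.n_genes)
        ]
        for c in range(1, dup.n_copies + 1):
            copies = [
                _GeneSkel(
                    f"{s.gid}c{c}", list(s.exon_lens), s.strand,
                    pair=list(s.pair) if s.pair else None,
                    evalue=s.evalue,
                    block_key=f"block{dup.block}.copy{c}",
                )
                for s in sources
            ]
            if dup.placement == "spread":
                target = (block.gamma_scaffold + c) % spec.scaffolds_gamma
                gamma[target].extend(copies)
            else:  # tandem
                at = block.gamma_start + block.n_genes + (c - 1) * block.n_genes
                gamma[block.gamma_scaffold][at:at] = copies
        ops.append(("duplicate", dup.block, dup.n_copies, dup.placement))

    for op in spec.rearrangements:
        kind = op[0]
        if kind == "split":
            _, scaf, gene_idx = op
            moved = gamma[scaf][gene_idx:]
            del gamma[scaf][gene_idx:]
            gamma.append(moved)
        elif kind == "fuse":
            _, i, j = op
            gamma[i].extend(gamma[j])
            del gamma[j]
        elif kind == "invert":
            _, scaf, start, n = op
            segment = gamma[scaf][start : start + n][::-1]
            for gs in segment:
                gs.strand = "+" if gs.strand == "-" else "-"
            gamma[scaf][start : start + n] = segment
        else:
            raise ValueError(f"unknown rearrangement op {kind!r}")
        ops.append(tuple(op))
    return beta, gamma, ops


def _realize(
    prefix: str,
    organism_id: str,
    scaffolds: list[list[_GeneSkel]],
    spec: SyntheticSpec,
    rng_struct: np.random.Generator,
    rng_seq: np.random.Generator,
    beta_coding: dict[str, str] | None = None,
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Lay out coordinates and sequences for one organism's skeleton.

    Paired exons copy the partner's strand-read coding sequence (reverse
    complemented into the genome as strand demands) so translated
    peptides are identical.
    """
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    coding_out: dict[str, str] = {}
    for si, gene_skels in enumerate(scaffolds):
        name = f"{prefix}{si + 1}"
        parts: list[str] = []
        pos = 0
        for gs in gene_skels:
            gap = int(rng_struct.integers(*spec.intergenic_bp))
            parts.append(_random_bases(gap, rng_seq))
            pos += gap
            n_ex = len(gs.exon_lens)
            lens_genomic = gs.exon_lens if gs.strand == "+" else gs.exon_lens[::-1]
            exon_rows: list[tuple[int, Region, str]] = []
            for k, length in enumerate(lens_genomic):
                t = k if gs.strand == "+" else n_ex - 1 - k  # transcription index
                if gs.pair is not None:
                    coding = beta_coding[gs.pair[t]]
                    assert len(coding) == length
                else:
                    coding = _random_codons(length, rng_seq)
                parts.append(coding if gs.strand == "+" else reverse_complement(coding))
                exon_rows.append((t, Region(name, pos, pos + length), coding))
                pos += length
                if k < n_ex - 1:
                    intron = int(rng_struct.integers(*spec.intron_bp))
                    parts.append(_random_bases(intron, rng_seq))
                    pos += intron
            exons = []
            for t, region, coding in sorted(exon_rows):
                exon_id = f"{gs.gid}.e{t + 1}"
                exons.append(Exon(exon_id, gs.gid, name, gs.strand, region, 0))
                coding_out[exon_id] = coding
            genes.append(Gene(gs.gid, name, gs.strand, exons))
        tail = int(rng_struct.integers(*spec.intergenic_bp))
        parts.append(_random_bases(tail, rng_seq))
        sequences[name] = "".join(parts)
    genes.sort(key=lambda g: (g.scaffold, g.span.start, g.gene_id))
    annotation = GenomeAnnotation(organism_id, sequences, genes)
    translate_exons(annotation)
    return annotation, coding_out


def _planted_pairings(
    gamma_skeleton: list[list[_GeneSkel]],
) -> list[tuple[str, str, float, str]]:
    out = []
    for gene_skels in gamma_skeleton:
        for gs in gene_skels:
            if gs.pair is None:
                continue
            for t in range(len(gs.exon_lens)):
                out.append((gs.pair[t], f"{gs.gid}.e{t + 1}", gs.evalue, gs.block_key))
    return out


def _full_coverage_hit(
    annotation_beta: GenomeAnnotation,
    annotation_gamma: GenomeAnnotation,
    beta_exon: str,
    gamma_exon: str,
    evalue: float,
) -> Hit:
    eb = annotation_beta.exon(beta_exon)
    eg = annotation_gamma.exon(gamma_exon)
    return make_hit(eb, eg, (1, len(eb.peptide)), (1, len(eg.peptide)), evalue)


def _noise_hits(
    spec: SyntheticSpec,
    annotation_beta: GenomeAnnotation,
    annotation_gamma: GenomeAnnotation,
    forbidden: set[tuple[str, str]],
    rng_hits: np.random.Generator,
) -> list[Hit]:
    beta_ids = [e.exon_id for e in annotation_beta.exons() if e.peptide]
    gamma_ids = [e.exon_id for e in annotation_gamma.exons() if e.peptide]
    taken = set(forbidden)
    out: list[Hit] = []
    while len(out) < spec.n_noise:
        pair = (
            beta_ids[int(rng_hits.integers(0, len(beta_ids)))],
            gamma_ids[int(rng_hits.integers(0, len(gamma_ids)))],
        )
        if pair in taken:
            continue
        taken.add(pair)
        quality = float(rng_hits.beta(*spec.noise_beta))
        out.append(
            _full_coverage_hit(
                annotation_beta, annotation_gamma, pair[0], pair[1], 1.0 - quality
            )
        )
    return out


def _assemble(
    spec: SyntheticSpec,
    annotation_beta: GenomeAnnotation,
    annotation_gamma: GenomeAnnotation,
    pairings: list[tuple[str, str, float, str]],
    ops: list[tuple],
    rng_hits: np.random.Generator,
) -> tuple[HitSet, GroundTruth]:
    planted = [
        _full_coverage_hit(annotation_beta, annotation_gamma, eb, eg, ev)
        for eb, eg, ev, _ in pairings
    ]
    forbidden = {(eb, eg) for eb, eg, _, _ in pairings}
    noise = _noise_hits(spec, annotation_beta, annotation_gamma, forbidden, rng_hits)
    hitset = HitSet.from_hits(planted + noise, "beta", "gamma")
    id_of = {(h.exon_beta, h.exon_gamma): h.hit_id for h in hitset.hits}
    blocks: dict[str, set[int]] = {}
    for eb, eg, _, key in pairings:
        blocks.setdefault(key, set()).add(id_of[(eb, eg)])
    truth = GroundTruth(
        blocks={k: frozenset(v) for k, v in sorted(blocks.items())},
        expected_recovered={k: len(v) >= 2 for k, v in sorted(blocks.items())},
        ops=ops,
    )
    return hitset, truth


def generate(spec: SyntheticSpec) -> GenerationResult:
    """Materialize a full fixture: two annotations, a HitSet, ground truth."""
    _validate(spec)
    rng_struct = np.random.default_rng(np.random.SeedSequence(_STRUCTURE_ENTROPY))
    rng_seq = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rng_hits = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    beta_skel, gamma_skel, ops = _build_skeletons(spec, rng_struct)
    annotation_beta, beta_coding = _realize(
        "b", "beta", beta_skel, spec, rng_struct, rng_seq
    )
    annotation_gamma, _ = _realize(
        "g", "gamma", gamma_skel, spec, rng_struct, rng_seq, beta_coding=beta_coding
    )
    pairings = _planted_pairings(gamma_skel)
    hitset, truth = _assemble(
        spec, annotation_beta, annotation_gamma, pairings, ops, rng_hits
    )
    log.info(
        "synthetic fixture: %d+%d scaffolds, %d planted + %d noise hits, %d blocks",
        spec.scaffolds_beta,
        spec.scaffolds_gamma,
        len(pairings),
        spec.n_noise,
        len(truth.blocks),
    )
    return GenerationResult(spec, annotation_beta, annotation_gamma, hitset, truth)


def generate_noise_replicates(spec: SyntheticSpec, n_replicates: int) -> Iterator[HitSet]:
    """Independent pure-noise HitSets over one fixed genome pair.

    Drives the family-wise type-I error property; the spec must plant no
    blocks.  Replicate i is reproducible from (spec.seed, i).
    """
    if spec.blocks:
        raise ValueError("noise replicates require a spec with zero planted blocks")
    base = generate(spec)
    yield base.hitset
    for i in range(1, n_replicates):
        rng_hits = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        noise = _noise_hits(
            spec, base.annotation_beta, base.annotation_gamma, set(), rng_hits
        )
        yield HitSet.from_hits(noise, "beta", "gamma")


def write_fixture(result: GenerationResult, outdir) -> dict[str, Path]:
    """Write FASTA/GFF3, per-direction BLAST tabular files, the merged hit
    table, the ground truth and a manifest recording the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for side, annotation in (
        ("beta", result.annotation_beta),
        ("gamma", result.annotation_gamma),
    ):
        paths[f"{side}_fasta"] = outdir / f"{side}.fasta"
        paths[f"{side}_gff3"] = outdir / f"{side}.gff3"
        write_genome_fasta(annotation, paths[f"{side}_fasta"])
        write_gff3(annotation, paths[f"{side}_gff3"])
    paths["hits_beta_gamma"] = outdir / "hits_beta_gamma.tsv"
    paths["hits_gamma_beta"] = outdir / "hits_gamma_beta.tsv"
    with open(paths["hits_beta_gamma"], "w") as fwd, open(
        paths["hits_gamma_beta"], "w"
    ) as rev:
        for h in result.hitset.hits:
            lb = h.pep_beta[1] - h.pep_beta[0] + 1
            lg = h.pep_gamma[1] - h.pep_gamma[0] + 1
            fwd.write(
                f"{h.exon_beta}\t{h.exon_gamma}\t100.00\t{lb}\t0\t0\t"
                f"{h.pep_beta[0]}\t{h.pep_beta[1]}\t{h.pep_gamma[0]}\t{h.pep_gamma[1]}\t"
                f"{h.evalue:.3g}\t{2 * lb:.1f}\n"
            )
            rev.write(
                f"{h.exon_gamma}\t{h.exon_beta}\t100.00\t{lg}\t0\t0\t"
                f"{h.pep_gamma[0]}\t{h.pep_gamma[1]}\t{h.pep_beta[0]}\t{h.pep_beta[1]}\t"
                f"{h.evalue:.3g}\t{2 * lg:.1f}\n"
            )
    paths["hit_table"] = outdir / "hits.tsv"
    write_hit_table(result.hitset, paths["hit_table"])
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "blocks": {k: sorted(v) for k, v in result.truth.blocks.items()},
                "expected_recovered": result.truth.expected_recovered,
                "ops": [list(op) for op in result.truth.ops],
            },
            fh,
            indent=2,
        )
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(dataclasses.asdict(result.spec), fh, indent=2, default=list)
    return paths


def random_hitset(seed: int, n_hits: int, coord_span: int = 100_000) -> HitSet:
    """Bare random hits on one scaffold pair (for clustering-level tests).

    Each hit gets its own dummy exon pair; regions are uniform within the
    coordinate span, qualities uniform in [0, 1].
    """
    rng = np.random.default_rng(seed)
    hits = []
    for i in range(n_hits):
        rb_start = int(rng.integers(0, coord_span))
        rg_start = int(rng.integers(0, coord_span))
        rb_len = int(rng.integers(30, 300))
        rg_len = int(rng.integers(30, 300))
        hits.append(
            Hit(
                hit_id=-1,
                exon_beta=f"xb{i}",
                exon_gamma=f"xg{i}",
                region_beta=Region("b1", rb_start, rb_start + rb_len),
                region_gamma=Region("g1", rg_start, rg_start + rg_len),
                pep_beta=(1, max(1, rb_len // 3)),
                pep_gamma=(1, max(1, rg_len // 3)),
                evalue=0.0,
                quality=float(rng.random()),
            )
        )
    return HitSet.from_hits(hits, "beta", "gamma")
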