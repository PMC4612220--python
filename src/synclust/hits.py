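"""Bi-directional protein hits between the exons of two organisms.

The mapping between organisms β and γ is a set of bi-directional hits: an
exon pair reported by the aligner in *both* query directions with mutually
overlapping aligned footprints.  Each hit h carries a genomic region on
each organism, an e-value E(h) and a quality score

    K(h) = (1 − min(1, E(h))) · (‖r_β‖ + ‖r_γ‖) / (‖x_β‖ + ‖x_γ‖)

combining alignment significance with the fraction of the two exons the
aligned regions cover; K ∈ [0, 1] with 1 the perfect score.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome_model import Exon, GenomeAnnotation, Region

log = logging.getLogger(__name__)

__all__ = [
    "DirectionalHit",
    "Hit",
    "HitSet",
    "parse_blast_tabular",
    "map_to_genomic",
    "hit_quality",
    "make_bidirectional",
    "run_external_aligner",
    "write_hit_table",
    "read_hit_table",
]

_BLAST_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


@dataclass(frozen=True)
class DirectionalHit:
    """One raw alignment record from a single query direction."""

    query_exon_id: str
    subject_exon_id: str
    query_aln: tuple[int, int]  # 1-based inclusive peptide coordinates
    subject_aln: tuple[int, int]
    evalue: float
    bitscore: float


@dataclass
class Hit:
    """A bi-directional match: one region on each organism plus K."""

    hit_id: int
    exon_beta: str
    exon_gamma: str
    region_beta: Region
    region_gamma: Region
    pep_beta: tuple[int, int]
    pep_gamma: tuple[int, int]
    evalue: float
    quality: float


class HitSet:
    """The hit universe H with its per-exon and per-scaffold-pair indexes."""

    def __init__(self, hits: list[Hit], beta_org: str, gamma_org: str):
        self.hits = hits
        self.beta_org = beta_org
        self.gamma_org = gamma_org
        self.by_scaffold_pair: dict[tuple[str, str], list[Hit]] = defaultdict(list)
        self.best_beta: dict[str, Hit] = {}
        self.best_gamma: dict[str, Hit] = {}
        for h in hits:
            self.by_scaffold_pair[(h.region_beta.scaffold, h.region_gamma.scaffold)].append(h)
            for index, exon_id in ((self.best_beta, h.exon_beta), (self.best_gamma, h.exon_gamma)):
                cur = index.get(exon_id)
                if cur is None or h.quality > cur.quality:
                    index[exon_id] = h
        self.by_scaffold_pair = dict(self.by_scaffold_pair)

    def __len__(self) -> int:
        return len(self.hits)

    @classmethod
    def from_hits(cls, hits: Iterable[Hit], beta_org: str, gamma_org: str) -> "HitSet":
        """Assign deterministic hit_ids in (scaffold, start) sort order."""
        ordered = sorted(
            hits,
            key=lambda h: (
                h.region_beta.scaffold,
                h.region_beta.start,
                h.region_beta.end,
                h.region_gamma.scaffold,
                h.region_gamma.start,
                h.region_gamma.end,
                h.exon_beta,
                h.exon_gamma,
                h.evalue,
            ),
        )
        renumbered = [
            Hit(i, h.exon_beta, h.exon_gamma, h.region_beta, h.region_gamma,
                h.pep_beta, h.pep_gamma, h.evalue, h.quality)
            for i, h in enumerate(ordered)
        ]
        return cls(renumbered, beta_org, gamma_org)

    def best_quality(self, side: str, exon_id: str) -> float:
        """Highest K of any hit genome-wide touching this exon (0 if none)."""
        index = self.best_beta if side == "beta" else self.best_gamma
        h = index.get(exon_id)
        return h.quality if h is not None else 0.0

    def has_hit(self, side: str, exon_id: str) -> bool:
        index = self.best_beta if side == "beta" else self.best_gamma
        return exon_id in index


def parse_blast_tabular(
    source, query_annotation: GenomeAnnotation, subject_annotation: GenomeAnnotation
) -> list[DirectionalHit]:
    """Parse a 12-column BLAST tabular (-outfmt 6) file of exon-vs-exon hits.

    qseqid/sseqid are exon_ids.  Rows naming unknown exons are dropped with
    a warning; a row with the wrong column count is a hard error naming the
    line.
    """
    out: list[DirectionalHit] = []
    dropped = 0
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_COLUMNS:
                raise ValueError(
                    f"{source}: line {lineno}: expected {_BLAST_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            if not query_annotation.has_exon(q) or not subject_annotation.has_exon(s):
                dropped += 1
                log.warning("%s: line %d: unknown exon id (%s, %s); dropped", source, lineno, q, s)
                continue
            out.append(
                DirectionalHit(
                    query_exon_id=q,
                    subject_exon_id=s,
                    query_aln=(int(fields[6]), int(fields[7])),
                    subject_aln=(int(fields[8]), int(fields[9])),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    if dropped:
        log.info("%s: dropped %d rows with unknown exon ids", source, dropped)
    return out


def map_to_genomic(exon: Exon, peptide_interval: tuple[int, int]) -> Region:
    """Genomic sub-interval covering peptide positions [p1, p2] of an exon.

    For '+' strand the interval is measured from the exon start plus the
    frame offset; for '−' strand the equivalent interval is measured from
    the exon end leftward.
    """
    p1, p2 = peptide_interval
    n_pep = len(exon.peptide) if exon.peptide else (exon.length - exon.frame_offset) // 3
    if not (1 <= p1 <= p2 <= n_pep):
        raise ValueError(
            f"peptide interval {peptide_interval} outside [1, {n_pep}] of exon {exon.exon_id}"
        )
    if exon.strand == "+":
        start = exon.region.start + exon.frame_offset + 3 * (p1 - 1)
        end = exon.region.start + exon.frame_offset + 3 * p2
    else:
        end = exon.region.end - exon.frame_offset - 3 * (p1 - 1)
        start = exon.region.end - exon.frame_offset - 3 * p2
    region = Region(exon.scaffold, start, end)
    assert exon.region.contains(region)
    return region


def hit_quality(
    region_beta: Region, region_gamma: Region, exon_beta: Exon, exon_gamma: Exon, evalue: float
) -> float:
    """K(h): e-value-weighted fraction of the two exons covered by the hit."""
    coverage = (region_beta.length + region_gamma.length) / (
        exon_beta.length + exon_gamma.length
    )
    return (1.0 - min(1.0, evalue)) * coverage


def make_hit(
    exon_beta: Exon,
    exon_gamma: Exon,
    pep_beta: tuple[int, int],
    pep_gamma: tuple[int, int],
    evalue: float,
) -> Hit:
    """Construct a hit (id unassigned) from peptide-coordinate footprints."""
    rb = map_to_genomic(exon_beta, pep_beta)
    rg = map_to_genomic(exon_gamma, pep_gamma)
    k = hit_quality(rb, rg, exon_beta, exon_gamma, evalue)
    return Hit(-1, exon_beta.exon_id, exon_gamma.exon_id, rb, rg, pep_beta, pep_gamma, evalue, k)


def _intersect(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def make_bidirectional(
    hits_beta_to_gamma: list[DirectionalHit],
    hits_gamma_to_beta: list[DirectionalHit],
    annotation_beta: GenomeAnnotation,
    annotation_gamma: GenomeAnnotation,
) -> HitSet:
    """Merge the two query directions into the bi-directional hit set H.

    An exon pair produces hits only if reported in both directions with
    aligned intervals overlapping by ≥1 peptide position on each exon.
    Each reciprocal alignment pairing that overlaps yields one hit whose
    footprint per exon is the intersection of the two directions'
    intervals and whose e-value is the (conservative) max of the two.
    """
    fwd: dict[tuple[str, str], list[DirectionalHit]] = defaultdict(list)
    rev: dict[tuple[str, str], list[DirectionalHit]] = defaultdict(list)
    for dh in hits_beta_to_gamma:
        fwd[(dh.query_exon_id, dh.subject_exon_id)].append(dh)
    for dh in hits_gamma_to_beta:
        rev[(dh.subject_exon_id, dh.query_exon_id)].append(dh)
    reciprocal = sorted(set(fwd) & set(rev))
    n_onesided = len(set(fwd) ^ set(rev))
    merged: list[Hit] = []
    for pair in reciprocal:
        eb = annotation_beta.exon(pair[0])
        eg = annotation_gamma.exon(pair[1])
        seen: dict[tuple, float] = {}
        for a in fwd[pair]:
            for b in rev[pair]:
                ib = _intersect(a.query_aln, b.subject_aln)
                ig = _intersect(a.subject_aln, b.query_aln)
                if ib is None or ig is None:
                    continue
                ev = max(a.evalue, b.evalue)
                key = (ib, ig)
                if key not in seen or ev < seen[key]:
                    seen[key] = ev
        for (ib, ig), ev in sorted(seen.items()):
            merged.append(make_hit(eb, eg, ib, ig, ev))
    hitset = HitSet.from_hits(merged, annotation_beta.organism_id, annotation_gamma.organism_id)
    log.info(
        "bidirectional merge: %d reciprocal exon pairs -> %d hits "
        "(%d one-sided pairs discarded)",
        len(reciprocal),
        len(hitset),
        n_onesided,
    )
    return hitset


def run_external_aligner(
    fasta_beta, fasta_gamma, workdir, aligner_cmd: str | None = None
) -> tuple[Path, Path]:
    """All-vs-all protein alignment in both directions via an external binary.

    Default: NCBI makeblastdb + blastp with default parameters, tabular
    output.  ``aligner_cmd`` may be a template with {query} {subject}
    {out} placeholders.  Users with precomputed tables bypass this
    entirely.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out_bg = workdir / "beta_vs_gamma.tsv"
    out_gb = workdir / "gamma_vs_beta.tsv"
    if aligner_cmd is not None:
        for query, subject, out in (
            (fasta_beta, fasta_gamma, out_bg),
            (fasta_gamma, fasta_beta, out_gb),
        ):
            cmd = aligner_cmd.format(query=query, subject=subject, out=out)
            subprocess.run(cmd, shell=True, check=True)
        return out_bg, out_gb
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError(
            "no protein aligner found on PATH (blastp/makeblastdb); either "
            "install BLAST+ or supply precomputed tabular hit files"
        )
    for fasta in (fasta_beta, fasta_gamma):
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
    for query, subject, out in (
        (fasta_beta, fasta_gamma, out_bg),
        (fasta_gamma, fasta_beta, out_gb),
    ):
        subprocess.run(
            ["blastp", "-query", str(query), "-db", str(subject),
             "-outfmt", "6", "-out", str(out)],
            check=True,
            capture_output=True,
        )
    return out_bg, out_gb


_TABLE_HEADER = (
    "hit_id\texon_beta\texon_gamma\tscaffold_beta\tstart_beta\tend_beta\t"
    "scaffold_gamma\tstart_gamma\tend_gamma\tpep_beta_start\tpep_beta_end\t"
    "pep_gamma_start\tpep_gamma_end\tevalue\tquality\n"
)


def write_hit_table(hitset: HitSet, destination) -> None:
    """Checkpoint/exchange format: merged hit table, 1-based coordinates."""
    with open(destination, "w") as fh:
        fh.write(f"# beta={hitset.beta_org}\tgamma={hitset.gamma_org}\n")
        fh.write(_TABLE_HEADER)
        for h in hitset.hits:
            fh.write(
                f"{h.hit_id}\t{h.exon_beta}\t{h.exon_gamma}\t"
                f"{h.region_beta.scaffold}\t{h.region_beta.start1}\t{h.region_beta.end1}\t"
                f"{h.region_gamma.scaffold}\t{h.region_gamma.start1}\t{h.region_gamma.end1}\t"
                f"{h.pep_beta[0]}\t{h.pep_beta[1]}\t{h.pep_gamma[0]}\t{h.pep_gamma[1]}\t"
                f"{h.evalue:.6g}\t{h.quality:.10g}\n"
            )


def read_hit_table(source) -> HitSet:
    hits: list[Hit] = []
    beta_org, gamma_org = "beta", "gamma"
    with open(source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = dict(p.split("=", 1) for p in line[1:].split("\t") if "=" in p)
                beta_org = parts.get("beta", beta_org).strip()
                gamma_org = parts.get("gamma", gamma_org).strip()
                continue
            if line.startswith("hit_id") or not line:
                continue
            f = line.split("\t")
            hits.append(
                Hit(
                    hit_id=int(f[0]),
                    exon_beta=f[1],
                    exon_gamma=f[2],
                    region_beta=Region.from_1based(f[3], int(f[4]), int(f[5])),
                    region_gamma=Region.from_1based(f[6], int(f[7]), int(f[8])),
                    pep_beta=(int(f[9]), int(f[10])),
                    pep_gamma=(int(f[11]), int(f[12])),
                    evalue=float(f[13]),
                    quality=float(f[14]),
                )
            )
    return HitSet(hits, beta_org, gamma_org)
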