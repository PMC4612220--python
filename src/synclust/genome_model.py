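"""Genome and annotation model.

Reads a genome (FASTA) together with its GFF3 annotation, builds the
gene/exon model, translates exon coding sequence to peptides and owns all
coordinate conventions.

Coordinates are stored 0-based half-open internally.  Every file interface
converts to/from the format's native convention: GFF3 and Circos files are
1-based inclusive, BED is 0-based half-open.  :class:`Region` exposes both
views so downstream arithmetic never has to guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "Region",
    "Exon",
    "Gene",
    "GenomeAnnotation",
    "load_annotation",
    "translate_exons",
    "write_exon_fasta",
    "write_genome_fasta",
    "write_gff3",
]


@dataclass(frozen=True, order=True)
class Region:
    """A genomic interval on one scaffold, 0-based half-open internally."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"degenerate region {self.scaffold}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        """Length in bp (equals end − start + 1 in 1-based inclusive terms)."""
        return self.end - self.start

    @property
    def start1(self) -> int:
        """1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end."""
        return self.end

    @classmethod
    def from_1based(cls, scaffold: str, start1: int, end1: int) -> "Region":
        return cls(scaffold, start1 - 1, end1)

    def contains(self, other: "Region") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )

    def hull(self, other: "Region") -> "Region":
        if self.scaffold != other.scaffold:
            raise ValueError("hull of regions on different scaffolds")
        return Region(self.scaffold, min(self.start, other.start), max(self.end, other.end))


@dataclass
class Exon:
    """An annotated coding interval; the atomic unit of homology.

    ``frame_offset`` is the number of bases (0–2) to skip, reading in
    transcription direction, before the first complete codon — the GFF3
    CDS phase.  ``peptide`` is filled by :func:`translate_exons`.
    """

    exon_id: str
    gene_id: str
    scaffold: str
    strand: str
    region: Region
    frame_offset: int = 0
    peptide: str = ""

    @property
    def length(self) -> int:
        return self.region.length


@dataclass
class Gene:
    gene_id: str
    scaffold: str
    strand: str
    exons: list[Exon]
    span: Region = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        start = min(e.region.start for e in self.exons)
        end = max(e.region.end for e in self.exons)
        self.span = Region(self.scaffold, start, end)


@dataclass
class GenomeAnnotation:
    """One organism: its scaffolds and its gene/exon model."""

    organism_id: str
    sequences: dict[str, str]
    genes: list[Gene]

    def __post_init__(self) -> None:
        self._exons_by_id: dict[str, Exon] = {}
        self._gene_by_id: dict[str, Gene] = {}
        for gene in self.genes:
            if gene.scaffold not in self.sequences:
                raise ValueError(
                    f"gene {gene.gene_id} on unknown scaffold {gene.scaffold!r}"
                )
            self._gene_by_id[gene.gene_id] = gene
            for exon in gene.exons:
                if exon.exon_id in self._exons_by_id:
                    raise ValueError(f"duplicate exon_id {exon.exon_id}")
                if exon.region.end > len(self.sequences[exon.scaffold]):
                    raise ValueError(
                        f"exon {exon.exon_id} extends past the end of {exon.scaffold}"
                    )
                self._exons_by_id[exon.exon_id] = exon

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def exons(self) -> Iterator[Exon]:
        for gene in self.genes:
            yield from gene.exons

    def exon(self, exon_id: str) -> Exon:
        return self._exons_by_id[exon_id]

    def has_exon(self, exon_id: str) -> bool:
        return exon_id in self._exons_by_id

    def gene(self, gene_id: str) -> Gene:
        return self._gene_by_id[gene_id]

    def gene_of_exon(self, exon_id: str) -> str:
        return self._exons_by_id[exon_id].gene_id

    @property
    def n_exons(self) -> int:
        return len(self._exons_by_id)


def _transcription_sorted(exons: list[Exon]) -> list[Exon]:
    if exons and exons[0].strand == "-":
        return sorted(exons, key=lambda e: -e.region.start)
    return sorted(exons, key=lambda e: e.region.start)


def load_annotation(fasta_source, gff3_source, organism_id: str) -> GenomeAnnotation:
    """Read genome FASTA + GFF3 into a validated :class:`GenomeAnnotation`.

    CDS features take precedence over exon features for each gene (only
    coding sequence is translated downstream); genes without any coding
    feature are skipped with a warning.  Features shared by several mRNAs
    are deduplicated by (interval, strand, frame).  Stable exon_ids are
    assigned as ``<gene_id>.e<ordinal>`` in transcription order.
    """
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_source), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_source),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[Gene] = []
    for gfeat in db.features_of_type("gene", order_by=("seqid", "start")):
        if gfeat.seqid not in sequences:
            raise ValueError(
                f"GFF3 references scaffold {gfeat.seqid!r} absent from the FASTA"
            )
        feats = list(db.children(gfeat, featuretype="CDS"))
        if not feats:
            feats = [f for f in db.children(gfeat, featuretype="exon")]
            for f in feats:
                f.frame = "0"
        if not feats:
            log.warning("gene %s has no coding features; skipped", gfeat.id)
            continue
        seen: set[tuple[int, int, str, int]] = set()
        exons: list[Exon] = []
        for f in feats:
            frame = int(f.frame) if f.frame in ("0", "1", "2") else 0
            key = (f.start, f.end, f.strand, frame)
            if key in seen:
                continue
            seen.add(key)
            exons.append(
                Exon(
                    exon_id="",
                    gene_id=gfeat.id,
                    scaffold=gfeat.seqid,
                    strand=f.strand,
                    region=Region.from_1based(gfeat.seqid, f.start, f.end),
                    frame_offset=frame,
                )
            )
        exons = _transcription_sorted(exons)
        for i, exon in enumerate(exons):
            exon.exon_id = f"{gfeat.id}.e{i + 1}"
        genes.append(Gene(gfeat.id, gfeat.seqid, gfeat.strand, exons))
    genes.sort(key=lambda g: (g.scaffold, g.span.start, g.gene_id))
    annotation = GenomeAnnotation(organism_id, sequences, genes)
    log.info(
        "loaded %s: %d scaffolds, %d genes, %d exons",
        organism_id,
        len(sequences),
        len(genes),
        annotation.n_exons,
    )
    return annotation


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def coding_sequence(annotation: GenomeAnnotation, exon: Exon) -> str:
    """Strand-read nucleotide sequence of the exon, before frame trimming."""
    raw = annotation.sequences[exon.scaffold][exon.region.start : exon.region.end]
    return reverse_complement(raw) if exon.strand == "-" else raw


def translate_exons(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Fill every exon's ``peptide`` with its standard-code translation.

    Minus-strand exons are reverse-complemented first; ``frame_offset``
    bases are skipped, a trailing partial codon is dropped, internal stop
    codons are kept as ``*`` (homology is the aligner's judgement call,
    not the parser's).
    """
    for exon in annotation.exons():
        nt = coding_sequence(annotation, exon)[exon.frame_offset :]
        n_codons = len(nt) // 3
        if n_codons == 0:
            log.warning("exon %s shorter than one codon; empty peptide", exon.exon_id)
            exon.peptide = ""
        else:
            exon.peptide = str(Seq(nt[: 3 * n_codons]).translate())
    return annotation


def write_exon_fasta(annotation: GenomeAnnotation, destination) -> int:
    """Write one protein FASTA record per exon with a non-empty peptide."""
    n = 0
    with open(destination, "w") as fh:
        for exon in annotation.exons():
            if not exon.peptide:
                continue
            fh.write(f">{exon.exon_id}\n{exon.peptide}\n")
            n += 1
    return n


def write_genome_fasta(annotation: GenomeAnnotation, destination, width: int = 70) -> None:
    with open(destination, "w") as fh:
        for name in sorted(annotation.sequences):
            fh.write(f">{name}\n")
            seq = annotation.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(annotation: GenomeAnnotation, destination) -> None:
    """Emit the gene/mRNA/exon/CDS model as GFF3 (1-based inclusive)."""
    with open(destination, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(annotation.sequences):
            fh.write(f"##sequence-region {name} 1 {len(annotation.sequences[name])}\n")
        for gene in annotation.genes:
            s, e = gene.span.start1, gene.span.end1
            fh.write(
                f"{gene.scaffold}\tsynclust\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            mrna = f"{gene.gene_id}.t1"
            fh.write(
                f"{gene.scaffold}\tsynclust\tmRNA\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={mrna};Parent={gene.gene_id}\n"
            )
            for exon in gene.exons:
                es, ee = exon.region.start1, exon.region.end1
                fh.write(
                    f"{exon.scaffold}\tsynclust\texon\t{es}\t{ee}\t.\t{exon.strand}\t.\t"
                    f"ID={exon.exon_id}.x;Parent={mrna}\n"
                )
                fh.write(
                    f"{exon.scaffold}\tsynclust\tCDS\t{es}\t{ee}\t.\t{exon.strand}\t"
                    f"{exon.frame_offset}\tID={exon.exon_id}.c;Parent={mrna}\n"
                )


def write_bed(regions: Iterable[Region], destination, names: Iterable[str] | None = None) -> None:
    """BED (0-based half-open) emission of arbitrary regions."""
    names = list(names) if names is not None else None
    with open(destination, "w") as fh:
        for i, r in enumerate(regions):
            label = names[i] if names else f"region{i}"
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{label}\n")
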