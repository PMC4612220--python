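"""Circos-ready visualization output at chromosome and region level.

Two views mirror the two scales at which synteny is explored: the
chromosome view draws one ribbon per significant cluster between a focus
scaffold and every partner scaffold, with genes as strand-colored tiles
(forward blue, reverse orange); the region view zooms into one cluster
and draws one ribbon per member hit, with exon tiles in green and ribbon
intensity a monotone function of the hit quality K.

Rendering is out of process: this module emits Circos karyotype, tile,
link and configuration files (all coordinates 1-based inclusive) and,
when matplotlib is available, a self-contained static fallback plot so
no external binary is ever required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .genome_model import GenomeAnnotation
from .hits import HitSet
from .significance import SyntenicCluster

log = logging.getLogger(__name__)

__all__ = [
    "KaryotypeEntry",
    "Tile",
    "Link",
    "VizBundle",
    "chromosome_view",
    "region_view",
    "write_circos",
    "read_links",
    "check_circos_dir",
    "render_static",
    "alpha_from_quality",
]

GENE_FWD_COLOR = "blue"
GENE_REV_COLOR = "orange"
EXON_COLOR = "green"
LINK_COLOR = "red"


def alpha_from_quality(k: float) -> float:
    """Linear map K ∈ [0,1] → ribbon opacity ∈ [0.15, 1.0]."""
    return 0.15 + 0.85 * max(0.0, min(1.0, k))


@dataclass(frozen=True)
class KaryotypeEntry:
    chrom_id: str
    label: str
    start: int  # 1-based inclusive
    end: int
    color: str = "grey"


@dataclass(frozen=True)
class Tile:
    chrom_id: str
    start: int
    end: int
    color: str


@dataclass(frozen=True)
class Link:
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    color: str = LINK_COLOR
    alpha: float = 1.0
    quality: float | None = None


@dataclass
class VizBundle:
    level: str  # "chromosome" | "region"
    karyotype: list[KaryotypeEntry] = field(default_factory=list)
    genes: list[Tile] = field(default_factory=list)
    exons: list[Tile] = field(default_factory=list)
    links: list[Link] = field(default_factory=list)

    def validate(self) -> None:
        bounds = {k.chrom_id: (k.start, k.end) for k in self.karyotype}

        def check(chrom: str, s: int, e: int, what: str) -> None:
            if chrom not in bounds:
                raise ValueError(f"{what} endpoint on unknown karyotype entry {chrom!r}")
            lo, hi = bounds[chrom]
            if not (lo <= s <= e <= hi):
                raise ValueError(f"{what} {chrom}:{s}-{e} outside karyotype [{lo},{hi}]")

        for t in self.genes + self.exons:
            check(t.chrom_id, t.start, t.end, "tile")
        for l in self.links:
            check(l.chrom1, l.start1, l.end1, "link")
            check(l.chrom2, l.start2, l.end2, "link")


def _chrom_id(organism_id: str, scaffold: str) -> str:
    return f"{organism_id}_{scaffold}"


def _gene_tiles(
    annotation: GenomeAnnotation, scaffold: str, window: tuple[int, int] | None = None
) -> tuple[list[Tile], list[Tile]]:
    """Strand-colored gene tiles (and green exon tiles) for one scaffold."""
    chrom = _chrom_id(annotation.organism_id, scaffold)
    genes: list[Tile] = []
    exons: list[Tile] = []
    for gene in annotation.genes:
        if gene.scaffold != scaffold:
            continue
        s, e = gene.span.start1, gene.span.end1
        if window is not None:
            if e < window[0] or s > window[1]:
                continue
            s, e = max(s, window[0]), min(e, window[1])
        color = GENE_FWD_COLOR if gene.strand == "+" else GENE_REV_COLOR
        genes.append(Tile(chrom, s, e, color))
        for exon in gene.exons:
            xs, xe = exon.region.start1, exon.region.end1
            if window is not None:
                if xe < window[0] or xs > window[1]:
                    continue
                xs, xe = max(xs, window[0]), min(xe, window[1])
            exons.append(Tile(chrom, xs, xe, EXON_COLOR))
    return genes, exons


def chromosome_view(
    clusters: list[SyntenicCluster],
    annotation_beta: GenomeAnnotation,
    annotation_gamma: GenomeAnnotation,
    focus_scaffold: str,
) -> VizBundle:
    """Overview of one query scaffold: one ribbon per cluster to each partner.

    The focus scaffold is placed first (it is drawn clockwise from 12
    o'clock), followed by every partner scaffold holding at least one
    cluster.
    """
    shown = [c for c in clusters if c.span_beta.scaffold == focus_scaffold]
    bundle = VizBundle(level="chromosome")
    focus_chrom = _chrom_id(annotation_beta.organism_id, focus_scaffold)
    bundle.karyotype.append(
        KaryotypeEntry(
            focus_chrom,
            focus_scaffold,
            1,
            annotation_beta.scaffold_lengths[focus_scaffold],
            "grey",
        )
    )
    partners = sorted({c.span_gamma.scaffold for c in shown})
    for scaffold in partners:
        bundle.karyotype.append(
            KaryotypeEntry(
                _chrom_id(annotation_gamma.organism_id, scaffold),
                scaffold,
                1,
                annotation_gamma.scaffold_lengths[scaffold],
                "lgrey",
            )
        )
    genes, _ = _gene_tiles(annotation_beta, focus_scaffold)
    bundle.genes.extend(genes)
    for scaffold in partners:
        genes, _ = _gene_tiles(annotation_gamma, scaffold)
        bundle.genes.extend(genes)
    for c in shown:
        bundle.links.append(
            Link(
                focus_chrom,
                c.span_beta.start1,
                c.span_beta.end1,
                _chrom_id(annotation_gamma.organism_id, c.span_gamma.scaffold),
                c.span_gamma.start1,
                c.span_gamma.end1,
                color=LINK_COLOR,
                alpha=1.0,
            )
        )
    if not shown:
        log.warning("scaffold %s has no clusters; karyotype-only bundle", focus_scaffold)
    bundle.validate()
    return bundle


def region_view(
    cluster: SyntenicCluster,
    hitset: HitSet,
    annotation_beta: GenomeAnnotation,
    annotation_gamma: GenomeAnnotation,
    flank_bp: int = 0,
) -> VizBundle:
    """Zoom into one cluster: one ribbon per member hit, intensity ∝ K."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    bundle = VizBundle(level="region")
    windows = {}
    for side, span, annotation in (
        ("beta", cluster.span_beta, annotation_beta),
        ("gamma", cluster.span_gamma, annotation_gamma),
    ):
        lo = max(1, span.start1 - flank_bp)
        hi = min(annotation.scaffold_lengths[span.scaffold], span.end1 + flank_bp)
        chrom = _chrom_id(annotation.organism_id, span.scaffold)
        windows[side] = (chrom, lo, hi)
        bundle.karyotype.append(KaryotypeEntry(chrom, span.scaffold, lo, hi, "grey"))
        genes, exons = _gene_tiles(annotation, span.scaffold, window=(lo, hi))
        bundle.genes.extend(genes)
        bundle.exons.extend(exons)
    member = [h for h in hitset.hits if h.hit_id in cluster.hit_ids]
    for h in sorted(member, key=lambda h: h.hit_id):
        bundle.links.append(
            Link(
                windows["beta"][0],
                h.region_beta.start1,
                h.region_beta.end1,
                windows["gamma"][0],
                h.region_gamma.start1,
                h.region_gamma.end1,
                color=LINK_COLOR,
                alpha=alpha_from_quality(h.quality),
                quality=h.quality,
            )
        )
    bundle.validate()
    return bundle


_CONF_TEMPLATE = """\
karyotype = karyotype.txt

<ideogram>
<spacing>
default = 0.005r
</spacing>
radius    = 0.90r
thickness = 20p
fill      = yes
</ideogram>

<plots>
<plot>
type = tile
file = genes.txt
r0   = 0.82r
r1   = 0.88r
</plot>
<plot>
type = tile
file = exons.txt
r0   = 0.76r
r1   = 0.81r
</plot>
</plots>

<links>
<link>
file      = links.txt
radius    = 0.75r
bezier_radius = 0r
ribbon    = yes
</link>
</links>

<<include etc/colors_fonts_patterns.conf>>
<<include etc/housekeeping.conf>>
"""


def write_circos(bundle: VizBundle, outdir) -> dict[str, Path]:
    """Write karyotype.txt, genes.txt, exons.txt, links.txt and circos.conf."""
    bundle.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.txt" for name in ("karyotype", "genes", "exons", "links")}
    with open(paths["karyotype"], "w") as fh:
        for k in bundle.karyotype:
            fh.write(f"chr - {k.chrom_id} {k.label} {k.start} {k.end} {k.color}\n")
    for name, tiles in (("genes", bundle.genes), ("exons", bundle.exons)):
        with open(paths[name], "w") as fh:
            for t in tiles:
                fh.write(f"{t.chrom_id} {t.start} {t.end} fill_color={t.color}\n")
    with open(paths["links"], "w") as fh:
        for l in bundle.links:
            options = f"color={l.color},alpha={l.alpha:.3f}"
            if l.quality is not None:
                options += f",k={l.quality:.4f}"
            fh.write(
                f"{l.chrom1} {l.start1} {l.end1} {l.chrom2} {l.start2} {l.end2} {options}\n"
            )
    conf = outdir / "circos.conf"
    conf.write_text(_CONF_TEMPLATE)
    paths["conf"] = conf
    return paths


def read_links(path) -> list[Link]:
    """Re-parse a links.txt file (round-trip identity with the bundle)."""
    links = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) != 7:
                raise ValueError(f"malformed links line: {line!r}")
            options = dict(kv.split("=", 1) for kv in fields[6].split(","))
            links.append(
                Link(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3], int(fields[4]), int(fields[5]),
                    color=options.get("color", LINK_COLOR),
                    alpha=float(options.get("alpha", 1.0)),
                    quality=float(options["k"]) if "k" in options else None,
                )
            )
    return links


def check_circos_dir(outdir) -> list[str]:
    """Self-contained format checker; returns a list of problems (empty = ok)."""
    outdir = Path(outdir)
    problems: list[str] = []
    bounds: dict[str, tuple[int, int]] = {}
    karyotype = outdir / "karyotype.txt"
    if not karyotype.exists():
        return [f"missing {karyotype}"]
    for line in karyotype.read_text().splitlines():
        fields = line.split()
        if len(fields) != 7 or fields[0] != "chr" or fields[1] != "-":
            problems.append(f"karyotype: bad line {line!r}")
            continue
        start, end = int(fields[4]), int(fields[5])
        if not (1 <= start <= end):
            problems.append(f"karyotype: bad range in {line!r}")
        bounds[fields[2]] = (start, end)

    def in_bounds(chrom: str, s: int, e: int, where: str) -> None:
        if chrom not in bounds:
            problems.append(f"{where}: unknown chromosome {chrom!r}")
        else:
            lo, hi = bounds[chrom]
            if not (lo <= s <= e <= hi):
                problems.append(f"{where}: {chrom}:{s}-{e} outside [{lo},{hi}]")

    for name in ("genes", "exons"):
        path = outdir / f"{name}.txt"
        if not path.exists():
            problems.append(f"missing {path}")
            continue
        for line in path.read_text().splitlines():
            fields = line.split()
            if len(fields) != 4 or not fields[3].startswith("fill_color="):
                problems.append(f"{name}: bad line {line!r}")
                continue
            in_bounds(fields[0], int(fields[1]), int(fields[2]), name)
    links = outdir / "links.txt"
    if not links.exists():
        problems.append(f"missing {links}")
    else:
        for line in links.read_text().splitlines():
            fields = line.split()
            if len(fields) != 7:
                problems.append(f"links: bad line {line!r}")
                continue
            in_bounds(fields[0], int(fields[1]), int(fields[2]), "links")
            in_bounds(fields[3], int(fields[4]), int(fields[5]), "links")
            if "color=" not in fields[6]:
                problems.append(f"links: missing color option in {line!r}")
    if not (outdir / "circos.conf").exists():
        problems.append("missing circos.conf")
    return problems


def render_static(bundle: VizBundle, path) -> None:
    """Two-track linear fallback plot (no Circos binary required)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import ConnectionPatch

    fig, (ax_top, ax_bot) = plt.subplots(2, 1, figsize=(10, 4), sharex=False)
    rows = {}
    offsets = {0: 0, 1: 0}
    for i, k in enumerate(bundle.karyotype):
        row = 0 if i == 0 else 1
        ax = ax_top if row == 0 else ax_bot
        x0 = offsets[row]
        ax.broken_barh([(x0, k.end - k.start + 1)], (0.4, 0.2), facecolors="lightgrey")
        ax.text(x0, 0.7, k.label, fontsize=8)
        rows[k.chrom_id] = (row, x0 - k.start)
        offsets[row] = x0 + (k.end - k.start + 1) * 1.05
    for t in bundle.genes:
        row, shift = rows[t.chrom_id]
        ax = ax_top if row == 0 else ax_bot
        ax.broken_barh([(t.start + shift, t.end - t.start + 1)], (0.15, 0.18),
                       facecolors=t.color)
    for t in bundle.exons:
        row, shift = rows[t.chrom_id]
        ax = ax_top if row == 0 else ax_bot
        ax.broken_barh([(t.start + shift, t.end - t.start + 1)], (0.0, 0.1),
                       facecolors=t.color)
    for l in bundle.links:
        r1, s1 = rows[l.chrom1]
        r2, s2 = rows[l.chrom2]
        a1 = ax_top if r1 == 0 else ax_bot
        a2 = ax_top if r2 == 0 else ax_bot
        mid1 = (l.start1 + l.end1) / 2 + s1
        mid2 = (l.start2 + l.end2) / 2 + s2
        fig.add_artist(
            ConnectionPatch(
                xyA=(mid1, 0.4), coordsA=a1.transData,
                xyB=(mid2, 0.6), coordsB=a2.transData,
                color=l.color, alpha=l.alpha,
            )
        )
    for ax in (ax_top, ax_bot):
        ax.set_ylim(-0.1, 1.0)
        ax.set_yticks([])
    fig.savefig(path, dpi=100)
    plt.close(fig)
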