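"""Bi-directional hit construction, genomic mapping and the quality score."""

import pytest

from conftest import build_annotation, full_hit
from synclust.genome_model import Region
from synclust.hits import (
    DirectionalHit,
    HitSet,
    hit_quality,
    make_bidirectional,
    map_to_genomic,
    parse_blast_tabular,
    read_hit_table,
    write_hit_table,
)
from synclust import synthetic


ROW = "bg1.e1\tgg1.e1\t95.0\t31\t1\t0\t10\t40\t5\t35\t1e-20\t80.0\n"


class TestParseBlastTabular:
    def test_field_mapping(self, tmp_path, toy_pair):
        ann_b, ann_g = toy_pair
        path = tmp_path / "h.tsv"
        path.write_text(ROW)
        (dh,) = parse_blast_tabular(path, ann_b, ann_g)
        assert dh.query_aln == (10, 40)
        assert dh.subject_aln == (5, 35)
        assert dh.evalue == pytest.approx(1e-20)

    def test_empty_file(self, tmp_path, toy_pair):
        path = tmp_path / "h.tsv"
        path.write_text("")
        assert parse_blast_tabular(path, *toy_pair) == []

    def test_wrong_column_count_names_line(self, tmp_path, toy_pair):
        path = tmp_path / "h.tsv"
        path.write_text(ROW + "a\tb\tc\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_blast_tabular(path, *toy_pair)

    def test_unknown_exon_dropped(self, tmp_path, toy_pair):
        path = tmp_path / "h.tsv"
        path.write_text(ROW.replace("bg1.e1", "nope"))
        assert parse_blast_tabular(path, *toy_pair) == []


class TestMapToGenomic:
    def _exon(self, strand):
        ann = build_annotation("o", {"s": 300}, [("g", "s", strand, [(101, 160)])])
        return ann.genes[0].exons[0]

    def test_plus_strand_partial(self):
        assert map_to_genomic(self._exon("+"), (1, 5)) == Region.from_1based("s", 101, 115)

    def test_full_coverage_identity(self):
        assert map_to_genomic(self._exon("+"), (1, 20)) == Region.from_1based("s", 101, 160)

    def test_minus_strand_measured_from_end(self):
        assert map_to_genomic(self._exon("-"), (1, 5)) == Region.from_1based("s", 146, 160)

    def test_outside_peptide_rejected(self):
        with pytest.raises(ValueError):
            map_to_genomic(self._exon("+"), (1, 21))


class TestHitQuality:
    def _exons(self, toy_pair):
        ann_b, ann_g = toy_pair
        return ann_b.exon("bg1.e1"), ann_g.exon("gg1.e1")

    def test_perfect_score(self, toy_pair):
        eb, eg = self._exons(toy_pair)
        assert hit_quality(eb.region, eg.region, eb, eg, 0.0) == 1.0

    def test_evalue_above_one_clamps_to_zero(self, toy_pair):
        eb, eg = self._exons(toy_pair)
        assert hit_quality(eb.region, eg.region, eb, eg, 5.0) == 0.0

    def test_half_significance_quarter_coverage(self, toy_pair):
        eb, eg = self._exons(toy_pair)
        # regions 30+30 bp over exons 60+60 bp, E = 0.5
        rb = Region.from_1based("b1", 101, 130)
        rg = Region.from_1based("g1", 101, 130)
        assert hit_quality(rb, rg, eb, eg, 0.5) == pytest.approx(0.25)

    def test_quality_bounds_on_synthetic(self):
        res = synthetic.generate(
            synthetic.SyntheticSpec(seed=2, genes_per_scaffold=10, n_noise=50)
        )
        assert all(0.0 <= h.quality <= 1.0 for h in res.hitset.hits)


def _dh(q, s, qa, sa, e=1e-10):
    return DirectionalHit(q, s, qa, sa, e, 50.0)


class TestMakeBidirectional:
    def test_footprint_is_intersection(self, toy_pair):
        ann_b, ann_g = toy_pair
        hs = make_bidirectional(
            [_dh("bg1.e1", "gg1.e1", (10, 20), (5, 15), 1e-20)],
            [_dh("gg1.e1", "bg1.e1", (7, 13), (12, 18), 1e-10)],
            ann_b, ann_g,
        )
        (h,) = hs.hits
        assert h.pep_beta == (12, 18)
        assert h.pep_gamma == (7, 13)
        assert h.evalue == pytest.approx(1e-10)  # max of the two directions

    def test_one_sided_pair_discarded(self, toy_pair):
        hs = make_bidirectional(
            [_dh("bg1.e1", "gg1.e1", (1, 10), (1, 10))], [], *toy_pair
        )
        assert len(hs) == 0

    def test_multiple_hsps_enumerated(self, toy_pair):
        # two local alignments each way; only mutually overlapping pairings survive
        fwd = [
            _dh("bg1.e1", "gg1.e1", (1, 8), (1, 8)),
            _dh("bg1.e1", "gg1.e1", (12, 20), (12, 20)),
        ]
        rev = [
            _dh("gg1.e1", "bg1.e1", (1, 8), (1, 8)),
            _dh("gg1.e1", "bg1.e1", (12, 20), (12, 20)),
        ]
        hs = make_bidirectional(fwd, rev, *toy_pair)
        assert sorted((h.pep_beta, h.pep_gamma) for h in hs.hits) == [
            ((1, 8), (1, 8)),
            ((12, 20), (12, 20)),
        ]

    def test_merge_is_symmetric_in_the_two_organisms(self, toy_pair):
        ann_b, ann_g = toy_pair
        fwd = [
            _dh("bg1.e1", "gg1.e1", (3, 18), (2, 17)),
            _dh("bg2.e1", "gg3.e1", (1, 10), (5, 14)),
        ]
        rev = [
            _dh("gg1.e1", "bg1.e1", (1, 15), (5, 19)),
            _dh("gg3.e1", "bg2.e1", (4, 12), (2, 10)),
        ]
        ab = make_bidirectional(fwd, rev, ann_b, ann_g)
        ba = make_bidirectional(rev, fwd, ann_g, ann_b)
        assert {
            (h.exon_beta, h.exon_gamma, h.pep_beta, h.pep_gamma, h.evalue) for h in ab.hits
        } == {
            (h.exon_gamma, h.exon_beta, h.pep_gamma, h.pep_beta, h.evalue) for h in ba.hits
        }

    def test_regions_contained_in_exons(self, toy_pair):
        ann_b, ann_g = toy_pair
        hs = make_bidirectional(
            [_dh("bg1.e1", "gg2.e1", (5, 15), (2, 12))],
            [_dh("gg2.e1", "bg1.e1", (4, 14), (7, 17))],
            ann_b, ann_g,
        )
        for h in hs.hits:
            assert ann_b.exon(h.exon_beta).region.contains(h.region_beta)
            assert ann_g.exon(h.exon_gamma).region.contains(h.region_gamma)


class TestHitSet:
    def test_best_by_exon_matches_brute_force(self):
        res = synthetic.generate(
            synthetic.SyntheticSpec(seed=11, genes_per_scaffold=8, n_noise=60)
        )
        hs = res.hitset
        for side, attr in (("beta", "exon_beta"), ("gamma", "exon_gamma")):
            index = hs.best_beta if side == "beta" else hs.best_gamma
            for exon_id, best in index.items():
                qualities = [h.quality for h in hs.hits if getattr(h, attr) == exon_id]
                assert best.quality == max(qualities)
        assert sum(len(v) for v in hs.by_scaffold_pair.values()) == len(hs)

    def test_table_round_trip(self, tmp_path, toy_pair):
        ann_b, ann_g = toy_pair
        hs = HitSet.from_hits(
            [full_hit(ann_b, ann_g, "bg1.e1", "gg1.e1", 0.0),
             full_hit(ann_b, ann_g, "bg2.e1", "gg2.e1", 0.3)],
            "beta", "gamma",
        )
        path = tmp_path / "hits.tsv"
        write_hit_table(hs, path)
        again = read_hit_table(path)
        assert again.beta_org == "beta" and again.gamma_org == "gamma"
        assert [
            (h.hit_id, h.exon_beta, h.exon_gamma, h.region_beta, h.region_gamma, h.quality)
            for h in again.hits
        ] == [
            (h.hit_id, h.exon_beta, h.exon_gamma, h.region_beta, h.region_gamma, h.quality)
            for h in hs.hits
        ]


class TestExternalAligner:
    def test_blastp_reproduces_identical_peptide_pair(self, tmp_path):
        pytest.importorskip("shutil")
        import shutil

        if shutil.which("blastp") is None:
            pytest.skip("BLAST+ not on PATH")
        from synclust.hits import run_external_aligner

        pep = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"
        (tmp_path / "a.faa").write_text(f">ax1\n{pep}\n")
        (tmp_path / "b.faa").write_text(f">bx1\n{pep}\n")
        t_ab, t_ba = run_external_aligner(
            tmp_path / "a.faa", tmp_path / "b.faa", tmp_path / "work"
        )
        ab = t_ab.read_text()
        ba = t_ba.read_text()
        assert "ax1\tbx1" in ab and "bx1\tax1" in ba

    def test_missing_binary_is_actionable(self, tmp_path, monkeypatch):
        from synclust import hits as hits_mod

        monkeypatch.setattr(hits_mod.shutil, "which", lambda _: None)
        with pytest.raises(RuntimeError, match="precomputed"):
            hits_mod.run_external_aligner(tmp_path / "a", tmp_path / "b", tmp_path / "w")
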