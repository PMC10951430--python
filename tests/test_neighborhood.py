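"""Positional classification against the closest protein-coding gene."""

import numpy as np
import pandas as pd
import pytest

from geneatlas.fixtures import FixtureSpec, generate_annotations
from geneatlas.merge import merge_annotations
from geneatlas.neighborhood import (
    classify_gene,
    classify_gene_pair,
    classify_genes,
    classify_transcript_pair,
    mirna_hosts,
    pair_for_coexpression,
)

from conftest import make_gene, make_transcript, random_source


class TestTranscriptPair:
    def test_same_strand_upstream(self):
        focal = make_transcript([(10_000, 11_000)], strand="+")
        pcg = make_transcript([(12_000, 15_000)], strand="+")
        pc = classify_transcript_pair(focal, pcg)
        assert pc.relation == "intergenic"
        assert pc.orientation == "same_strand_up"
        assert pc.distance == 1_000

    def test_divergent_head_to_head(self):
        focal = make_transcript([(10_000, 11_000)], strand="-")
        pcg = make_transcript([(12_000, 15_000)], strand="+")
        assert classify_transcript_pair(focal, pcg).orientation == "divergent"

    def test_convergent_tail_to_tail(self):
        focal = make_transcript([(10_000, 11_000)], strand="+")
        pcg = make_transcript([(12_000, 15_000)], strand="-")
        assert classify_transcript_pair(focal, pcg).orientation == "convergent"

    def test_intronic_containment_sense(self):
        pcg = make_transcript([(12_000, 12_500), (14_000, 15_000)], strand="+")
        focal = make_transcript([(13_000, 13_200)], strand="+")
        pc = classify_transcript_pair(focal, pcg)
        assert pc.relation == "genic_intronic"
        assert pc.direction == "sense"
        assert pc.distance == 0

    def test_exonic_overlap_antisense_is_genic(self):
        pcg = make_transcript([(12_000, 12_500)], strand="+")
        focal = make_transcript([(12_400, 12_800)], strand="-")
        pc = classify_transcript_pair(focal, pcg)
        assert pc.relation == "genic_exonic"
        assert pc.direction == "antisense"

    def test_beyond_window_unclassified(self):
        focal = make_transcript([(1_000, 2_000)])
        pcg = make_transcript([(500_000, 501_000)])
        assert classify_transcript_pair(focal, pcg, window=100_000) is None

    def test_different_chromosome_unclassified(self):
        focal = make_transcript([(1_000, 2_000)], chrom="chr1")
        pcg = make_transcript([(1_000, 2_000)], chrom="chr2")
        assert classify_transcript_pair(focal, pcg) is None


def _pcg(exons, gene_id, strand="+", chrom="chr1"):
    return make_gene(exons, chrom, strand, gene_id)


def _lnc(exons, gene_id, strand="+", chrom="chr1"):
    return make_gene(exons, chrom, strand, gene_id, biotype="lncRNA",
                     biotype_class="lncRNA")


class TestGeneLevel:
    def test_genic_beats_closer_intergenic(self):
        host = _pcg([(12_000, 12_500), (14_000, 15_000)], "A")
        near = _pcg([(13_300, 13_400)], "B")  # hypothetical: 100 bp away
        focal = _lnc([(13_000, 13_200)], "L")
        pc = classify_gene(focal, [host, near])
        # both genic against host (intronic) and intergenic 100 bp from B;
        # precedence picks the genic call
        assert pc.partner_id == "A"
        assert pc.relation == "genic_intronic"

    def test_no_pcg_within_window_unclassified(self):
        focal = _lnc([(1_000, 2_000)], "L")
        far = _pcg([(900_000, 901_000)], "A")
        assert classify_gene(focal, [far], window=100_000) is None

    def test_closest_partner_wins(self):
        focal = _lnc([(100_000, 101_000)], "L")
        near = _pcg([(111_000, 112_000)], "NEAR")
        far = _pcg([(141_000, 142_000)], "FAR")
        pc = classify_gene(focal, [near, far], window=1_000_000)
        assert pc.partner_id == "NEAR"
        assert pc.distance == 10_000

    def test_role_swap_maps_up_to_down(self, rng):
        """Swapping focal/partner roles flips SS.up <-> SS.down and leaves
        divergent/convergent unchanged."""
        flip = {"same_strand_up": "same_strand_down",
                "same_strand_down": "same_strand_up",
                "divergent": "divergent", "convergent": "convergent"}
        n_checked = 0
        for _ in range(300):
            genes = random_source(rng, "R", 2, n_chroms=1).genes
            a, b = genes
            ab = classify_gene_pair(a, b, window=10**9)
            ba = classify_gene_pair(b, a, window=10**9)
            if ab is None or ab.relation != "intergenic":
                continue
            assert ba.orientation == flip[ab.orientation]
            assert ba.distance == ab.distance
            n_checked += 1
        assert n_checked > 30

    def test_genic_distance_zero_intergenic_positive(self, rng):
        for _ in range(200):
            a, b = random_source(rng, "R", 2, n_chroms=1).genes
            pc = classify_gene_pair(a, b, window=50_000)
            if pc is None:
                continue
            if pc.relation == "intergenic":
                assert 0 < pc.distance <= 50_000
            else:
                assert pc.distance == 0

    def test_matches_exhaustive_oracle(self, rng):
        pcgs, lncs = [], []
        for trial in range(3):
            src = random_source(rng, f"T{trial}", 150, n_chroms=2,
                                region=400_000)
            pcgs = [g for g in src.genes if g.biotype_class == "pcg"]
            lncs = [g for g in src.genes if g.biotype_class == "lncRNA"]
            table = classify_genes(lncs, pcgs, window=100_000)
            for _, row in table.iterrows():
                focal = next(g for g in lncs if g.gene_id == row["focal_id"])
                # oracle: evaluate every candidate, sort by the stated rule
                best = None
                for partner in pcgs:
                    pc = classify_gene_pair(focal, partner, window=100_000)
                    if pc and (best is None or pc.sort_key() < best.sort_key()):
                        best = pc
                if best is None:
                    assert row["relation"] == "unclassified"
                else:
                    assert row["partner_id"] == best.partner_id
                    assert row["relation"] == best.relation


class TestMirnaHosts:
    def _atlas(self):
        spec = FixtureSpec(seed=13, n_sources=2, pcg_per_source=30,
                           lnc_per_source=30, n_mirnas=12,
                           overlap_fraction=0.2)
        sources, truth = generate_annotations(spec)
        return merge_annotations(sources), truth

    def test_planted_hosts_recovered_exactly(self):
        atlas, truth = self._atlas()
        hosts = mirna_hosts(atlas).set_index("mirna_id")
        planted = truth.query("role == 'mirna'").set_index("gene_id")
        assert set(hosts.index) == set(planted.index)
        for mirna_id, row in planted.iterrows():
            assert hosts.loc[mirna_id, "host_gene_id"] == row["host_gene_id"]
            assert hosts.loc[mirna_id, "relation"] == row["host_relation"]

    def test_intergenic_mirna_has_no_row(self):
        from geneatlas.merge import MergedAtlas
        mir = make_gene([(500_000, 500_080)], gene_id="MIRX", biotype="miRNA",
                        biotype_class="miRNA")
        pcg = _pcg([(1_000, 2_000)], "A")
        atlas = MergedAtlas(genes=[mir, pcg], order=["S"])
        assert mirna_hosts(atlas).empty

    def test_smallest_enclosing_host_wins(self):
        from geneatlas.merge import MergedAtlas
        big = _pcg([(1_000, 1_200), (9_000, 9_500)], "BIG")
        small = _lnc([(2_000, 4_000)], "SMALL")
        mir = make_gene([(3_000, 3_080)], gene_id="MIR", biotype="miRNA",
                        biotype_class="miRNA")
        atlas = MergedAtlas(genes=[big, small, mir], order=["S"])
        hosts = mirna_hosts(atlas)
        assert list(hosts["host_gene_id"]) == ["SMALL"]
        assert list(hosts["host_class"]) == ["lncRNA"]


class TestCoexpressionPairing:
    def test_closest_of_two_flanking_pcgs(self):
        from geneatlas.merge import MergedAtlas
        focal = _lnc([(100_000, 101_000)], "L")
        near = _pcg([(111_000, 112_000)], "NEAR")
        far = _pcg([(141_000, 142_000)], "FAR")
        atlas = MergedAtlas(genes=[focal, near, far], order=["S"])
        pairs = pair_for_coexpression(atlas, "lncRNA", "pcg")
        assert list(pairs["partner_id"]) == ["NEAR"]
        assert pairs["pair_type"].iloc[0] == "lncRNA:pcg"

    def test_no_partner_within_window_unpaired(self):
        from geneatlas.merge import MergedAtlas
        focal = _lnc([(1_000, 2_000)], "L")
        far = _pcg([(5_000_000, 5_001_000)], "A")
        atlas = MergedAtlas(genes=[focal, far], order=["S"])
        assert pair_for_coexpression(atlas, "lncRNA", "pcg").empty

    def test_matches_all_pairs_oracle(self, rng):
        src = random_source(rng, "C", 200, n_chroms=2, region=500_000)
        from geneatlas.merge import MergedAtlas
        atlas = MergedAtlas(genes=src.genes, order=["C"])
        pairs = pair_for_coexpression(atlas, "lncRNA", "pcg",
                                      window=1_000_000)
        pcgs = [g for g in src.genes if g.biotype_class == "pcg"]
        got = dict(zip(pairs["focal_id"], pairs["partner_id"]))
        for focal in (g for g in src.genes if g.biotype_class == "lncRNA"):
            best = None
            for partner in pcgs:
                pc = classify_gene_pair(focal, partner, window=1_000_000)
                if pc and (best is None or pc.sort_key() < best.sort_key()):
                    best = pc
            if best is None:
                assert focal.gene_id not in got
            else:
                assert got[focal.gene_id] == best.partner_id
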