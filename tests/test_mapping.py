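"""SNP-to-gene mapping: GWS filter, clumping, proximity/eQTL/chromatin,
merge semantics — with brute-force oracles on random instances."""

import numpy as np
import pytest

import drugsea as ds
from drugsea.io import EqtlRecord, GeneModel, LoopRecord
from drugsea.mapping import (
    REGULOME_NUMERIC,
    clump_leads,
    filter_gws,
    implicate_genes,
    map_chromatin,
    map_eqtl,
    map_proximity,
    merge_hits,
)
from conftest import make_snp


class TestFilterGws:
    def test_all_above_alpha_empty(self, snp_factory):
        recs = [snp_factory(f"rs{i}", p=0.1) for i in range(5)]
        assert filter_gws(recs, 5e-8) == []

    def test_boundary_inclusive(self, snp_factory):
        rec = snp_factory("rs1", p=5e-8)
        assert filter_gws([rec], 5e-8) == [rec]

    def test_planted_count_recovered(self, snp_factory):
        rng = np.random.default_rng(3)
        recs = [snp_factory(f"bg{i}", pos=i + 1, p=float(rng.uniform(1e-6, 1)))
                for i in range(988)]
        recs += [snp_factory(f"hit{i}", pos=5_000_000 + i, p=1e-9) for i in range(12)]
        rng.shuffle(recs)
        kept = filter_gws(recs, 5e-8)
        assert len(kept) == 12
        # original order preserved
        assert [r.variant_id for r in kept] == [r.variant_id for r in recs if r.p <= 5e-8]

    def test_bad_alpha(self, snp_factory):
        with pytest.raises(ValueError):
            filter_gws([snp_factory()], 1.0)


class TestClumpLeads:
    def test_greedy_hand_trace(self, snp_factory):
        # p-ascending greedy with 250 kb window: pos 900,000 (p=1e-10) first,
        # then pos 100 (1e-9); pos 150 absorbed by the pos-100 lead.
        recs = [snp_factory("a", pos=100, p=1e-9),
                snp_factory("b", pos=150, p=1e-8),
                snp_factory("c", pos=900_000, p=1e-10)]
        leads = clump_leads(recs, 250_000)
        assert [l.record.variant_id for l in leads] == ["c", "a"]
        assert [l.locus_rank for l in leads] == [1, 2]

    def test_single_snp(self, snp_factory):
        rec = snp_factory()
        leads = clump_leads([rec])
        assert len(leads) == 1 and leads[0].record is rec

    def test_tie_broken_by_chrom_pos(self, snp_factory):
        a = snp_factory("a", chrom="chr2", pos=100, p=1e-9)
        b = snp_factory("b", chrom="chr1", pos=100, p=1e-9)
        leads = clump_leads([a, b], 250_000)
        assert leads[0].record.variant_id == "b"

    def test_invariants_on_random_instances(self, snp_factory):
        rng = np.random.default_rng(11)
        for trial in range(20):
            window = 100_000
            recs = [snp_factory(f"rs{i}", chrom=f"chr{rng.integers(1, 4)}",
                                pos=int(rng.integers(1, 2_000_000)),
                                p=float(rng.uniform(1e-12, 5e-8)))
                    for i in range(40)]
            leads = clump_leads(recs, window)
            assert len(leads) <= len(recs)
            by_chrom = {}
            for l in leads:
                by_chrom.setdefault(l.record.chrom, []).append(l.record.pos0)
            for positions in by_chrom.values():  # pairwise >= window apart
                s = sorted(positions)
                assert all(b - a >= window for a, b in zip(s, s[1:]))
            for r in recs:  # every SNP within window of some lead on its chrom
                assert any(abs(r.pos0 - q) < window or r.pos0 == q
                           for q in by_chrom.get(r.chrom, []))


class TestMapProximity:
    GENE = GeneModel("GENE1", "chr1", 100_000, 105_000, 0.5)

    def test_flank_lower_boundary_inclusive(self, snp_factory):
        # 1-based 90,001 = 0-based 90,000 = start - flank: inside
        hit = map_proximity([snp_factory(pos=90_001)], [self.GENE], 10_000)
        assert [h.gene_id for h in hit] == ["GENE1"]

    def test_just_outside_flank(self, snp_factory):
        assert map_proximity([snp_factory(pos=90_000)], [self.GENE], 10_000) == []

    def test_upper_boundary_exclusive(self, snp_factory):
        # 0-based end+flank = 115,000 is outside; 114,999 inside
        assert map_proximity([snp_factory(pos=115_001)], [self.GENE], 10_000) == []
        assert len(map_proximity([snp_factory(pos=115_000)], [self.GENE], 10_000)) == 1

    def test_negative_flank_rejected(self, snp_factory):
        with pytest.raises(ValueError):
            map_proximity([snp_factory()], [self.GENE], -1)

    def test_agrees_with_all_pairs_scan(self, snp_factory):
        rng = np.random.default_rng(29)
        for trial in range(10):
            genes = [GeneModel(f"G{i}", f"chr{rng.integers(1, 3)}",
                               int(s := rng.integers(0, 3_000_000)),
                               int(s + rng.integers(1_000, 80_000)))
                     for i in range(50)]
            snps = [snp_factory(f"rs{i}", chrom=f"chr{rng.integers(1, 3)}",
                                pos=int(rng.integers(1, 3_100_000)))
                    for i in range(200)]
            flank = 10_000
            got = {(h.gene_id, v) for h in map_proximity(snps, genes, flank)
                   for v in h.snp_ids}
            expected = {(g.gene_id, s.variant_id) for g in genes for s in snps
                        if g.chrom == s.chrom and g.start - flank <= s.pos0 < g.end + flank}
            assert got == expected

    def test_monotone_in_flank(self, snp_factory):
        rng = np.random.default_rng(5)
        genes = [GeneModel(f"G{i}", "chr1", int(s := rng.integers(0, 1_000_000)),
                           int(s + 20_000)) for i in range(30)]
        snps = [snp_factory(f"rs{i}", pos=int(rng.integers(1, 1_050_000)))
                for i in range(100)]
        narrow = {h.gene_id for h in map_proximity(snps, genes, 0)}
        wide = {h.gene_id for h in map_proximity(snps, genes, 10_000)}
        assert narrow <= wide

    def test_agg_matches_direct_recomputation(self, snp_factory):
        snps = [snp_factory("rs1", pos=101_000, beta=0.10, cadd=12.0, regulome="2b"),
                snp_factory("rs2", pos=102_000, beta=-0.25, p=1e-10, cadd=3.0,
                            regulome="1a", exonic=True)]
        (hit,) = map_proximity(snps, [self.GENE], 10_000)
        agg = hit.agg
        assert agg["max_abs_beta"] == pytest.approx(0.25)
        assert agg["mean_abs_beta"] == pytest.approx(0.175)
        assert agg["max_cadd"] == pytest.approx(12.0)
        assert agg["regulome_best"] == pytest.approx(REGULOME_NUMERIC["1a"]) == 7.0
        assert agg["any_exonic"] == 1.0
        assert agg["pli"] == pytest.approx(0.5)
        assert agg["max_z"] >= agg["mean_z"]
        assert hit.lead_variant == "rs2"


class TestMapEqtl:
    def test_link_and_dedup(self, snp_factory):
        gws = [snp_factory("rs1"), snp_factory("rs2", pos=2000)]
        eqtls = [EqtlRecord("rs1", "GENE9", 1e-6), EqtlRecord("rs2", "GENE9", 1e-4),
                 EqtlRecord("rs_absent", "GENE7", 1e-8)]
        hits = map_eqtl(gws, eqtls)
        assert len(hits) == 1
        assert hits[0].gene_id == "GENE9" and hits[0].sources == {"eqtl"}
        assert hits[0].snp_ids == {"rs1", "rs2"}

    def test_no_shared_variants_empty(self, snp_factory):
        assert map_eqtl([snp_factory("rsX")], [EqtlRecord("rsY", "G", 0.1)]) == []


class TestMapChromatin:
    GENES = [GeneModel("GENE3", "chr1", 500_000, 520_000)]

    def test_cross_anchor_contact(self, snp_factory):
        loop = LoopRecord("chr1", 1_000, 5_000, "chr1", 499_000, 501_000)
        hits = map_chromatin([snp_factory(pos=2_001)], [loop], self.GENES, 2_000)
        assert [h.gene_id for h in hits] == ["GENE3"]
        assert hits[0].sources == {"chromatin"}

    def test_same_anchor_only_no_hit(self, snp_factory):
        # SNP and promoter both fall only in anchor A
        loop = LoopRecord("chr1", 498_000, 522_000, "chr2", 0, 1_000)
        assert map_chromatin([snp_factory(pos=510_001)], [loop], self.GENES, 2_000) == []

    def test_agrees_with_all_pairs_scan(self, snp_factory):
        rng = np.random.default_rng(41)
        for trial in range(10):
            genes = [GeneModel(f"G{i}", "chr1", int(s := rng.integers(0, 2_000_000)),
                               int(s + 10_000)) for i in range(40)]
            snps = [snp_factory(f"rs{i}", pos=int(rng.integers(1, 2_000_000)))
                    for i in range(60)]
            loops = [LoopRecord("chr1", int(a := rng.integers(0, 2_000_000)),
                                int(a + 20_000), "chr1",
                                int(b := rng.integers(0, 2_000_000)), int(b + 20_000))
                     for _ in range(30)]
            pf = 2_000
            got = {h.gene_id for h in map_chromatin(snps, loops, genes, pf)}
            expected = set()
            for lp in loops:
                for s in snps:
                    for g in genes:
                        prom = (g.start - pf, g.start + pf)
                        for (sa, se_, ga, ge) in [
                            (lp.startA, lp.endA, lp.startB, lp.endB),
                            (lp.startB, lp.endB, lp.startA, lp.endA),
                        ]:
                            if sa <= s.pos0 < se_ and prom[0] < ge and ga < prom[1]:
                                expected.add(g.gene_id)
            assert got == expected


class TestMergeHits:
    def _hits(self, snp_factory):
        a = map_proximity([snp_factory("rs1", pos=101_000)],
                          [GeneModel("GA", "chr1", 100_000, 105_000)], 0)
        b = map_eqtl([snp_factory("rs2", pos=999)], [EqtlRecord("rs2", "GA", 1e-5)])
        c = map_eqtl([snp_factory("rs3", pos=55)], [EqtlRecord("rs3", "GB", 1e-5)])
        return a, b, c

    def test_union_semantics(self, snp_factory):
        a, b, c = self._hits(snp_factory)
        merged = merge_hits(a, b, c)
        assert [h.gene_id for h in merged] == ["GA", "GB"]
        ga = merged[0]
        assert ga.sources == {"proximity", "eqtl"}
        assert ga.snp_ids == {"rs1", "rs2"}
        # aggregates recomputed over the union
        assert ga.agg["max_abs_beta"] == pytest.approx(
            max(abs(r.beta) for r in ga.snp_records.values()))

    def test_commutative_associative_idempotent(self, snp_factory):
        a, b, c = self._hits(snp_factory)

        def key(hits):
            return [(h.gene_id, tuple(sorted(h.sources)), tuple(sorted(h.snp_ids)))
                    for h in hits]

        assert key(merge_hits(a, b)) == key(merge_hits(b, a))
        assert key(merge_hits(merge_hits(a, b), c)) == key(merge_hits(a, merge_hits(b, c)))
        assert key(merge_hits(a, a)) == key(merge_hits(a))
        assert key(merge_hits(a, [])) == key(merge_hits(a))  # identity


class TestImplicateGenes:
    def test_sources_toggle_monotone(self, small_genome, snp_factory):
        genes = small_genome
        g0 = genes[0]
        snps = [snp_factory("rs1", chrom=g0.chrom, pos=g0.start + 10),
                snp_factory("rs2", chrom=g0.chrom, pos=g0.start + 20, p=0.5)]
        eqtls = [EqtlRecord("rs1", genes[3].gene_id, 1e-6)]
        prox_only = implicate_genes(snps, genes, sources=("proximity",))
        both = implicate_genes(snps, genes, eqtls=eqtls, sources=("proximity", "eqtl"))
        assert {h.gene_id for h in prox_only} <= {h.gene_id for h in both}
        assert genes[3].gene_id in {h.gene_id for h in both}

    def test_lead_aggregation_drops_correlated_snps(self, snp_factory):
        # two GWS SNPs 1 kb apart in one gene: both support membership, but
        # aggregates use the clumped lead only
        gene = GeneModel("GA", "chr1", 100_000, 140_000)
        snps = [snp_factory("lead", pos=110_000, p=1e-12, beta=0.08),
                snp_factory("shadow", pos=111_000, p=1e-9, beta=0.30)]
        (hit,) = implicate_genes(snps, [gene], clump_window=250_000)
        assert hit.snp_ids == {"lead"}
        assert hit.agg["max_abs_beta"] == pytest.approx(0.08)

    def test_unknown_source_rejected(self, small_genome, snp_factory):
        with pytest.raises(ValueError, match="unknown mapping sources"):
            implicate_genes([snp_factory()], small_genome, sources=("magma",))
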