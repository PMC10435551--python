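"""SNP-to-gene linking, weight normalization, gene PIPs, credible gene sets."""

import math

import numpy as np
import pandas as pd
import pytest

from genepip import genemap as gm
from genepip.annotate import PeakRecord
from genepip.io import GeneModel, LinkRecord, VariantRecord


def snp(vid, pos, chrom="chr1", z=0.0, block="b1"):
    return VariantRecord(vid, chrom, pos, z, block)


GENE_A = GeneModel("gA", "chr1", "+", 100_001, exons=((100_000, 100_400),))
GENE_B = GeneModel("gB", "chr1", "+", 130_001, exons=((130_000, 130_400),))


class TestLinking:
    def test_exonic_snp_links_only_its_gene(self):
        entries = gm.link_snp_to_genes(snp("s1", 100_200), [GENE_A, GENE_B])
        assert [(e["gene_id"], e["weight"], e["method"]) for e in entries] == [("gA", 1.0, "Exon")]

    def test_distance_fallback_weights(self):
        # SNP 10 kb from gA's TSS and 50 kb from gB's (adjust positions)
        ga = GeneModel("gA", "chr1", "+", 200_001)
        gb = GeneModel("gB", "chr1", "+", 240_001)
        entries = gm.link_snp_to_genes(snp("s1", 190_001), [ga, gb])
        w = {e["gene_id"]: e["weight"] for e in entries}
        assert w["gA"] == pytest.approx(math.exp(-0.2), abs=1e-9)
        assert w["gB"] == pytest.approx(math.exp(-1.0), abs=1e-9)
        assert all(e["method"] == "Distance" for e in entries)

    def test_ocr_near_active_promoter_links(self):
        # promoter of gC overlaps an OCR (active); SNP sits in an OCR 15 kb away
        gc = GeneModel("gC", "chr1", "+", 500_001)
        peaks = [
            PeakRecord("prom", "chr1", 499_900, 500_100),
            PeakRecord("enh", "chr1", 484_900, 485_100),
        ]
        entries = gm.link_snp_to_genes(snp("s1", 485_000), [gc], ocr_peaks=peaks)
        assert [(e["gene_id"], e["method"]) for e in entries] == [("gC", "NearbyOCR")]

    def test_ocr_beyond_20kb_does_not_link(self):
        gc = GeneModel("gC", "chr1", "+", 500_001)
        peaks = [
            PeakRecord("prom", "chr1", 499_900, 500_100),
            PeakRecord("enh", "chr1", 449_900, 450_100),  # ~48 kb away
        ]
        entries = gm.link_snp_to_genes(snp("s1", 450_000), [gc], ocr_peaks=peaks)
        assert all(e["method"] == "Distance" for e in entries)

    def test_abc_loop_links_with_weight_one(self):
        link = LinkRecord("chr1", 49_900, 50_100, "gA", "ABC", 0.5)
        entries = gm.link_snp_to_genes(snp("s1", 50_000), [GENE_A, GENE_B], links=[link])
        assert [(e["gene_id"], e["weight"], e["method"]) for e in entries] == [("gA", 1.0, "ABC")]

    def test_abc_below_threshold_ignored(self):
        link = LinkRecord("chr1", 49_900, 50_100, "gA", "ABC", 0.01)
        entries = gm.link_snp_to_genes(snp("s1", 50_000), [GENE_A, GENE_B], links=[link])
        assert all(e["method"] == "Distance" for e in entries)

    def test_utr_rule_applies_only_outside_ocrs(self):
        g = GeneModel("gU", "chr1", "+", 700_001, exons=((700_000, 710_000),),
                      utrs=((709_000, 710_000),))
        entries = gm.link_snp_to_genes(snp("s1", 709_500), [g])
        # also exonic here; exon stage already links it
        assert entries[0]["method"] == "Exon"
        g2 = GeneModel("gU2", "chr1", "+", 800_001, utrs=((809_000, 810_000),))
        entries = gm.link_snp_to_genes(snp("s2", 809_500), [g2])
        assert [(e["gene_id"], e["method"]) for e in entries] == [("gU2", "UTR")]
        peaks = [PeakRecord("p", "chr1", 809_400, 809_600)]
        entries = gm.link_snp_to_genes(snp("s3", 809_500), [g2], ocr_peaks=peaks)
        assert all(e["method"] != "UTR" for e in entries)

    def test_accumulate_mode_links_exon_and_loop(self):
        link = LinkRecord("chr1", 100_100, 100_300, "gB", "ABC", 0.5)
        entries = gm.link_snp_to_genes(snp("s1", 100_200), [GENE_A, GENE_B], links=[link])
        methods = {e["gene_id"]: e["method"] for e in entries}
        assert methods == {"gA": "Exon", "gB": "ABC"}

    def test_first_hit_mode_stops_at_first_stage(self):
        link = LinkRecord("chr1", 100_100, 100_300, "gB", "ABC", 0.5)
        cfg = gm.GeneMapConfig(link_mode="first-hit")
        entries = gm.link_snp_to_genes(snp("s1", 100_200), [GENE_A, GENE_B], links=[link], cfg=cfg)
        assert [e["gene_id"] for e in entries] == ["gA"]

    def test_no_gene_within_window_yields_nothing(self):
        far = GeneModel("gF", "chr1", "+", 5_000_001)
        assert gm.link_snp_to_genes(snp("s1", 1_000), [far]) == []


class TestNormalization:
    def test_hand_example(self):
        w = pd.DataFrame(
            {"variant_id": ["s", "s"], "gene_id": ["gA", "gB"],
             "weight": [math.exp(-0.2), math.exp(-1.0)], "method": "Distance", "distance": [1e4, 5e4]}
        )
        out = gm.normalize_weights(w)
        np.testing.assert_allclose(out["norm_weight"], [0.6900, 0.3100], atol=5e-5)

    def test_single_link_is_one_and_pair_splits(self):
        w = pd.DataFrame(
            {"variant_id": ["a", "b", "b"], "gene_id": ["g1", "g1", "g2"],
             "weight": [0.37, 1.0, 1.0], "method": "Distance", "distance": np.nan}
        )
        out = gm.normalize_weights(w)
        assert out[out.variant_id == "a"]["norm_weight"].iloc[0] == 1.0
        np.testing.assert_allclose(out[out.variant_id == "b"]["norm_weight"], 0.5)

    def test_per_snp_weights_sum_to_one(self, rng):
        rows = []
        for i in range(30):
            for g in range(rng.integers(1, 5)):
                rows.append({"variant_id": f"s{i}", "gene_id": f"g{g}",
                             "weight": float(rng.uniform(0.01, 1.0)),
                             "method": "Distance", "distance": np.nan})
        out = gm.normalize_weights(pd.DataFrame(rows))
        sums = out.groupby("variant_id")["norm_weight"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_doubling_decay_scale_never_hurts_far_gene(self):
        for d_near, d_far in [(1e4, 5e4), (2e4, 9e5), (100.0, 3e5)]:
            def norm_far(scale):
                wn, wf = math.exp(-d_near / scale), math.exp(-d_far / scale)
                return wf / (wn + wf)
            assert norm_far(1e5) >= norm_far(5e4) - 1e-15


def worked_example():
    """Two-SNP locus: s1 exonic to g1 (PIP .6), s2 looped to g1 and g2 (PIP .4)."""
    g1 = GeneModel("g1", "chr1", "+", 10_001, exons=((10_000, 10_400),))
    g2 = GeneModel("g2", "chr1", "+", 60_001, exons=((60_000, 60_400),))
    links = [
        LinkRecord("chr1", 29_900, 30_100, "g1", "ABC", 0.5),
        LinkRecord("chr1", 29_900, 30_100, "g2", "ABC", 0.5),
    ]
    variants = [snp("s1", 10_200, z=4.0), snp("s2", 30_000, z=3.0)]
    linker = gm.SnpGeneLinker([g1, g2], links=links)
    weights = gm.normalize_weights(linker.link_all(variants))
    pips = pd.DataFrame(
        {"variant_id": ["s1", "s2"], "block_id": "b1", "pip": [0.6, 0.4]}
    )
    return pips, weights


class TestGenePips:
    def test_worked_example(self):
        pips, weights = worked_example()
        gene, support, locus = gm.compute_gene_pips(pips, weights)
        got = dict(zip(gene.gene_id, gene.gene_pip))
        assert got["g1"] == pytest.approx(0.8, abs=1e-12)
        assert got["g2"] == pytest.approx(0.2, abs=1e-12)

    def test_exclusive_exonic_snp_attains_upper_bound(self):
        g1 = GeneModel("g1", "chr1", "+", 10_001, exons=((10_000, 10_400),))
        linker = gm.SnpGeneLinker([g1])
        weights = gm.normalize_weights(linker.link_all([snp("s1", 10_100)]))
        pips = pd.DataFrame({"variant_id": ["s1"], "block_id": "b1", "pip": [1.0]})
        gene, _, _ = gm.compute_gene_pips(pips, weights)
        assert gene.gene_pip.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_multi_block_gene_sums_and_flags(self):
        weights = pd.DataFrame(
            {"variant_id": ["a", "b"], "gene_id": ["g", "g"], "weight": [1.0, 1.0],
             "method": "Exon", "distance": np.nan}
        )
        pips = pd.DataFrame(
            {"variant_id": ["a", "b"], "block_id": ["b1", "b2"], "pip": [0.7, 0.6]}
        )
        gene, _, _ = gm.compute_gene_pips(pips, gm.normalize_weights(weights))
        assert gene.gene_pip.iloc[0] == pytest.approx(1.3, abs=1e-12)
        assert bool(gene.multi_block.iloc[0])

    def test_conservation_of_pip_mass(self, rng):
        rows, pips = [], []
        for i in range(40):
            pips.append({"variant_id": f"s{i}", "block_id": f"b{i % 4}",
                         "pip": float(rng.uniform(0, 0.2))})
            for g in rng.choice(6, size=rng.integers(1, 4), replace=False):
                rows.append({"variant_id": f"s{i}", "gene_id": f"g{g}",
                             "weight": float(rng.uniform(0.1, 1.0)),
                             "method": "Distance", "distance": np.nan})
        gene, _, locus = gm.compute_gene_pips(
            pd.DataFrame(pips), gm.normalize_weights(pd.DataFrame(rows))
        )
        assert gene.gene_pip.sum() == pytest.approx(pd.DataFrame(pips).pip.sum(), abs=1e-10)


class TestCredibleGeneSets:
    def test_worked_example_set(self):
        pips, weights = worked_example()
        _, _, locus = gm.compute_gene_pips(pips, weights)
        cgs = gm.credible_gene_set(locus, coverage=0.8)
        assert cgs.gene_id.tolist() == ["g1"]

    def test_even_split_takes_both(self):
        locus = pd.DataFrame(
            {"block_id": ["L", "L"], "gene_id": ["gA", "gB"], "contribution": [0.5, 0.5]}
        )
        assert gm.credible_gene_set(locus, coverage=0.8).gene_id.tolist() == ["gA", "gB"]

    def test_ties_broken_by_gene_id(self):
        locus = pd.DataFrame(
            {"block_id": ["L"] * 3, "gene_id": ["gC", "gA", "gB"],
             "contribution": [0.4, 0.4, 0.2]}
        )
        cgs = gm.credible_gene_set(locus, coverage=0.8)
        assert cgs.gene_id.tolist() == ["gA", "gC"]

    def test_multi_block_gene_counts_only_local_share(self):
        locus = pd.DataFrame(
            {"block_id": ["L1", "L1", "L2"], "gene_id": ["gX", "gY", "gX"],
             "contribution": [0.3, 0.6, 0.9]}
        )
        cgs = gm.credible_gene_set(locus, coverage=0.8)
        l1 = cgs[cgs.block_id == "L1"]
        assert l1.gene_id.tolist() == ["gY", "gX"]  # gX's other-locus 0.9 not counted here
        assert l1.contribution.tolist() == [0.6, 0.3]

    def test_empty_locus_flagged(self, caplog):
        import logging
        locus = pd.DataFrame({"block_id": ["L"], "gene_id": ["g"], "contribution": [0.0]})
        with caplog.at_level(logging.WARNING, logger="genepip"):
            out = gm.credible_gene_set(locus)
        assert out.empty and "no gene-mapped PIP" in caplog.text


class TestScalars:
    def test_weight_mass_within_100kb(self):
        assert gm.weight_mass_within(5e4, 1e5) == pytest.approx(1 - math.exp(-2), abs=1e-15)

    def test_weight_mass_limits(self):
        assert gm.weight_mass_within(5e4, 1e12) == pytest.approx(1.0, abs=1e-9)
        assert gm.weight_mass_within(5e4, 5e4) == pytest.approx(1 - math.exp(-1), abs=1e-15)

    def test_precision(self):
        assert gm.evaluate_precision({"a", "b", "c", "d"}, {"a", "b", "c"}) == 0.75
        assert gm.evaluate_precision({"a"}, {"a", "b"}) == 1.0
        with pytest.raises(ValueError):
            gm.evaluate_precision(set(), {"a"})

    def test_nearest_gene_by_tss(self):
        g5 = GeneModel("g5kb", "chr1", "+", 105_001)
        g7 = GeneModel("g7kb", "chr1", "+", 93_001)
        out = gm.nearest_gene_baseline({"L": ("chr1", 100_001)}, [g5, g7])
        assert out["L"] == "g5kb"

    def test_nearest_gene_tie_by_id(self):
        ga = GeneModel("ga", "chr1", "+", 95_001)
        gb = GeneModel("gb", "chr1", "+", 105_001)
        out = gm.nearest_gene_baseline({"L": ("chr1", 100_001)}, [gb, ga])
        assert out["L"] == "ga"
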