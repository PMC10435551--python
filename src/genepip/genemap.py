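"""Gene-level aggregation of fine-mapping PIPs.

A SNP is linked to nearby genes through a staged weighting scheme:

1. exon or active promoter (promoter window overlapping an OCR): weight 1;
2. enhancer loops — ABC links (score >= 0.015), promoter-capture Hi-C, or an
   OCR within 20 kb of an active promoter: weight 1;
3. UTR (outside OCRs): weight 1;
4. only if none of the above links the SNP to any gene, exponential distance
   decay ``w = exp(-d / 5e4)`` to every gene with TSS within 1 Mb, where d is
   the SNP-to-TSS distance.

Weights are normalized per SNP to sum to 1 and the gene PIP is the weighted
sum of SNP PIPs, interpretable as the probability the gene is the causal gene
of its locus (or, for genes spanning several LD blocks, the expected number
of causal variants targeting the gene).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, LinkRecord, VariantRecord
from .annotate import PeakRecord

logger = logging.getLogger("genepip")

METHOD_ORDER = ["Exon", "ActivePromoter", "ABC", "PCHiC", "NearbyOCR", "UTR", "Distance"]


@dataclass
class GeneMapConfig:
    promoter_upstream: int = 2000  # bp upstream of TSS (strand-aware)
    promoter_downstream: int = 500
    abc_min_score: float = 0.015
    proximal_ocr_dist: int = 20_000
    decay_scale: float = 5e4
    distance_window: float = 1e6
    link_mode: str = "accumulate"  # or "first-hit"
    report_threshold: float = 0.1


def promoter_interval(gene: GeneModel, cfg: GeneMapConfig) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, 0-based half-open."""
    t = gene.tss - 1
    if gene.strand == "+":
        return (max(t - cfg.promoter_upstream, 0), t + cfg.promoter_downstream + 1)
    return (max(t - cfg.promoter_downstream, 0), t + cfg.promoter_upstream + 1)


class SnpGeneLinker:
    """Pre-indexed SNP-to-gene linking over a fixed gene/peak/link landscape."""

    def __init__(
        self,
        gene_models: list[GeneModel],
        ocr_peaks: list[PeakRecord] | None = None,
        links: list[LinkRecord] | None = None,
        cfg: GeneMapConfig | None = None,
    ):
        self.cfg = cfg or GeneMapConfig()
        self.genes = {g.gene_id: g for g in gene_models}
        peaks = ocr_peaks or []
        links = links or []

        self._exon = self._gene_interval_trees([(g, iv) for g in gene_models for iv in g.exons])
        self._utr = self._gene_interval_trees([(g, iv) for g in gene_models for iv in g.utrs])

        self._ocr: dict[str, IntervalTree] = {}
        for p in peaks:
            self._ocr.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.peak_id)

        # promoters active iff the window intersects any OCR
        self._promoter: dict[str, IntervalTree] = {}
        self.active_promoters: dict[str, tuple[int, int]] = {}
        for g in gene_models:
            s, e = promoter_interval(g, self.cfg)
            tree = self._ocr.get(g.chrom)
            if tree is not None and tree.overlap(s, e):
                self.active_promoters[g.gene_id] = (s, e)
                self._promoter.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)

        self._links: dict[str, IntervalTree] = {}
        for l in links:
            if l.link_type == "ABC" and (l.score is None or l.score < self.cfg.abc_min_score):
                continue
            self._links.setdefault(l.chrom, IntervalTree()).addi(l.start, l.end, l)

        # per-chromosome TSS arrays for the distance fallback
        self._tss: dict[str, tuple[np.ndarray, list[str]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in gene_models:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gl in by_chrom.items():
            gl = sorted(gl, key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = (np.array([g.tss for g in gl]), [g.gene_id for g in gl])

    @staticmethod
    def _gene_interval_trees(pairs) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for g, (s, e) in pairs:
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
        return trees

    def _point_hits(self, trees: dict[str, IntervalTree], chrom: str, pos: int):
        tree = trees.get(chrom)
        return tree.at(pos - 1) if tree is not None else set()

    def link(self, variant: VariantRecord) -> list[dict]:
        """Raw weight entries for one SNP: gene_id, weight, method, distance."""
        cfg = self.cfg
        chrom, pos = variant.chrom, variant.pos
        entries: dict[str, dict] = {}

        def add(gene_id: str, method: str):
            if gene_id not in entries:
                entries[gene_id] = {
                    "variant_id": variant.variant_id, "gene_id": gene_id,
                    "weight": 1.0, "method": method, "distance": np.nan,
                }

        staged: list[list[tuple[str, str]]] = [[], [], []]
        for iv in self._point_hits(self._exon, chrom, pos):
            staged[0].append((iv.data, "Exon"))
        for iv in self._point_hits(self._promoter, chrom, pos):
            staged[0].append((iv.data, "ActivePromoter"))
        for iv in self._point_hits(self._links, chrom, pos):
            l: LinkRecord = iv.data
            if l.gene_id in self.genes:
                staged[1].append((l.gene_id, "ABC" if l.link_type == "ABC" else "PCHiC"))
        in_ocr = bool(self._point_hits(self._ocr, chrom, pos))
        if in_ocr:
            for gene_id, (s, e) in self.active_promoters.items():
                g = self.genes[gene_id]
                if g.chrom != chrom:
                    continue
                for iv in self._ocr[chrom].at(pos - 1):
                    gap = max(s - iv.end, iv.begin - e, 0)
                    if gap <= cfg.proximal_ocr_dist:
                        staged[1].append((gene_id, "NearbyOCR"))
                        break
        if not in_ocr:
            for iv in self._point_hits(self._utr, chrom, pos):
                staged[2].append((iv.data, "UTR"))

        for stage in staged:
            for gene_id, method in stage:
                add(gene_id, method)
            if entries and cfg.link_mode == "first-hit":
                break

        if not entries:
            tss, gene_ids = self._tss.get(chrom, (np.array([]), []))
            for t, gid in zip(tss, gene_ids):
                d = abs(pos - int(t))
                if d <= cfg.distance_window:
                    entries[gid] = {
                        "variant_id": variant.variant_id, "gene_id": gid,
                        "weight": math.exp(-d / cfg.decay_scale),
                        "method": "Distance", "distance": float(d),
                    }
            if not entries:
                logger.info("SNP %s links to no gene within %d bp", variant.variant_id, int(cfg.distance_window))
        return list(entries.values())

    def link_all(self, variants: list[VariantRecord]) -> pd.DataFrame:
        rows = [e for v in variants for e in self.link(v)]
        cols = ["variant_id", "gene_id", "weight", "method", "distance"]
        return pd.DataFrame(rows, columns=cols)


def link_snp_to_genes(
    variant: VariantRecord,
    gene_models: list[GeneModel],
    ocr_peaks: list[PeakRecord] | None = None,
    links: list[LinkRecord] | None = None,
    cfg: GeneMapConfig | None = None,
) -> list[dict]:
    """One-off SNP-to-gene linking (builds the index; use SnpGeneLinker in loops)."""
    return SnpGeneLinker(gene_models, ocr_peaks, links, cfg).link(variant)


def normalize_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Add per-SNP normalized weights (summing to 1 over linked genes)."""
    out = weights.copy()
    totals = out.groupby("variant_id")["weight"].transform("sum")
    zero = totals <= 0
    if zero.any():
        dropped = out.loc[zero, "variant_id"].unique().tolist()
        logger.warning("dropping %d SNP(s) with zero link weight: %s", len(dropped), dropped[:5])
        out = out[~zero]
        totals = totals[~zero]
    out["norm_weight"] = out["weight"] / totals
    return out


def compute_gene_pips(
    finemap_results: pd.DataFrame,
    weights: pd.DataFrame,
    report_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene PIPs as normalized-weight-weighted sums of SNP PIPs.

    Parameters
    ----------
    finemap_results
        Per-SNP table with columns ``variant_id``, ``block_id``, ``pip``
        (PIPs normalized within each block).
    weights
        Normalized weight table from :func:`normalize_weights`.
    report_threshold
        Fractional-PIP floor for the support listing (the full support table
        is returned regardless; the filtered listing mirrors reporting
        conventions for top genes).

    Returns
    -------
    (gene table, support table, per-locus contribution table).
    """
    if "norm_weight" not in weights.columns:
        weights = normalize_weights(weights)
    merged = weights.merge(
        finemap_results[["variant_id", "block_id", "pip"]], on="variant_id", how="inner"
    )
    merged["fractional_pip"] = merged["pip"] * merged["norm_weight"]

    locus = (
        merged.groupby(["block_id", "gene_id"], as_index=False)["fractional_pip"]
        .sum()
        .rename(columns={"fractional_pip": "contribution"})
    )
    gene = (
        locus.groupby("gene_id")
        .agg(gene_pip=("contribution", "sum"), n_blocks=("block_id", "nunique"))
        .reset_index()
        .sort_values("gene_pip", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    gene["multi_block"] = gene["n_blocks"] > 1

    support = merged[
        ["gene_id", "variant_id", "block_id", "pip", "norm_weight", "fractional_pip", "method"]
    ].sort_values(["gene_id", "fractional_pip"], ascending=[True, False], kind="stable")
    support["reported"] = support["fractional_pip"] >= report_threshold
    return gene, support.reset_index(drop=True), locus


def credible_gene_set(locus_contributions: pd.DataFrame, coverage: float = 0.8) -> pd.DataFrame:
    """Per-locus minimal gene set capturing ``coverage`` of the mapped PIP.

    Genes are ranked by their within-locus contribution (ties by gene id);
    a gene spanning several loci enters each locus's set only with its
    contribution from that locus.
    """
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    rows = []
    for block_id, grp in locus_contributions.groupby("block_id", sort=False):
        grp = grp.sort_values(["contribution", "gene_id"], ascending=[False, True], kind="stable")
        total = grp["contribution"].sum()
        if total <= 0:
            logger.warning("locus %s has no gene-mapped PIP; empty credible gene set", block_id)
            continue
        target = coverage * total
        csum = 0.0
        for rank, (_, r) in enumerate(grp.iterrows(), start=1):
            csum += r["contribution"]
            rows.append(
                {
                    "block_id": block_id, "rank": rank, "gene_id": r["gene_id"],
                    "contribution": r["contribution"], "cumulative": csum,
                }
            )
            if csum >= target - 1e-12:
                break
    return pd.DataFrame(rows, columns=["block_id", "rank", "gene_id", "contribution", "cumulative"])


def weight_mass_within(decay_scale: float, cutoff: float) -> float:
    """Fraction of exponential-decay link weight lying within ``cutoff`` bp.

    Area under ``exp(-d / decay_scale)`` from 0 to cutoff over its total:
    ``1 - exp(-cutoff / decay_scale)``.
    """
    if decay_scale <= 0 or cutoff <= 0:
        raise ValueError("decay_scale and cutoff must be > 0")
    return 1.0 - math.exp(-cutoff / decay_scale)


def evaluate_precision(nominated: set[str], plausible: set[str]) -> float:
    """Fraction of nominated genes that are plausible."""
    if not nominated:
        raise ValueError("nominated gene set is empty")
    return len(set(nominated) & set(plausible)) / len(set(nominated))


def nearest_gene_baseline(
    top_snps: dict[str, tuple[str, int]],
    gene_models: list[GeneModel],
) -> dict[str, str]:
    """Nearest gene (by TSS distance, ties by gene id) to each locus's top SNP.

    ``top_snps`` maps locus id to (chrom, 1-based position).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for locus, (chrom, pos) in top_snps.items():
        genes = by_chrom.get(chrom, [])
        if not genes:
            continue
        out[locus] = min(genes, key=lambda g: (abs(g.tss - pos), g.gene_id)).gene_id
    return out
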