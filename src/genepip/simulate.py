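"""Synthetic data generators with ground truth for every pipeline input.

The GWAS generator follows the standard summary-statistics likelihood: for a
block with LD matrix R and a single causal variant at index c with effect
``lambda`` on the z scale (standing in for sqrt(n) * beta of the generative
model y = sum_j x_j beta_j + eps), the z-score vector is drawn

    z ~ MVN(lambda * R[:, c],  R)

with exactly one causal variant per block, placed within the block with
probability proportional to exp(alpha . A_j) — the same logistic enrichment
model the estimation side assumes.  LD is AR1: R_jk = rho^|j-k|.

Defaults are the study conditions used throughout the test-suite: 1000
blocks of 100 SNPs, causal effect lambda = 5, one 10% annotation with true
log-odds ln 8 (log2 fold enrichment 3), AR1 rho = 0.5.

All generators require an explicit seed or Generator; there is no default
entropy source (``numpy.random.default_rng`` streams, stable across
platforms).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from . import io as gio
from .annotate import AnnotationMatrix, PeakRecord
from .io import GeneModel, LDBlock, LinkRecord, VariantRecord

logger = logging.getLogger("genepip")


@dataclass
class SimConfig:
    """Generator settings; the defaults are the simulation study conditions."""

    seed: int
    n_blocks: int = 1000
    snps_per_block: int = 100
    ar1_rho: float = 0.5
    lam: float = 5.0  # causal effect on the z scale (sqrt(n) * beta)
    annotation_fracs: dict[str, float] = field(default_factory=lambda: {"ocr": 0.1})
    annotation_logodds: dict[str, float] = field(default_factory=lambda: {"ocr": math.log(8.0)})
    snp_spacing: int = 1000
    # gene landscape
    n_loci: int = 100
    genes_per_locus: int = 4
    locus_span: int = 1_000_000
    snps_per_locus: int = 50
    landscape_lam: float = 6.0
    exon_causal_prob: float = 0.3  # causal SNP in an exon; else distal OCR + loop
    # eQTL mixture
    cell_fractions: tuple[float, ...] = (0.35, 0.25, 0.20, 0.12, 0.08)
    n_individuals: int = 500

    def __post_init__(self):
        if not (0 <= self.ar1_rho < 1):
            raise ValueError(f"ar1_rho must be in [0, 1), got {self.ar1_rho}")
        if abs(sum(self.cell_fractions) - 1.0) > 1e-9:
            raise ValueError("cell_fractions must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _as_rng(rng: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# LD and z-scores
# ---------------------------------------------------------------------------

def simulate_ld(m: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix R_jk = rho^|j-k| (symmetric positive definite)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= rho < 1):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    return toeplitz(rho ** np.arange(m))


def simulate_block(
    R: np.ndarray, causal_index: int, lam: float, rng: np.random.Generator | int
) -> np.ndarray:
    """One block's z-vector: MVN(lam * R[:, causal], R)."""
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    if not (0 <= causal_index < m):
        raise ValueError(f"causal_index {causal_index} out of range for {m} SNPs")
    rng = _as_rng(rng)
    L = np.linalg.cholesky(R)
    return lam * R[:, causal_index] + L @ rng.standard_normal(m)


def simulate_blocks(
    R: np.ndarray,
    causal_indices: np.ndarray,
    lam: float | np.ndarray,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Vectorized z-score draws for many blocks sharing one LD matrix."""
    R = np.asarray(R, dtype=float)
    rng = _as_rng(rng)
    idx = np.asarray(causal_indices, dtype=int)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), idx.shape)
    means = lam[:, None] * R[:, idx].T
    L = np.linalg.cholesky(R)
    return means + rng.standard_normal((idx.shape[0], R.shape[0])) @ L.T


# ---------------------------------------------------------------------------
# annotated GWAS genome
# ---------------------------------------------------------------------------

@dataclass
class SimGenome:
    variants: pd.DataFrame  # variant_id, chrom, pos, z, block_id
    blocks: list[LDBlock]
    annotations: AnnotationMatrix
    truth: pd.DataFrame  # block_id, causal_index, causal_variant_id
    R: np.ndarray
    config: SimConfig


def simulate_annotated_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """GWAS blocks with annotation-enriched causal placement.

    The causal SNP of block b is drawn with probability proportional to
    ``exp(sum_k alpha_k A_jk)`` over the block's SNPs; z-scores then follow
    the summary-statistics likelihood above.
    """
    rng = cfg.rng() if rng is None else rng
    B, m = cfg.n_blocks, cfg.snps_per_block
    names = list(cfg.annotation_fracs)
    A = np.column_stack(
        [rng.random(B * m) < cfg.annotation_fracs[k] for k in names]
    ).astype(int) if names else np.zeros((B * m, 0), dtype=int)
    alpha = np.array([cfg.annotation_logodds.get(k, 0.0) for k in names])

    logits = (A @ alpha).reshape(B, m)
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    u = rng.random(B)
    causal = (u[:, None] > cum).sum(axis=1)

    R = simulate_ld(m, cfg.ar1_rho)
    Z = simulate_blocks(R, causal, cfg.lam, rng)

    block_span = m * cfg.snp_spacing
    block_ids = [f"block{b:05d}" for b in range(B)]
    variant_ids = np.array([f"rs{b * m + j}" for b in range(B) for j in range(m)])
    pos = np.array(
        [b * block_span + j * cfg.snp_spacing + cfg.snp_spacing // 2 for b in range(B) for j in range(m)]
    )
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": "chr1",
            "pos": pos,
            "z": Z.ravel(),
            "block_id": np.repeat(block_ids, m),
        }
    )
    blocks = [
        LDBlock(
            block_id=block_ids[b], chrom="chr1",
            start=b * block_span, end=(b + 1) * block_span,
            variant_ids=list(variant_ids[b * m:(b + 1) * m]), R=R,
        )
        for b in range(B)
    ]
    ann = AnnotationMatrix(
        pd.DataFrame(A, index=variant_ids, columns=names), disjoint=False
    )
    truth = pd.DataFrame(
        {
            "block_id": block_ids,
            "causal_index": causal,
            "causal_variant_id": [variant_ids[b * m + c] for b, c in enumerate(causal)],
        }
    )
    return SimGenome(variants=variants, blocks=blocks, annotations=ann, truth=truth, R=R, config=cfg)


# ---------------------------------------------------------------------------
# gene landscape
# ---------------------------------------------------------------------------

@dataclass
class SimLandscape:
    variants: pd.DataFrame
    blocks: list[LDBlock]
    gene_models: list[GeneModel]
    peaks: list[PeakRecord]
    links: list[LinkRecord]
    truth: pd.DataFrame  # block_id, causal_gene, causal_variant_id, mechanism
    R: np.ndarray
    config: SimConfig


def _make_gene(gene_id: str, chrom: str, tss: int, strand: str) -> GeneModel:
    t = tss - 1  # 0-based
    if strand == "+":
        exons = ((t, t + 400), (t + 5000, t + 5400), (t + 9600, t + 10000))
        utrs = ((t + 9600, t + 10000),)
    else:
        exons = ((t - 10000, t - 9600), (t - 5400, t - 5000), (t - 400, t + 1))
        utrs = ((t - 10000, t - 9600),)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, exons=exons, utrs=utrs)


def simulate_gene_landscape(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimLandscape:
    """Loci with genes, OCR peaks, enhancer loops and a designated causal gene.

    Each locus carries one causal SNP.  With probability
    ``exon_causal_prob`` it sits in an exon of the causal gene; otherwise it
    sits in a distal OCR (50-250 kb from the causal gene's TSS, so the
    nearest gene is frequently a decoy) connected to the causal gene's
    promoter by an ABC loop.  The causal gene's promoter always overlaps an
    OCR (it is "active").  z-scores follow the block generator at
    ``landscape_lam``.
    """
    rng = cfg.rng() if rng is None else rng
    chrom = "chr1"
    genes: list[GeneModel] = []
    peaks: list[PeakRecord] = []
    links: list[LinkRecord] = []
    blocks: list[LDBlock] = []
    truth_rows = []
    all_variants = []

    R = simulate_ld(cfg.snps_per_locus, cfg.ar1_rho)
    causal_sites = rng.integers(0, cfg.snps_per_locus, size=cfg.n_loci)
    Z = simulate_blocks(R, causal_sites, cfg.landscape_lam, rng)

    for l in range(cfg.n_loci):
        off = l * cfg.locus_span
        block_id = f"locus{l:04d}"
        tss = np.sort(rng.uniform(0.15, 0.85, cfg.genes_per_locus)) * cfg.locus_span
        tss = (off + tss).astype(int)
        locus_genes = [
            _make_gene(f"g{l:04d}_{i}", chrom, int(t) + 1, rng.choice(["+", "-"]))
            for i, t in enumerate(tss)
        ]
        genes.extend(locus_genes)
        causal_gene = locus_genes[int(rng.integers(cfg.genes_per_locus))]

        while True:  # unique positions so the causal SNP stays identifiable
            pos = np.sort(rng.integers(off + 1, off + cfg.locus_span, cfg.snps_per_locus))
            if np.unique(pos).size == pos.size:
                break
        ci = int(causal_sites[l])
        mech = "exon" if rng.random() < cfg.exon_causal_prob else "loop"
        if mech == "exon":
            ex = causal_gene.exons[int(rng.integers(len(causal_gene.exons)))]
            pos[ci] = int(rng.integers(ex[0] + 1, ex[1] + 1))  # 1-based inside exon
        else:
            d = int(rng.uniform(5e4, 2.5e5)) * (1 if rng.random() < 0.5 else -1)
            p = int(np.clip(causal_gene.tss + d, off + 1, off + cfg.locus_span - 1))
            pos[ci] = p
            ocr = PeakRecord(
                peak_id=f"peak_{block_id}_enh", chrom=chrom, start=p - 1 - 250, end=p - 1 + 250
            )
            peaks.append(ocr)
            links.append(
                LinkRecord(
                    chrom=chrom, start=ocr.start, end=ocr.end,
                    gene_id=causal_gene.gene_id, link_type="ABC",
                    score=float(rng.uniform(0.02, 1.0)),
                )
            )
        # promoter OCR keeps the causal gene's promoter active
        t0 = causal_gene.tss - 1
        peaks.append(
            PeakRecord(peak_id=f"peak_{block_id}_prom", chrom=chrom, start=max(t0 - 200, 0), end=t0 + 200)
        )

        # z-scores are indexed by the pre-sort SNP order: variant j keeps z[l, j],
        # so the causal z stays attached to the (possibly moved) causal position
        vids = [f"s{l:04d}_{j}" for j in range(cfg.snps_per_locus)]
        df = pd.DataFrame(
            {"variant_id": vids, "chrom": chrom, "pos": pos, "z": Z[l], "block_id": block_id}
        ).sort_values("pos", kind="stable")
        all_variants.append(df)
        blocks.append(
            LDBlock(block_id=block_id, chrom=chrom, start=off, end=off + cfg.locus_span,
                    variant_ids=df["variant_id"].tolist(), R=R)
        )
        truth_rows.append(
            {
                "block_id": block_id,
                "causal_gene": causal_gene.gene_id,
                "causal_variant_id": vids[ci],
                "mechanism": mech,
            }
        )

    variants = pd.concat(all_variants, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return SimLandscape(
        variants=variants, blocks=blocks, gene_models=genes, peaks=peaks,
        links=links, truth=truth, R=R, config=cfg,
    )


# ---------------------------------------------------------------------------
# eQTL cell-type mixture and sharing tables
# ---------------------------------------------------------------------------

def simulate_eqtl_mixture(
    cfg: SimConfig,
    beta: float = 0.5,
    n_eqtls: int = 100,
    specific_prob: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Bulk-expression mixture with cell-type-specific and shared eQTLs.

    A specific eQTL acting in cell type k (tissue fraction f_k) contributes
    bulk slope ``f_k * beta``; a shared eQTL contributes ``beta``.  Returns
    genotype matrix X (n_eqtls x n_individuals), bulk expression Y, and a
    truth table with each eQTL's category and true bulk slope.
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_individuals
    X = rng.normal(size=(n_eqtls, n))
    rows = []
    Y = np.empty_like(X)
    for i in range(n_eqtls):
        if rng.random() < specific_prob:
            k = int(rng.integers(len(cfg.cell_fractions)))
            slope = cfg.cell_fractions[k] * beta
            cat = f"specific:ct{k}"
        else:
            slope = beta
            cat = "shared"
        Y[i] = slope * X[i] + rng.normal(size=n)
        rows.append({"eqtl": f"e{i}", "category": cat, "true_slope": slope})
    return X, Y, pd.DataFrame(rows)


def simulate_eqtl_records(
    n: int,
    w: dict[str, float],
    p_c: dict[str, float],
    rng: np.random.Generator | int,
    tissue_means: dict[str, float] | None = None,
    n_tissues_max: int = 49,
) -> pd.DataFrame:
    """Fine-mapped eQTL table with known category proportions and sharing.

    Categories are drawn with probabilities ``w``; each record is active in
    the second tissue with its category's probability ``p_c``; the number of
    active tissues is Poisson around the category mean (shared categories
    high, specific low by default).
    """
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError("category proportions w must sum to 1")
    rng = _as_rng(rng)
    cats = list(w)
    if tissue_means is None:
        tissue_means = {c: (35.0 if "shared" in c else 5.0) for c in cats}
    draw = rng.choice(len(cats), size=n, p=[w[c] for c in cats])
    rows = []
    for i, ci in enumerate(draw):
        c = cats[ci]
        rows.append(
            {
                "variant_id": f"ev{i}",
                "gene_id": f"eg{i}",
                "pip": float(rng.uniform(0.8, 1.0)),
                "category": c,
                "n_tissues_active": int(np.clip(rng.poisson(tissue_means[c]), 1, n_tissues_max)),
                "shared_second": bool(rng.random() < p_c[c]),
            }
        )
    return pd.DataFrame(rows)


def simulate_matched_controls(
    n: int, proportions: dict[str, float], rng: np.random.Generator | int
) -> pd.DataFrame:
    """Categorized control variants with given category proportions."""
    total = sum(proportions.values())
    rng = _as_rng(rng)
    cats = list(proportions)
    draw = rng.choice(len(cats), size=n, p=[proportions[c] / total for c in cats])
    return pd.DataFrame(
        {"variant_id": [f"cv{i}" for i in range(n)], "category": [cats[ci] for ci in draw]}
    )


# ---------------------------------------------------------------------------
# writers: every generated file parses back through genepip.io
# ---------------------------------------------------------------------------

def write_genome(genome: SimGenome, out_dir: str) -> dict[str, str]:
    """Write a simulated genome in the formats the readers consume."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    p = os.path.join(out_dir, "sumstats.tsv")
    genome.variants[["chrom", "pos", "variant_id", "z"]].rename(
        columns={"variant_id": "id"}
    ).to_csv(p, sep="\t", index=False, float_format="%.12g")
    paths["sumstats"] = p
    p = os.path.join(out_dir, "blocks.bed")
    gio.write_blocks(genome.blocks, p)
    paths["blocks"] = p
    p = os.path.join(out_dir, "ld.txt")
    gio.write_ld_matrix(genome.R, p)
    paths["ld"] = p
    p = os.path.join(out_dir, "annotations.tsv")
    genome.annotations.data.reset_index(names="variant_id").to_csv(p, sep="\t", index=False)
    paths["annotations"] = p
    p = os.path.join(out_dir, "truth.tsv")
    genome.truth.to_csv(p, sep="\t", index=False)
    paths["truth"] = p
    logger.info("wrote simulated genome (seed %d) to %s", genome.config.seed, out_dir)
    return paths


def write_landscape(landscape: SimLandscape, out_dir: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    p = os.path.join(out_dir, "sumstats.tsv")
    landscape.variants[["chrom", "pos", "variant_id", "z"]].rename(
        columns={"variant_id": "id"}
    ).to_csv(p, sep="\t", index=False, float_format="%.12g")
    paths["sumstats"] = p
    p = os.path.join(out_dir, "blocks.bed")
    gio.write_blocks(landscape.blocks, p)
    paths["blocks"] = p
    p = os.path.join(out_dir, "genes.tsv")
    gio.write_gene_models(landscape.gene_models, p)
    paths["genes"] = p
    p = os.path.join(out_dir, "links.bedpe")
    gio.write_links(landscape.links, p)
    paths["links"] = p
    p = os.path.join(out_dir, "peaks.bed")
    with open(p, "w") as fh:
        for pk in landscape.peaks:
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.peak_id}\n")
    paths["peaks"] = p
    p = os.path.join(out_dir, "truth.tsv")
    landscape.truth.to_csv(p, sep="\t", index=False)
    paths["truth"] = p
    return paths
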