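"""SNP-level functional annotation from open-chromatin peaks and gene models.

Builds the disjoint annotation categories used both for enrichment estimation
and for PIP partitioning: coding exon, UTR, conserved sequence, and
open-chromatin region (OCR) classes.  OCRs are classified by cell-type
sharing: cell-type-specific (differentially accessible in exactly one cell
type), shared in 2-3 or in 4+ cell types (by top-quantile accessibility for
non-DA peaks, by DA cell-type count for multi-DA peaks), or non-DA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ConfigurationError, GeneModel, VariantRecord

logger = logging.getLogger("genepip")

CAT_SPECIFIC = "specific"  # rendered as "specific:<cell type>"
CAT_SHARED_23 = "shared_2_3"
CAT_SHARED_4P = "shared_4plus"
CAT_NON_DA = "non_DA"
CAT_OTHER = "other"

DEFAULT_PRECEDENCE = [
    "coding",
    "utr",
    "conserved",
    # OCR classes, most specific first; cell-type-specific entries are
    # inserted ahead of the shared classes by build_snp_annotations.
    CAT_SHARED_23,
    CAT_SHARED_4P,
    CAT_NON_DA,
]


@dataclass(frozen=True)
class PeakRecord:
    """An open-chromatin peak with per-cell-type normalized accessibility."""

    peak_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    accessibility: dict[str, float] = field(default_factory=dict)
    da_cell_types: frozenset[str] = frozenset()

    def __post_init__(self):
        if any(v < 0 for v in self.accessibility.values()):
            raise ValueError(f"peak {self.peak_id}: accessibility must be >= 0")


def classify_peak_sharing(
    peaks: list[PeakRecord],
    cell_types: list[str] | None = None,
    q: float = 0.75,
) -> pd.Series:
    """Assign each peak a sharing category.

    Within each cell type, peaks at or above the ``q``-quantile of normalized
    accessibility (ties included) count as highly accessible.  DA peaks in
    exactly one cell type are cell-type-specific; DA peaks in several cell
    types are moved to the shared classes by their DA cell-type count.
    Non-DA peaks highly accessible in 2-3 cell types are ``shared_2_3``, in
    4 or more ``shared_4plus``, and otherwise ``non_DA``.
    """
    if cell_types is None:
        cell_types = sorted({ct for p in peaks for ct in p.accessibility})
    if len(cell_types) < 2:
        raise ConfigurationError("peak sharing classification needs >= 2 cell types")
    for p in peaks:
        unknown = p.da_cell_types - set(cell_types)
        if unknown:
            raise ConfigurationError(
                f"peak {p.peak_id}: DA cell type(s) {sorted(unknown)} not among declared "
                f"cell types {cell_types}"
            )

    # per-cell-type top-quantile indicator over the full peak universe
    acc = np.array([[p.accessibility.get(ct, 0.0) for ct in cell_types] for p in peaks])
    thresholds = np.quantile(acc, q, axis=0)
    n_top = (acc >= thresholds).sum(axis=1)

    out = {}
    n_moved = 0
    for p, nt in zip(peaks, n_top):
        n_da = len(p.da_cell_types)
        if n_da == 1:
            out[p.peak_id] = f"{CAT_SPECIFIC}:{next(iter(p.da_cell_types))}"
        elif n_da >= 2:
            out[p.peak_id] = CAT_SHARED_4P if n_da >= 4 else CAT_SHARED_23
            n_moved += 1
        elif nt >= 4:
            out[p.peak_id] = CAT_SHARED_4P
        elif nt >= 2:
            out[p.peak_id] = CAT_SHARED_23
        else:
            out[p.peak_id] = CAT_NON_DA
    if n_moved:
        logger.info(
            "moved %d multi-cell-type DA peak(s) to shared classes (%.2f%% of peaks); "
            "quantile ties at the %.0f%% boundary are included in the top set",
            n_moved, 100.0 * n_moved / max(len(peaks), 1), 100 * (1 - q),
        )
    return pd.Series(out, name="category")


class AnnotationMatrix:
    """Binary variant-by-annotation matrix, optionally disjoint.

    ``data`` holds one-hot integer columns indexed by variant id.  When
    ``disjoint`` is true every row sums to at most 1 (zero rows mean the
    catch-all category ``other``) and a precedence order must resolve
    overlaps at construction time.
    """

    def __init__(self, data: pd.DataFrame, disjoint: bool = True, precedence: list[str] | None = None):
        self.data = data.astype(int)
        self.disjoint = disjoint
        self.precedence = precedence
        if disjoint and (self.data.sum(axis=1) > 1).any():
            bad = self.data.index[self.data.sum(axis=1) > 1][:5].tolist()
            raise ConfigurationError(f"disjoint annotation matrix has multi-label rows: {bad}")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.index)

    def categories(self) -> pd.Series:
        """Per-variant category name (``other`` for all-zero rows)."""
        if not self.disjoint:
            raise ConfigurationError("categories() requires a disjoint matrix")
        cat = pd.Series(CAT_OTHER, index=self.data.index, name="category")
        for name in self.data.columns:
            cat[self.data[name] == 1] = name
        return cat

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        if self.disjoint:
            out.insert(0, "category", self.categories())
        return out.reset_index(names="variant_id")


def _tree_from_intervals(intervals) -> IntervalTree:
    t = IntervalTree()
    for s, e in intervals:
        if e > s:
            t.addi(s, e)
    return t


class _TrackIndex:
    """Per-chromosome interval trees for a set of named tracks."""

    def __init__(self, tracks: dict[str, dict[str, list[tuple[int, int]]]]):
        self.trees = {
            name: {chrom: _tree_from_intervals(ivs) for chrom, ivs in by_chrom.items()}
            for name, by_chrom in tracks.items()
        }

    def hits(self, chrom: str, pos: int) -> list[str]:
        """Track names overlapping a 1-based position."""
        p = pos - 1
        return [
            name for name, by_chrom in self.trees.items()
            if chrom in by_chrom and by_chrom[chrom].overlaps_point(p)
        ]


def _collect(by_chrom: dict, chrom: str, start: int, end: int) -> None:
    by_chrom.setdefault(chrom, []).append((start, end))


def gene_model_tracks(gene_models: list[GeneModel]) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """``coding`` (exons) and ``utr`` interval tracks from gene models."""
    coding: dict[str, list] = {}
    utr: dict[str, list] = {}
    for g in gene_models:
        for s, e in g.exons:
            _collect(coding, g.chrom, s, e)
        for s, e in g.utrs:
            _collect(utr, g.chrom, s, e)
    return {"coding": coding, "utr": utr}


def peak_category_tracks(
    peaks: list[PeakRecord], categories: pd.Series
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    tracks: dict[str, dict[str, list]] = {}
    for p in peaks:
        cat = categories[p.peak_id]
        tracks.setdefault(cat, {})
        _collect(tracks[cat], p.chrom, p.start, p.end)
    return tracks


def build_snp_annotations(
    variants: list[VariantRecord],
    peaks: list[PeakRecord] | None = None,
    peak_categories: pd.Series | None = None,
    gene_models: list[GeneModel] | None = None,
    extra_tracks: dict[str, dict[str, list[tuple[int, int]]]] | None = None,
    precedence: list[str] | None = None,
    disjoint: bool = True,
) -> AnnotationMatrix:
    """Label every SNP with the highest-precedence annotation it overlaps.

    Tracks are assembled from gene models (coding, utr), classified peaks
    (one track per OCR category), and any ``extra_tracks`` (e.g. conserved
    elements as BED intervals keyed by chromosome).  SNPs overlapping no
    track fall into the implicit ``other`` category (all-zero row).
    """
    tracks: dict[str, dict[str, list[tuple[int, int]]]] = {}
    if gene_models:
        tracks.update(gene_model_tracks(gene_models))
    if peaks is not None:
        if peak_categories is None:
            raise ConfigurationError("peaks supplied without categories; run classify_peak_sharing")
        tracks.update(peak_category_tracks(peaks, peak_categories))
    if extra_tracks:
        tracks.update(extra_tracks)

    if precedence is None:
        specific = sorted(n for n in tracks if n.startswith(f"{CAT_SPECIFIC}:"))
        precedence = [n for n in DEFAULT_PRECEDENCE[:3] if n in tracks] + specific + [
            n for n in DEFAULT_PRECEDENCE[3:] if n in tracks
        ]
        leftover = [n for n in tracks if n not in precedence]
        precedence += sorted(leftover)
    if disjoint:
        missing = set(tracks) - set(precedence)
        if missing:
            raise ConfigurationError(
                f"disjoint annotation requires a precedence covering all tracks; missing {sorted(missing)}"
            )

    index = _TrackIndex(tracks)
    rank = {name: i for i, name in enumerate(precedence)}
    names = [n for n in precedence if n in tracks] if disjoint else sorted(tracks)
    mat = pd.DataFrame(0, index=[v.variant_id for v in variants], columns=names, dtype=int)
    for v in variants:
        hits = index.hits(v.chrom, v.pos)
        if not hits:
            continue
        if disjoint:
            mat.loc[v.variant_id, min(hits, key=lambda h: rank[h])] = 1
        else:
            mat.loc[v.variant_id, hits] = 1
    return AnnotationMatrix(mat, disjoint=disjoint, precedence=precedence)


EQTL_FILTERED = "filtered"
EQTL_UNASSIGNED = "unassigned"


def assign_eqtl_category(
    chrom: str,
    pos: int,
    peaks: list[PeakRecord],
    peak_categories: pd.Series,
    gene_models: list[GeneModel],
) -> str:
    """Functional category of a fine-mapped eQTL variant.

    Variants in OCRs that overlap exons or UTRs, and variants in non-DA
    OCRs, are ambiguous and ``filtered``.  Variants in intronic OCRs take
    the OCR's sharing class (``intron_ocr:<class>``); variants in exons or
    UTRs outside OCRs are ``exon`` / ``utr``; everything else is
    ``unassigned``.
    """
    gm_tracks = gene_model_tracks(gene_models)
    exon_trees = {c: _tree_from_intervals(ivs) for c, ivs in gm_tracks["coding"].items()}
    utr_trees = {c: _tree_from_intervals(ivs) for c, ivs in gm_tracks["utr"].items()}
    body: dict[str, list] = {}
    for g in gene_models:
        span = [s for s, _ in g.exons] + [e for _, e in g.exons] + [g.tss - 1]
        _collect(body, g.chrom, min(span), max(span) + 1)
    body_trees = {c: _tree_from_intervals(ivs) for c, ivs in body.items()}

    p0 = pos - 1
    in_exon = chrom in exon_trees and exon_trees[chrom].overlaps_point(p0)
    in_utr = chrom in utr_trees and utr_trees[chrom].overlaps_point(p0)
    containing = [
        p for p in peaks
        if p.chrom == chrom and p.start <= p0 < p.end
    ]
    if containing:
        for p in containing:
            ocr_hits_exonic = (
                (chrom in exon_trees and bool(exon_trees[chrom].overlap(p.start, p.end)))
                or (chrom in utr_trees and bool(utr_trees[chrom].overlap(p.start, p.end)))
            )
            if ocr_hits_exonic or peak_categories[p.peak_id] == CAT_NON_DA:
                return EQTL_FILTERED
        in_gene = chrom in body_trees and body_trees[chrom].overlaps_point(p0)
        if in_gene:
            cats = sorted(peak_categories[p.peak_id] for p in containing)
            return f"intron_ocr:{cats[0]}"
        return EQTL_UNASSIGNED
    if in_utr:  # UTRs lie within exon intervals; the more specific label wins
        return "utr"
    if in_exon:
        return "exon"
    return EQTL_UNASSIGNED
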