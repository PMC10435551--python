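"""Partition of fine-mapping PIPs into disjoint functional categories.

Summed PIP per category is interpretable as the expected number of causal
variants falling in that category; per-locus proportions give the
probability that the locus's causal variant lies in each category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotate import AnnotationMatrix, CAT_OTHER, CAT_SPECIFIC
from .io import ConfigurationError

logger = logging.getLogger("genepip")


@dataclass
class PipPartition:
    scope: str  # "genomewide" or "locus:<id>"
    summed: dict[str, float]
    proportions: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.summed.values())


def _partition(pips: pd.Series, categories: pd.Series, scope: str) -> PipPartition:
    summed = pips.groupby(categories).sum().to_dict()
    total = sum(summed.values())
    props = {c: (v / total if total > 0 else 0.0) for c, v in summed.items()}
    return PipPartition(scope=scope, summed=summed, proportions=props)


def partition_pips(
    finemap_results: pd.DataFrame,
    annotations: AnnotationMatrix,
    scope: str = "genomewide",
) -> PipPartition | dict[str, PipPartition]:
    """Sum PIPs within disjoint annotation categories.

    ``finemap_results`` needs columns ``variant_id``, ``block_id``, ``pip``.
    ``scope="genomewide"`` returns one partition over all loci;
    ``scope="locus"`` returns one per LD block.  Variants absent from the
    annotation matrix fall in the ``other`` category.
    """
    if not annotations.disjoint:
        raise ConfigurationError("PIP partitioning requires a disjoint annotation matrix")
    cats = annotations.categories()
    cat = finemap_results["variant_id"].map(cats).fillna(CAT_OTHER)
    cat.index = finemap_results.index
    if scope == "genomewide":
        return _partition(finemap_results["pip"], cat, "genomewide")
    if scope == "locus":
        out = {}
        for block_id, grp in finemap_results.groupby("block_id", sort=False):
            out[block_id] = _partition(grp["pip"], cat.loc[grp.index], f"locus:{block_id}")
        return out
    raise ValueError(f"scope must be 'genomewide' or 'locus', got {scope!r}")


def partition_table(partitions: dict[str, PipPartition] | PipPartition) -> pd.DataFrame:
    if isinstance(partitions, PipPartition):
        partitions = {partitions.scope: partitions}
    rows = [
        {"scope": scope, "category": c, "summed_pip": p.summed[c], "proportion": p.proportions[c]}
        for scope, p in partitions.items()
        for c in sorted(p.summed)
    ]
    return pd.DataFrame(rows)


def locus_celltype_assignment(
    locus_partitions: dict[str, PipPartition],
    ocr_floor: float = 0.25,
    ocr_prefixes: tuple[str, ...] = (f"{CAT_SPECIFIC}:", "shared_", "non_DA"),
) -> pd.DataFrame:
    """Cell-type attribution of loci through their OCR PIP mass.

    Loci whose total PIP in OCR categories is below ``ocr_floor`` are
    excluded.  For the rest, each OCR category's share is reported both raw
    (share of the locus's total PIP) and renormalized over OCR categories
    only (a probability distribution over chromatin contexts given that the
    causal variant is in open chromatin).
    """
    rows = []
    n_excluded = 0
    for locus, part in locus_partitions.items():
        ocr = {
            c: v for c, v in part.summed.items()
            if any(c.startswith(pref) for pref in ocr_prefixes)
        }
        ocr_total = sum(ocr.values())
        if ocr_total < ocr_floor:
            n_excluded += 1
            continue
        locus_total = part.total
        for c, v in sorted(ocr.items()):
            rows.append(
                {
                    "locus": locus.removeprefix("locus:"),
                    "category": c,
                    "summed_pip": v,
                    "raw_share": v / locus_total if locus_total > 0 else 0.0,
                    "ocr_share": v / ocr_total,
                }
            )
    if n_excluded:
        logger.info("excluded %d locus/loci with OCR PIP below %.2f", n_excluded, ocr_floor)
    return pd.DataFrame(rows, columns=["locus", "category", "summed_pip", "raw_share", "ocr_share"])
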