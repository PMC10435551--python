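"""Readers, writers and coordinate plumbing for GWAS fine-mapping inputs.

Conventions
-----------
GWAS variant positions are 1-based; every BED/BEDPE interval is 0-based
half-open.  Conversion happens only here, at the I/O boundary: a 1-based
position ``p`` lies inside a half-open interval ``[s, e)`` iff ``s < p <= e``.
Allele columns, when present in summary statistics, are accepted and ignored
(fine-mapping consumes z-scores and LD only).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("genepip")


class SchemaError(ValueError):
    """A required column is missing or a file does not match its schema."""


class ConfigurationError(ValueError):
    """Inconsistent configuration, e.g. overlapping LD blocks."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A single GWAS variant with its association z-score."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    z: float
    block_id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1, got {self.pos}")
        if not np.isfinite(self.z):
            raise ValueError(f"{self.variant_id}: z-score must be finite, got {self.z}")


@dataclass
class LDBlock:
    """An approximately independent LD block with optional correlation matrix."""

    block_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    variant_ids: list[str] = field(default_factory=list)
    R: np.ndarray | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"block {self.block_id}: start must be < end")
        if self.R is not None:
            self.validate_ld()

    def validate_ld(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError(f"block {self.block_id}: R must be square")
        if self.variant_ids and R.shape[0] != len(self.variant_ids):
            raise ValueError(
                f"block {self.block_id}: R dimension {R.shape[0]} != "
                f"{len(self.variant_ids)} member variants"
            )
        if not np.allclose(np.diag(R), 1.0, atol=1e-6):
            raise ValueError(f"block {self.block_id}: R must have unit diagonal")
        if np.nanmax(np.abs(R)) > 1.0 + 1e-6:
            raise ValueError(f"block {self.block_id}: correlations must lie in [-1, 1]")
        self.R = R

    def contains(self, pos: int) -> bool:
        """1-based position inside the 0-based half-open interval."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class GeneModel:
    """Simplified gene model: TSS plus exon and UTR intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based
    exons: tuple[tuple[int, int], ...] = ()
    utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, ivs in (("exons", self.exons), ("utrs", self.utrs)):
            for s, e in ivs:
                if s >= e:
                    raise ValueError(f"{self.gene_id}: empty {name} interval [{s}, {e})")
            if list(ivs) != sorted(ivs):
                raise ValueError(f"{self.gene_id}: {name} intervals must be sorted")


@dataclass(frozen=True)
class LinkRecord:
    """A region-to-gene regulatory link (enhancer loop or proximal OCR)."""

    chrom: str
    start: int  # 0-based half-open region
    end: int
    gene_id: str
    link_type: str  # ABC | PCHIC | PROXIMAL_OCR
    score: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"link {self.gene_id}: malformed interval [{self.start}, {self.end})")
        if self.link_type == "ABC" and self.score is None:
            raise ValueError(f"ABC link to {self.gene_id} must carry a score")
        if self.score is not None and self.score < 0:
            raise ValueError(f"link to {self.gene_id}: score must be >= 0")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

DEFAULT_SUMSTAT_SCHEMA = {"chrom": "chrom", "pos": "pos", "id": "id", "z": "z"}


def read_summary_stats(path: str, schema: dict[str, str] | None = None) -> list[VariantRecord]:
    """Read a tab-separated GWAS summary-statistics table into variant records.

    ``schema`` maps the logical fields chrom/pos/id/z onto the file's column
    names.  Rows must be unique on (chrom, pos, id); a non-numeric z-score is a
    row-level error reported with its line number.
    """
    schema = dict(DEFAULT_SUMSTAT_SCHEMA, **(schema or {}))
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("summary statistics file %s is empty", path)
        return []
    if df.empty:
        logger.warning("summary statistics file %s has no data rows", path)
        return []
    missing = [c for c in ("chrom", "pos", "id", "z") if schema[c] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mapped column(s) {[schema[c] for c in missing]}; "
            f"found {list(df.columns)}"
        )
    extra = set(df.columns) - {schema[c] for c in ("chrom", "pos", "id", "z")}
    alleles = {c for c in extra if c.lower() in {"a1", "a2", "ref", "alt", "ea", "nea", "allele1", "allele2"}}
    if alleles:
        logger.info("ignoring allele column(s) %s (fine-mapping uses z only)", sorted(alleles))

    z = pd.to_numeric(df[schema["z"]], errors="coerce")
    bad = z.isna() | ~np.isfinite(z)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}, line {row + 2}: non-numeric or non-finite z-score "
            f"{df[schema['z']].iloc[row]!r} for variant {df[schema['id']].iloc[row]!r}"
        )
    key = df[[schema["chrom"], schema["pos"], schema["id"]]]
    dup = key.duplicated()
    if dup.any():
        dup_ids = df[schema["id"]][dup].tolist()
        raise ValueError(f"{path}: duplicate (chrom, pos, id) rows rejected: {dup_ids[:5]}")

    records = [
        VariantRecord(
            variant_id=str(r[schema["id"]]),
            chrom=str(r[schema["chrom"]]),
            pos=int(r[schema["pos"]]),
            z=float(zi),
        )
        for (_, r), zi in zip(df.iterrows(), z)
    ]
    sex = [v.variant_id for v in records if v.chrom.lstrip("chr") in ("X", "Y")]
    if sex:
        logger.warning(
            "%d variant(s) on chrX/chrY (inputs are expected pre-filtered to autosomes): %s",
            len(sex), sex[:5],
        )
    logger.info("read %d variants from %s", len(records), path)
    return records


def write_summary_stats(variants: list[VariantRecord], path: str) -> None:
    pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "id": [v.variant_id for v in variants],
            "z": [v.z for v in variants],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

def read_blocks(path: str) -> list[LDBlock]:
    """Read LD block definitions from BED (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    blocks = []
    for i, row in df.iterrows():
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        name = str(row[3]) if df.shape[1] > 3 and not pd.isna(row[3]) else f"{chrom}_{start}_{end}"
        blocks.append(LDBlock(block_id=name, chrom=chrom, start=start, end=end))
    _check_non_overlapping(blocks)
    return blocks


def write_blocks(blocks: list[LDBlock], path: str) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\n")


def _check_non_overlapping(blocks: list[LDBlock]) -> None:
    by_chrom: dict[str, list[LDBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bl in by_chrom.items():
        bl = sorted(bl, key=lambda b: b.start)
        for a, b in zip(bl, bl[1:]):
            if b.start < a.end:
                raise ConfigurationError(
                    f"overlapping LD blocks on {chrom}: {a.block_id} and {b.block_id}"
                )


def assign_blocks(variants: list[VariantRecord], blocks: list[LDBlock]) -> list[VariantRecord]:
    """Assign each variant to the unique LD block containing it.

    Variants falling in no block are dropped (count logged).  Each block's
    ``variant_ids`` list is populated in input variant order.
    """
    _check_non_overlapping(blocks)
    by_chrom: dict[str, list[LDBlock]] = {}
    for b in blocks:
        b.variant_ids = []
        by_chrom.setdefault(b.chrom, []).append(b)
    starts = {c: np.array([b.start for b in sorted(bl, key=lambda b: b.start)]) for c, bl in by_chrom.items()}
    sorted_blocks = {c: sorted(bl, key=lambda b: b.start) for c, bl in by_chrom.items()}

    assigned: list[VariantRecord] = []
    n_dropped = 0
    for v in variants:
        if v.chrom not in starts:
            n_dropped += 1
            continue
        # block with the largest start < pos (1-based pos in 0-based half-open [s, e))
        i = int(np.searchsorted(starts[v.chrom], v.pos, side="left")) - 1
        if i >= 0 and sorted_blocks[v.chrom][i].contains(v.pos):
            blk = sorted_blocks[v.chrom][i]
            blk.variant_ids.append(v.variant_id)
            assigned.append(replace(v, block_id=blk.block_id))
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d variant(s) falling in no LD block", n_dropped)
    logger.info("assigned %d variants to %d blocks", len(assigned), len(blocks))
    return assigned


def read_ld_matrix(path: str) -> np.ndarray:
    """Dense LD correlation matrix from whitespace text or a .npy container."""
    if path.endswith(".npy"):
        R = np.load(path)
    else:
        R = np.loadtxt(path)
    return np.atleast_2d(np.asarray(R, dtype=float))


def write_ld_matrix(R: np.ndarray, path: str) -> None:
    if path.endswith(".npy"):
        np.save(path, R)
    else:
        np.savetxt(path, R, fmt="%.12g")


# ---------------------------------------------------------------------------
# gene models, links, peaks
# ---------------------------------------------------------------------------

def _format_intervals(ivs) -> str:
    return ",".join(f"{s}-{e}" for s, e in ivs) if ivs else "."


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    text = str(text).strip()
    if text in (".", "", "nan"):
        return ()
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        if int(s) >= int(e):
            raise ValueError(f"malformed interval {part!r} (start >= end)")
        out.append((int(s), int(e)))
    return tuple(out)


def read_gene_models(path: str) -> list[GeneModel]:
    """Read the simplified gene-model table.

    Columns: gene_id, chrom, strand, tss (1-based), exons, utrs — the last two
    as comma-joined 0-based half-open ``start-end`` runs, ``.`` when absent.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss", "exons", "utrs"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: gene model table needs columns {sorted(required)}")
    genes = []
    for i, row in df.iterrows():
        try:
            genes.append(
                GeneModel(
                    gene_id=str(row.gene_id),
                    chrom=str(row.chrom),
                    strand=str(row.strand),
                    tss=int(row.tss),
                    exons=_parse_intervals(row.exons),
                    utrs=_parse_intervals(row.utrs),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}, line {i + 2}: {err}") from err
    return genes


def write_gene_models(genes: list[GeneModel], path: str) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "exons": [_format_intervals(g.exons) for g in genes],
            "utrs": [_format_intervals(g.utrs) for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


ABC_MIN_SCORE = 0.015


def read_links(
    path: str,
    type_column: int = 7,
    score_column: int = 8,
    abc_min_score: float = ABC_MIN_SCORE,
) -> list[LinkRecord]:
    """Read region-to-promoter links from a BEDPE-like table.

    Columns (0-based): chrom1, start1, end1, chrom2, start2, end2, gene_id,
    then link type and score at ``type_column`` / ``score_column`` (score may
    be ``.``).  ABC links below ``abc_min_score`` are filtered out.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    links: list[LinkRecord] = []
    n_filtered = 0
    for i, row in df.iterrows():
        start, end = int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"{path}, line {i + 1}: malformed interval {start}-{end}")
        raw_score = row[score_column]
        score = None if (pd.isna(raw_score) or str(raw_score) == ".") else float(raw_score)
        link_type = str(row[type_column]).upper()
        if link_type == "ABC" and (score is None or score < abc_min_score):
            n_filtered += 1
            continue
        links.append(
            LinkRecord(
                chrom=str(row[0]), start=start, end=end,
                gene_id=str(row[6]), link_type=link_type, score=score,
            )
        )
    if n_filtered:
        logger.info("filtered %d ABC link(s) below score %.3g", n_filtered, abc_min_score)
    return links


def write_links(links: list[LinkRecord], path: str) -> None:
    with open(path, "w") as fh:
        for l in links:
            score = "." if l.score is None else f"{l.score:.12g}"
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.chrom}\t{l.start}\t{l.end}\t"
                f"{l.gene_id}\t{l.link_type}\t{score}\n"
            )


def write_results(tables: dict[str, pd.DataFrame], out_dir: str) -> dict[str, str]:
    """Write each table as ``<out_dir>/<name>.tsv`` (reals at 12 sig. digits)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths[name] = p
        logger.info("wrote %s (%d rows)", p, len(df))
    return paths
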