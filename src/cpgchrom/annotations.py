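"""Gene and promoter annotation.

Loads gene models, filters them for length and promoter isolation, classifies
promoters by CpG-island overlap and by windowed CpG observed/expected content
(the high/intermediate/low CpG-promoter scheme), and tests promoter overlap
with arbitrary interval sets such as CTCF binding peaks.

Coordinates are 0-based and half-open throughout, as in BED.  The TSS of a
minus-strand gene is the right-most base of its annotated extent; promoter
sequences handed to :func:`classify_weber` are expected strand-oriented
(reverse-complemented for minus-strand genes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GenomicInterval",
    "IslandClass",
    "WeberClass",
    "PromoterClass",
    "filter_genes",
    "classify_island_overlap",
    "cpg_oe_ratio",
    "classify_weber",
    "overlaps_any",
    "read_gene_table",
    "write_gene_table",
    "read_bed",
]

_VALID_STRANDS = frozenset("+-")


class IslandClass(str, Enum):
    """Promoter class by CpG-island overlap at the TSS."""

    CPG = "CPG"
    NONCPG = "NONCPG"


class WeberClass(str, Enum):
    """Promoter class from the windowed CpG observed/expected scan."""

    HCP = "HCP"
    ICP = "ICP"
    LCP = "LCP"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class GeneModel:
    """One gene, anchored at its most 5' transcription start site.

    ``tss`` and ``end_`` are genomic coordinates; for a minus-strand gene
    ``end_ < tss``.  ``n_tss`` counts annotated alternative start sites and
    supports the single-TSS sensitivity filter.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    end_: int
    n_tss: int = 1

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.tss < 0 or self.end_ < 0:
            raise ValueError(f"gene {self.gene_id}: negative coordinate")
        if self.length < 1:
            raise ValueError(f"gene {self.gene_id}: zero-length gene")
        if self.strand == "+" and self.end_ <= self.tss:
            raise ValueError(f"gene {self.gene_id}: end must lie downstream of TSS")
        if self.strand == "-" and self.end_ >= self.tss:
            raise ValueError(f"gene {self.gene_id}: end must lie downstream of TSS")

    @property
    def length(self) -> int:
        return abs(self.end_ - self.tss)

    @property
    def extent(self) -> tuple[int, int]:
        """Genomic span ``(left, right)`` of the annotated gene, both inclusive."""
        return (min(self.tss, self.end_), max(self.tss, self.end_))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end_)``."""

    chrom: str
    start: int
    end_: int

    def __post_init__(self) -> None:
        if self.start >= self.end_:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end_}: start must precede end"
            )


@dataclass(frozen=True)
class PromoterClass:
    island_class: IslandClass
    weber_class: WeberClass = WeberClass.UNKNOWN


# ---------------------------------------------------------------------------
# gene filtering


def filter_genes(
    genes: Sequence[GeneModel],
    min_length_bp: int = 3000,
    isolation_bp: int = 500,
) -> list[GeneModel]:
    """Drop short genes and genes whose promoter has a close neighbour.

    A gene is retained iff its length is at least ``min_length_bp`` and no
    *other* input gene's annotated extent (TSS through gene end) comes within
    ``isolation_bp`` of its TSS.  Short genes still count as neighbours.
    Input order is preserved; the filter is idempotent.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    kept: list[GeneModel] = []
    for g in genes:
        if g.length < min_length_bp:
            continue
        crowded = False
        for other in by_chrom[g.chrom]:
            if other is g:
                continue
            lo, hi = other.extent
            dist = max(lo - g.tss, g.tss - hi, 0)
            if dist <= isolation_bp:
                crowded = True
                break
        if not crowded:
            kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# interval indexing


class _IntervalIndex:
    """Merged, sorted per-chromosome intervals supporting vectorised queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        raw: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault(iv.chrom, []).append((iv.start, iv.end_))
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in raw.items():
            ivs.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in ivs:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[chrom] = (np.asarray(starts), np.asarray(ends))

    def covers_point(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` lies inside some interval ``[start, end_)``."""
        if chrom not in self._merged:
            return False
        starts, ends = self._merged[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def intersects(self, chrom: str, start: int, end_: int) -> bool:
        """True iff ``[start, end_)`` intersects some interval."""
        if chrom not in self._merged:
            return False
        starts, ends = self._merged[chrom]
        i = int(np.searchsorted(starts, end_, side="left")) - 1
        return i >= 0 and start < ends[i]

    def coverage_mask(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean per-position coverage for an array of genomic positions."""
        if chrom not in self._merged:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = self._merged[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out


def classify_island_overlap(
    genes: Sequence[GeneModel], islands: Sequence[GenomicInterval]
) -> dict[str, IslandClass]:
    """Label each gene CPG iff its TSS falls inside a CpG island.

    The test is a point-in-interval test on the TSS against half-open island
    intervals; a gene on a chromosome with no islands is NONCPG.
    """
    index = _IntervalIndex(islands)
    chroms_with_islands = set(index._merged)
    out: dict[str, IslandClass] = {}
    for g in genes:
        if g.chrom not in chroms_with_islands:
            log.info("gene %s: chromosome %s absent from island set", g.gene_id, g.chrom)
        out[g.gene_id] = (
            IslandClass.CPG if index.covers_point(g.chrom, g.tss) else IslandClass.NONCPG
        )
    return out


def overlaps_any(
    genes: Sequence[GeneModel],
    peaks: Sequence[GenomicInterval],
    mode: str = "tss_point",
    window_bp: int = 500,
) -> dict[str, bool]:
    """Test each gene's promoter for overlap with a peak set.

    ``tss_point`` tests the TSS coordinate itself; ``promoter_window`` tests
    the half-open window ``[tss - window_bp, tss + window_bp)``.
    """
    if mode not in ("tss_point", "promoter_window"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    index = _IntervalIndex(peaks)
    out: dict[str, bool] = {}
    for g in genes:
        if mode == "tss_point":
            out[g.gene_id] = index.covers_point(g.chrom, g.tss)
        else:
            out[g.gene_id] = index.intersects(
                g.chrom, max(g.tss - window_bp, 0), g.tss + window_bp
            )
    return out


# ---------------------------------------------------------------------------
# CpG content classification

_BASE_CODE = np.full(256, 0, dtype=np.int8)  # 0=other, 1=C, 2=G, 3=N
for _b in "Cc":
    _BASE_CODE[ord(_b)] = 1
for _b in "Gg":
    _BASE_CODE[ord(_b)] = 2
for _b in "Nn":
    _BASE_CODE[ord(_b)] = 3


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    is_c = codes == 1
    is_g = codes == 2
    is_n = codes == 3
    is_cg = np.zeros(len(seq), dtype=bool)
    if len(seq) >= 2:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, is_n, is_cg


def cpg_oe_ratio(seq: str) -> float:
    """CpG observed/expected ratio ``N_CpG * L / (N_C * N_G)``.

    N bases count as neither C nor G and never form a CpG.  Returns 0.0 when
    the sequence contains no C or no G.
    """
    if len(seq) < 2:
        raise ValueError("cpg_oe_ratio requires a sequence of length >= 2")
    is_c, is_g, _, is_cg = _encode(seq)
    n_c = int(is_c.sum())
    n_g = int(is_g.sum())
    if n_c == 0 or n_g == 0:
        return 0.0
    return int(is_cg.sum()) * len(seq) / (n_c * n_g)


def classify_weber(
    promoter_seq: str,
    window_bp: int = 500,
    step_bp: int = 1,
    oe_high: float = 0.75,
    gc_high: float = 55.0,
    oe_low: float = 0.48,
    max_n_frac: float = 0.10,
    expected_length: int | None = 1500,
) -> WeberClass:
    """Classify a promoter as HCP / ICP / LCP by a sliding-window CpG scan.

    The promoter sequence spans TSS-1200 to TSS+300 (strand-oriented).  The
    scan slides a ``window_bp`` window in ``step_bp`` steps: HCP if any window
    has CpG o/e > ``oe_high`` and GC% > ``gc_high``; LCP if every window has
    o/e <= ``oe_low``; otherwise ICP.  Windows with more than ``max_n_frac``
    N bases are skipped; GC% is computed over non-N bases.
    """
    if expected_length is not None and len(promoter_seq) != expected_length:
        raise ValueError(
            f"promoter sequence length {len(promoter_seq)} != expected {expected_length}"
        )
    if len(promoter_seq) < window_bp:
        raise ValueError("promoter sequence shorter than scan window")

    is_c, is_g, is_n, is_cg = _encode(promoter_seq)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(0, len(promoter_seq) - window_bp + 1, step_bp)
    n_c = cum_c[starts + window_bp] - cum_c[starts]
    n_g = cum_g[starts + window_bp] - cum_g[starts]
    n_n = cum_n[starts + window_bp] - cum_n[starts]
    # dinucleotides fully inside the window: start .. start+window_bp-2
    n_cg = cum_cg[starts + window_bp - 1] - cum_cg[starts]

    usable = n_n <= max_n_frac * window_bp
    if not usable.all():
        log.info("classify_weber: skipped %d windows with >10%% N", int((~usable).sum()))
    if not usable.any():
        return WeberClass.UNKNOWN

    n_c, n_g, n_n, n_cg = (a[usable] for a in (n_c, n_g, n_n, n_cg))
    denom = (n_c * n_g).astype(float)
    oe = np.where(denom > 0, n_cg * window_bp / np.where(denom > 0, denom, 1.0), 0.0)
    non_n = window_bp - n_n
    gc_pct = np.where(non_n > 0, 100.0 * (n_c + n_g) / np.where(non_n > 0, non_n, 1), 0.0)

    if np.any((oe > oe_high) & (gc_pct > gc_high)):
        return WeberClass.HCP
    if np.all(oe <= oe_low):
        return WeberClass.LCP
    return WeberClass.ICP


# ---------------------------------------------------------------------------
# file I/O

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "end", "n_tss"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a tab-delimited gene table with header ``gene_id chrom strand tss end n_tss``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    return [
        GeneModel(
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss),
            end_=int(row.end),
            n_tss=int(row.n_tss),
        )
        for row in df.itertuples(index=False)
    ]


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.end_, g.n_tss) for g in genes],
        columns=_GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+-column BED file into half-open intervals (extra columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out
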