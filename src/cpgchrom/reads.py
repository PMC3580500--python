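"""Mapped-read processing: deduplication, dyad inference, and count tracks.

Sequenced nucleosome / ChIP fragments are represented by their mapped reads.
Each read's start is shifted 75 bp in the direction of sequencing —
approximately half the isolated fragment length — to estimate the nucleosome
dyad position, and deduplicated dyads are tallied into per-chromosome,
per-base integer count tracks.  Tracks carry a rescaling multiplier that
normalises libraries to a common depth (10 million fragments by default);
the multiplier is applied at read-out so the integer tallies stay exact.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MappedRead",
    "DyadTrack",
    "dedup",
    "shift_to_dyad",
    "build_track",
    "read_bed_reads",
    "write_bed_reads",
    "write_bedgraph",
]

DEFAULT_SHIFT_BP = 75
DEFAULT_TARGET_TOTAL = 10_000_000


@dataclass(frozen=True)
class MappedRead:
    """A mapped read: 0-based half-open ``[start, end_)`` on ``chrom``."""

    chrom: str
    start: int
    end_: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end_:
            raise ValueError(f"read {self.chrom}:{self.start}-{self.end_}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.chrom}:{self.start}: bad strand {self.strand!r}")


@dataclass
class DyadTrack:
    """Per-chromosome integer dyad tallies with a global rescaling multiplier.

    ``sum(counts) == n_reads`` exactly; ``scale = target_total / n_reads`` is
    the multiplier consumers apply when reading values out.
    """

    counts: dict[str, np.ndarray]
    n_reads: int
    scale: float
    target_total: int
    n_discarded: int = 0

    def scaled(self, chrom: str) -> np.ndarray:
        return self.counts[chrom] * self.scale


def dedup(reads: Sequence[MappedRead]) -> list[MappedRead]:
    """Remove duplicate reads, keeping the first occurrence of each
    (chrom, start, end, strand) tuple; order preserved."""
    seen: set[tuple[str, int, int, str]] = set()
    out: list[MappedRead] = []
    for r in reads:
        key = (r.chrom, r.start, r.end_, r.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def shift_to_dyad(read: MappedRead, shift_bp: int = DEFAULT_SHIFT_BP) -> tuple[str, int]:
    """Shift a read's 5' end ``shift_bp`` bases in its sequencing direction.

    Plus-strand reads sequence rightward from ``start``; minus-strand reads
    sequence leftward from their 5' end at ``end_ - 1``.  The returned dyad
    may be negative for minus-strand reads near a chromosome start; callers
    discard those.
    """
    if read.strand == "+":
        return read.chrom, read.start + shift_bp
    return read.chrom, (read.end_ - 1) - shift_bp


def build_track(
    reads: Sequence[MappedRead],
    chrom_sizes: Mapping[str, int],
    target_total: int = DEFAULT_TARGET_TOTAL,
    shift_bp: int = DEFAULT_SHIFT_BP,
    deduplicate: bool = True,
) -> DyadTrack:
    """Dedup, dyad-shift, and tally reads into a per-base count track.

    Dyads falling off a chromosome (negative, or past the annotated size) are
    discarded and counted in ``n_discarded``.  ``scale`` is set so that the
    retained reads rescale to ``target_total`` fragments.
    """
    for r in reads:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome {r.chrom}")
    if deduplicate:
        reads = dedup(reads)

    counts = {c: np.zeros(size, dtype=np.int64) for c, size in chrom_sizes.items()}
    n_kept = 0
    n_discarded = 0
    # group per chromosome for a vectorised bincount
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        chrom, dyad = shift_to_dyad(r, shift_bp)
        by_chrom.setdefault(chrom, []).append(dyad)
    for chrom, dyads in by_chrom.items():
        arr = np.asarray(dyads, dtype=np.int64)
        ok = (arr >= 0) & (arr < chrom_sizes[chrom])
        n_discarded += int((~ok).sum())
        arr = arr[ok]
        n_kept += len(arr)
        if len(arr):
            counts[chrom] += np.bincount(arr, minlength=chrom_sizes[chrom])
    if n_kept == 0:
        raise ValueError("no reads remain after deduplication and boundary filtering")
    if n_discarded:
        log.info("build_track: discarded %d off-chromosome dyads", n_discarded)
    return DyadTrack(
        counts=counts,
        n_reads=n_kept,
        scale=target_total / n_kept,
        target_total=target_total,
        n_discarded=n_discarded,
    )


# ---------------------------------------------------------------------------
# file I/O


def read_bed_reads(path: str | Path, strand_column: int = 6) -> list[MappedRead]:
    """Read mapped reads from a 6-column BED file (name/score ignored).

    ``strand_column`` is the 1-based column holding the strand, for headerless
    BED variants that put it elsewhere.
    """
    out: list[MappedRead] = []
    sc = strand_column - 1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= sc:
                raise ValueError(f"{path}:{ln}: no strand in column {strand_column}")
            out.append(MappedRead(fields[0], int(fields[1]), int(fields[2]), fields[sc]))
    return out


def write_bed_reads(reads: Iterable[MappedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end_}\tread{i}\t0\t{r.strand}\n")


def write_bedgraph(track: DyadTrack, path: str | Path, scaled: bool = True) -> None:
    """Write the track as bedGraph, collapsing equal-valued runs; zero runs omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            vals = track.counts[chrom]
            nz = np.flatnonzero(vals)
            if not len(nz):
                continue
            # run boundaries: changes in value or gaps in position
            breaks = np.flatnonzero((np.diff(nz) != 1) | (np.diff(vals[nz]) != 0))
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(nz) - 1]])
            for s, e in zip(starts, ends):
                v = vals[nz[s]] * track.scale if scaled else vals[nz[s]]
                fh.write(f"{chrom}\t{nz[s]}\t{nz[e] + 1}\t{v:g}\n")
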