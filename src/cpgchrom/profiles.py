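"""TSS-anchored, strand-oriented metagene profiles.

A :class:`ProfileMatrix` holds per-gene, per-base scaled dyad counts in a
window around the transcription start site, oriented so that position ``+k``
is always ``k`` bases downstream in the direction of transcription.  From it
derive average profiles, loess-smoothed curves with a ~95% (two standard
error) confidence band, nucleosome-background-subtracted modification
profiles, G+C-content profiles, interval-density (e.g. exon-density)
profiles, and expression-ordered heatmap matrices for export.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel, GenomicInterval, _IntervalIndex
from .reads import DyadTrack

log = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "AverageProfile",
    "profile_matrix",
    "average_profile",
    "loess_smooth",
    "background_subtract",
    "gc_profile",
    "interval_density_profile",
    "heatmap_matrix",
    "write_profile_matrix",
    "read_profile_matrix",
    "write_average_profile",
    "read_average_profile",
    "plot_profile",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class ProfileMatrix:
    """Genes x relative-position matrix of (scaled) per-base values.

    ``valid`` is False where a gene's window ran off its chromosome; such
    cells hold 0 and are excluded from averages.
    """

    gene_ids: list[str]
    rel_positions: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.rel_positions)):
            raise ValueError("profile matrix shape mismatch")

    def column(self, rel_pos: int) -> int:
        idx = int(np.searchsorted(self.rel_positions, rel_pos))
        if idx >= len(self.rel_positions) or self.rel_positions[idx] != rel_pos:
            raise KeyError(f"relative position {rel_pos} not in matrix")
        return idx

    def window(self, lo: int, hi: int) -> "ProfileMatrix":
        """Sub-matrix restricted to relative positions ``[lo, hi)``."""
        sel = (self.rel_positions >= lo) & (self.rel_positions < hi)
        return ProfileMatrix(
            gene_ids=list(self.gene_ids),
            rel_positions=self.rel_positions[sel],
            values=self.values[:, sel],
            valid=self.valid[:, sel],
            scale=self.scale,
        )


@dataclass
class AverageProfile:
    """Per-position mean signal with optional smoothed curve and SE band."""

    rel_positions: np.ndarray
    mean: np.ndarray
    smooth: np.ndarray | None = None
    se_band: tuple[np.ndarray, np.ndarray] | None = None
    n_genes: int = 0


def profile_matrix(
    track: DyadTrack,
    genes: Sequence[GeneModel],
    upstream_bp: int = 500,
    downstream_bp: int = 3000,
) -> ProfileMatrix:
    """Collect scaled dyad counts around each TSS, oriented by strand.

    Cell ``(g, k)`` holds ``scale`` times the dyad count at the genomic base
    ``k`` bp downstream of gene ``g``'s TSS in its direction of transcription
    (negative ``k`` is upstream).  Positions off the chromosome are zero and
    flagged invalid; a gene on a chromosome absent from the track gets an
    all-invalid zero row with a warning.
    """
    rel = np.arange(-upstream_bp, downstream_bp + 1)
    n_pos = len(rel)
    values = np.zeros((len(genes), n_pos), dtype=float)
    valid = np.zeros((len(genes), n_pos), dtype=bool)
    for i, g in enumerate(genes):
        if g.chrom not in track.counts:
            log.warning("gene %s: chromosome %s missing from track", g.gene_id, g.chrom)
            continue
        counts = track.counts[g.chrom]
        if g.strand == "+":
            genomic = g.tss + rel
        else:
            genomic = g.tss - rel
        ok = (genomic >= 0) & (genomic < len(counts))
        valid[i] = ok
        values[i, ok] = counts[genomic[ok]] * track.scale
    return ProfileMatrix(
        gene_ids=[g.gene_id for g in genes],
        rel_positions=rel,
        values=values,
        valid=valid,
        scale=track.scale,
    )


def average_profile(matrix: ProfileMatrix) -> AverageProfile:
    """Column means over genes, excluding off-chromosome (invalid) cells."""
    if len(matrix.gene_ids) == 0:
        raise ValueError("cannot average an empty profile matrix")
    n = matrix.valid.sum(axis=0)
    sums = np.where(matrix.valid, matrix.values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return AverageProfile(
        rel_positions=matrix.rel_positions.copy(), mean=mean, n_genes=len(matrix.gene_ids)
    )


# ---------------------------------------------------------------------------
# loess


def _tricube(d: np.ndarray, dmax: float) -> np.ndarray:
    if dmax <= 0:
        return np.ones_like(d, dtype=float)
    u = np.minimum(np.abs(d) / dmax, 1.0)
    return (1.0 - u**3) ** 3


def _hat_vector(d: np.ndarray, degree: int) -> np.ndarray:
    """Row of the linear smoother: fitted value at d=0 as a linear form in y."""
    w = _tricube(d, float(np.max(np.abs(d))))
    X = np.vander(d.astype(float), degree + 1, increasing=True)
    XtW = X.T * w
    beta_map = np.linalg.solve(XtW @ X, XtW)  # (degree+1, span)
    return beta_map[0]


def loess_smooth(
    profile: AverageProfile,
    span_bp: int = 180,
    degree: int = 2,
    band_se: float = 2.0,
) -> AverageProfile:
    """Locally weighted polynomial regression over the position grid.

    Each position's fit uses its ``span_bp`` nearest positions with tricube
    weights and a degree-``degree`` local polynomial.  The confidence band is
    the fit +/- ``band_se`` pointwise standard errors of the linear smoother,
    with the residual variance estimated globally as RSS / (n - tr(L)).
    Returns a new profile with ``smooth`` and ``se_band`` filled.
    """
    if span_bp < 3 * (degree + 1):
        raise ValueError(f"span_bp={span_bp} too small for degree {degree}")
    y = np.asarray(profile.mean, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("profile mean must be finite everywhere before smoothing")
    n = len(y)
    span = min(span_bp, n)
    h1 = (span - 1) // 2

    smooth = np.empty(n)
    l_norm2 = np.empty(n)  # ||l_i||^2 per position
    trace_l = 0.0

    # interior positions share one symmetric window -> one hat vector
    d_int = np.arange(span, dtype=float) - h1
    hat_int = _hat_vector(d_int, degree)
    i_lo, i_hi = h1, n - span + h1  # inclusive range of unclamped centres
    if i_hi >= i_lo:
        smooth[i_lo : i_hi + 1] = np.correlate(y, hat_int, mode="valid")
        l_norm2[i_lo : i_hi + 1] = float(hat_int @ hat_int)
        trace_l += (i_hi - i_lo + 1) * float(hat_int[h1])
    for i in list(range(0, min(i_lo, n))) + list(range(max(i_hi + 1, 0), n)):
        start = int(np.clip(i - h1, 0, n - span))
        d = np.arange(start, start + span, dtype=float) - i
        hat = _hat_vector(d, degree)
        smooth[i] = hat @ y[start : start + span]
        l_norm2[i] = float(hat @ hat)
        trace_l += float(hat[i - start])

    rss = float(np.sum((y - smooth) ** 2))
    dof = max(n - trace_l, 1.0)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * l_norm2)
    return AverageProfile(
        rel_positions=profile.rel_positions.copy(),
        mean=y.copy(),
        smooth=smooth,
        se_band=(smooth - band_se * se, smooth + band_se * se),
        n_genes=profile.n_genes,
    )


# ---------------------------------------------------------------------------
# background subtraction


def _window_sums(values: np.ndarray, window_bp: int) -> np.ndarray:
    """Centered window sums per row, truncated (not wrapped) at the edges."""
    hw = window_bp // 2
    n = values.shape[1]
    cum = np.concatenate(
        [np.zeros((values.shape[0], 1)), np.cumsum(values, axis=1)], axis=1
    )
    j = np.arange(n)
    lo = np.clip(j - hw, 0, n)
    hi = np.clip(j + hw + 1, 0, n)
    return cum[:, hi] - cum[:, lo]


def background_subtract(
    mod_track: DyadTrack,
    nuc_track: DyadTrack,
    genes: Sequence[GeneModel],
    window_bp: int = 75,
    upstream_bp: int = 500,
    downstream_bp: int = 3000,
    band_se: float = 2.0,
) -> AverageProfile:
    """Sliding-window difference between a modification track and nucleosome
    occupancy, averaged over genes.

    Per gene and position, both tracks' scaled dyad counts are summed in a
    centered ``window_bp`` window (sliding 1 bp) and differenced; the result
    is the per-position mean difference across genes with a +/- ``band_se``
    standard-error band under a Normal assumption.  Both tracks must have
    been rescaled to the same target depth.
    """
    if mod_track.target_total != nuc_track.target_total:
        raise ValueError("modification and occupancy tracks rescaled to different totals")
    margin = window_bp // 2
    pm_mod = profile_matrix(mod_track, genes, upstream_bp + margin, downstream_bp + margin)
    pm_nuc = profile_matrix(nuc_track, genes, upstream_bp + margin, downstream_bp + margin)
    diff = _window_sums(pm_mod.values, window_bp) - _window_sums(pm_nuc.values, window_bp)
    diff = diff[:, margin : diff.shape[1] - margin]
    rel = pm_mod.rel_positions[margin : len(pm_mod.rel_positions) - margin]

    mean = diff.mean(axis=0)
    n = diff.shape[0]
    if n < 2:
        log.warning("background_subtract: single gene, standard error undefined")
        se = np.full_like(mean, np.nan)
    else:
        se = diff.std(axis=0, ddof=1) / np.sqrt(n)
    return AverageProfile(
        rel_positions=rel,
        mean=mean,
        smooth=mean.copy(),
        se_band=(mean - band_se * se, mean + band_se * se),
        n_genes=n,
    )


# ---------------------------------------------------------------------------
# sequence-derived profiles


def fetch_sequence(genome, chrom: str, start: int, end_: int) -> str:
    """Fetch ``[start, end_)`` from a genome source (dict of strings or
    pyfaidx.Fasta-like), padding out-of-range flanks with N."""
    left_pad = max(0, -start)
    start = max(start, 0)
    rec = genome[chrom]
    if hasattr(rec, "seq") or not isinstance(rec, str):
        piece = rec[start:end_]
        seq = piece.seq if hasattr(piece, "seq") else str(piece)
    else:
        seq = rec[start:end_]
    right_pad = (end_ - start) - len(seq)
    return "N" * left_pad + seq.upper() + "N" * max(right_pad, 0)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_profile(
    genes: Sequence[GeneModel],
    genome,
    flank_bp: int = 3000,
    window_bp: int = 75,
) -> AverageProfile:
    """Average windowed G+C fraction around the TSS, strand-oriented.

    Per position, the G+C fraction of the centered ``window_bp`` window is
    computed over non-N bases (windows that are entirely N are masked) and
    averaged across genes.
    """
    if not genes:
        raise ValueError("gc_profile requires at least one gene")
    rel = np.arange(-flank_bp, flank_bp + 1)
    hw = window_bp // 2
    total = np.zeros(len(rel))
    n_at = np.zeros(len(rel))
    for g in genes:
        seq = fetch_sequence(genome, g.chrom, g.tss - flank_bp - hw, g.tss + flank_bp + hw + 1)
        if g.strand == "-":
            seq = reverse_complement(seq)
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (codes == ord("G")) | (codes == ord("C"))
        is_base = is_gc | (codes == ord("A")) | (codes == ord("T"))
        cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
        cum_b = np.concatenate([[0], np.cumsum(is_base)])
        j = np.arange(len(rel))
        gc = cum_gc[j + window_bp] - cum_gc[j]
        nb = cum_b[j + window_bp] - cum_b[j]
        ok = nb > 0
        total[ok] += gc[ok] / nb[ok]
        n_at += ok
    with np.errstate(invalid="ignore"):
        mean = np.where(n_at > 0, total / np.maximum(n_at, 1), np.nan)
    return AverageProfile(rel_positions=rel, mean=mean, n_genes=len(genes))


def interval_density_profile(
    genes: Sequence[GeneModel],
    intervals: Sequence[GenomicInterval],
    flank_bp: int = 3000,
) -> AverageProfile:
    """Per oriented position, the fraction of genes covered by >= 1 interval."""
    if not genes:
        raise ValueError("interval_density_profile requires at least one gene")
    rel = np.arange(-flank_bp, flank_bp + 1)
    index = _IntervalIndex(intervals)
    frac = np.zeros(len(rel))
    for g in genes:
        genomic = g.tss + rel if g.strand == "+" else g.tss - rel
        frac += index.coverage_mask(g.chrom, genomic)
    return AverageProfile(rel_positions=rel, mean=frac / len(genes), n_genes=len(genes))


def heatmap_matrix(matrix: ProfileMatrix, order_by: Mapping[str, float]) -> ProfileMatrix:
    """Reorder rows by a per-gene ranking (e.g. expression rank); values untouched.

    Ties are broken stably by gene_id.  Raises if the ranking misses a gene.
    """
    missing = [g for g in matrix.gene_ids if g not in order_by]
    if missing:
        raise ValueError(f"ranking missing genes: {missing[:5]}")
    order = sorted(range(len(matrix.gene_ids)),
                   key=lambda i: (order_by[matrix.gene_ids[i]], matrix.gene_ids[i]))
    return ProfileMatrix(
        gene_ids=[matrix.gene_ids[i] for i in order],
        rel_positions=matrix.rel_positions.copy(),
        values=matrix.values[order],
        valid=matrix.valid[order],
        scale=matrix.scale,
    )


# ---------------------------------------------------------------------------
# file I/O


def write_profile_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write as gzip TSV: first column gene_id, header of relative positions."""
    with gzip.GzipFile(path, "wb", mtime=0) as raw:
        header = "gene_id\t" + "\t".join(str(p) for p in matrix.rel_positions) + "\n"
        raw.write(header.encode())
        for gid, row in zip(matrix.gene_ids, matrix.values):
            raw.write((gid + "\t" + "\t".join(f"{v:g}" for v in row) + "\n").encode())


def read_profile_matrix(path: str | Path) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    return ProfileMatrix(
        gene_ids=[str(g) for g in df.index],
        rel_positions=np.asarray([int(c) for c in df.columns]),
        values=values,
        valid=np.ones_like(values, dtype=bool),
    )


def write_average_profile(profile: AverageProfile, path: str | Path) -> None:
    """Write TSV ``pos mean smooth lo hi`` (empty smooth/band columns if absent)."""
    n = len(profile.rel_positions)
    smooth = profile.smooth if profile.smooth is not None else np.full(n, np.nan)
    lo, hi = profile.se_band if profile.se_band is not None else (
        np.full(n, np.nan), np.full(n, np.nan))
    pd.DataFrame(
        {"pos": profile.rel_positions, "mean": profile.mean,
         "smooth": smooth, "lo": lo, "hi": hi}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_average_profile(path: str | Path) -> AverageProfile:
    df = pd.read_csv(path, sep="\t")
    return AverageProfile(
        rel_positions=df["pos"].to_numpy(),
        mean=df["mean"].to_numpy(dtype=float),
        smooth=df["smooth"].to_numpy(dtype=float),
        se_band=(df["lo"].to_numpy(dtype=float), df["hi"].to_numpy(dtype=float)),
    )


def plot_profile(profiles: Mapping[str, AverageProfile], path: str | Path,
                 title: str = "") -> None:
    """Quick-look PNG of one or more smoothed average profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, p in profiles.items():
        curve = p.smooth if p.smooth is not None else p.mean
        (line,) = ax.plot(p.rel_positions, curve, label=label)
        if p.se_band is not None:
            ax.fill_between(p.rel_positions, p.se_band[0], p.se_band[1],
                            alpha=0.2, color=line.get_color())
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("signal")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
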