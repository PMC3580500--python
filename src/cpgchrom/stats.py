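"""Promoter-level statistics for the CpG / non-CpG comparison.

Three bespoke analyses: (i) promoter asymmetry scores — the fraction of
promoter-proximal dyads falling in the 500 bp upstream of the TSS — compared
between gene classes with a Wilcoxon rank-sum (or, for matched pairs,
signed-rank) test; (ii) per-gene modification peak positions within 2 kb
downstream of the TSS correlated with expression rank (Spearman); and
(iii) CTCF-overlap fractions in ten expression bins per class with Wilson
binomial confidence intervals and an overall chi-squared test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .annotations import IslandClass
from .profiles import ProfileMatrix, _window_sums

log = logging.getLogger(__name__)

__all__ = [
    "AsymmetryResult",
    "PeakShiftResult",
    "OverlapEnrichment",
    "asymmetry_score",
    "compare_asymmetry",
    "peak_positions",
    "peak_shift_correlation",
    "ctcf_enrichment",
    "wilson_interval",
]


@dataclass
class AsymmetryResult:
    per_gene: dict[str, float]
    dropped: list[str]
    group_test: tuple[float, float] | None = None


@dataclass
class PeakShiftResult:
    per_gene: dict[str, int]
    rho: float
    p_value: float
    dropped: list[str] = field(default_factory=list)


@dataclass
class OverlapEnrichment:
    """Per-expression-bin overlap fractions for each class, plus a 2x2 test."""

    per_bin: list[dict]
    chi2: float
    chi2_p: float
    table: list[list[int]]


# ---------------------------------------------------------------------------
# asymmetry


def asymmetry_score(matrix: ProfileMatrix, half_window_bp: int = 500) -> AsymmetryResult:
    """Upstream-read fraction per gene within +/- ``half_window_bp`` of the TSS.

    The score is the dyad-count sum over ``[-half_window_bp, 0)`` divided by
    the sum over ``[-half_window_bp, +half_window_bp)``; the TSS base itself
    counts as downstream.  Genes with no reads in the window are excluded and
    reported in ``dropped``.
    """
    sub = matrix.window(-half_window_bp, half_window_bp)
    if len(sub.rel_positions) != 2 * half_window_bp:
        raise ValueError("profile matrix does not cover the full +/- window")
    upstream = sub.values[:, sub.rel_positions < 0].sum(axis=1)
    total = sub.values.sum(axis=1)
    per_gene: dict[str, float] = {}
    dropped: list[str] = []
    for gid, up, tot in zip(sub.gene_ids, upstream, total):
        if tot > 0:
            per_gene[gid] = float(up / tot)
        else:
            dropped.append(gid)
    if dropped:
        log.info("asymmetry_score: %d genes with no promoter-proximal reads", len(dropped))
    return AsymmetryResult(per_gene=per_gene, dropped=dropped)


def _ranksum_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test via the tie-corrected normal approximation."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 0.0, 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def compare_asymmetry(
    cpg_scores: Sequence[float],
    noncpg_scores: Sequence[float],
    paired: bool = False,
    max_exact_n: int = 8,
) -> tuple[float, float]:
    """Compare asymmetry-score distributions between gene classes.

    Default is the two-sided Wilcoxon rank-sum (Mann-Whitney) test with tie
    correction; small tie-free groups use the exact null distribution.  With
    ``paired=True`` the Wilcoxon signed-rank test is run instead on
    expression-matched pairs (the two inputs must then align).
    """
    x = np.asarray(cpg_scores, dtype=float)
    y = np.asarray(noncpg_scores, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two scores")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length, aligned groups")
        if np.all(x == y):
            return 0.0, 1.0
        res = sps.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    if no_ties and max(len(x), len(y)) <= max_exact_n:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    return _ranksum_asymptotic(x, y)


# ---------------------------------------------------------------------------
# peak shift


def peak_positions(
    matrix: ProfileMatrix,
    search_bp: int = 2000,
    smooth_window_bp: int = 0,
) -> tuple[dict[str, int], list[str]]:
    """Leftmost argmax of each gene's row over ``[0, search_bp]`` inclusive.

    ``smooth_window_bp`` > 0 applies a centered moving-window sum to each row
    first; single-base argmax on sparse rows is noisy, so smoothing is
    recommended for low-coverage data.  All-zero rows are excluded and
    returned in the dropped list.
    """
    sel = (matrix.rel_positions >= 0) & (matrix.rel_positions <= search_bp)
    if matrix.rel_positions[sel][0] != 0 or matrix.rel_positions[sel][-1] != search_bp:
        raise ValueError("profile matrix does not cover [0, search_bp]")
    rows = matrix.values[:, sel]
    if smooth_window_bp > 1:
        rows = _window_sums(rows, smooth_window_bp)
    positions = matrix.rel_positions[sel]
    peaks: dict[str, int] = {}
    dropped: list[str] = []
    for gid, row in zip(matrix.gene_ids, rows):
        if not row.any():
            dropped.append(gid)
            continue
        peaks[gid] = int(positions[int(np.argmax(row))])
    return peaks, dropped


def peak_shift_correlation(
    peaks: Mapping[str, int], expr_ranks: Mapping[str, float]
) -> tuple[float, float]:
    """Spearman correlation between peak position and expression rank.

    Uses genes present in both mappings; requires >= 3.  A constant peak
    vector has no defined correlation and returns (nan, nan).
    """
    common = [g for g in peaks if g in expr_ranks]
    if len(common) < 3:
        raise ValueError("peak-shift correlation requires >= 3 genes with both values")
    p = np.asarray([peaks[g] for g in common], dtype=float)
    e = np.asarray([expr_ranks[g] for g in common], dtype=float)
    if np.all(p == p[0]) or np.all(e == e[0]):
        log.warning("peak_shift_correlation: constant input, correlation undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(p, e)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# CTCF overlap enrichment


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    z = sps.norm.ppf(0.5 + conf / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def ctcf_enrichment(
    gene_classes: Mapping[str, IslandClass],
    overlaps: Mapping[str, bool],
    expr_ranks: Mapping[str, float],
    n_bins: int = 10,
) -> OverlapEnrichment:
    """Per-expression-bin CTCF-overlap fractions for CpG vs non-CpG promoters.

    Each class is split independently into ``n_bins`` equally sized expression
    bins (sizes differ by at most 1, remainder to the lowest bins); per bin
    the overlap fraction and its 95% Wilson interval are reported.  The
    overall 2x2 class-by-overlap table is tested with a chi-squared test
    without continuity correction.
    """
    per_class: dict[str, list[str]] = {"CPG": [], "NONCPG": []}
    for gid, cls in gene_classes.items():
        if gid in overlaps and gid in expr_ranks:
            per_class[IslandClass(cls).value].append(gid)
    for cls, ids in per_class.items():
        ids.sort(key=lambda g: (expr_ranks[g], g))

    bins: dict[str, list[list[str]]] = {
        cls: [list(chunk) for chunk in np.array_split(np.asarray(ids, dtype=object), n_bins)]
        for cls, ids in per_class.items()
    }
    per_bin: list[dict] = []
    for b in range(n_bins):
        entry: dict = {"bin": b + 1}
        for cls, key in (("CPG", "cpg"), ("NONCPG", "noncpg")):
            ids = bins[cls][b]
            n = len(ids)
            k = sum(bool(overlaps[g]) for g in ids)
            if n == 0:
                entry[f"fraction_{key}"] = float("nan")
                entry[f"ci_{key}"] = (float("nan"), float("nan"))
                entry[f"n_{key}"] = 0
            else:
                entry[f"fraction_{key}"] = k / n
                entry[f"ci_{key}"] = wilson_interval(k, n)
                entry[f"n_{key}"] = n
        per_bin.append(entry)

    table = []
    for cls in ("CPG", "NONCPG"):
        k = sum(bool(overlaps[g]) for g in per_class[cls])
        table.append([k, len(per_class[cls]) - k])
    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        # no variation in overlap (or an empty class): independence is vacuous
        log.info("ctcf_enrichment: degenerate 2x2 table %s", table)
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return OverlapEnrichment(per_bin=per_bin, chi2=float(chi2), chi2_p=float(p), table=table)
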