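"""Expression ranking, tiering, and expression-matched gene-set construction.

Genes are ranked by linear-scale expression, split into equally sized tiers
(low / medium / high by default), and CpG / non-CpG promoter gene sets are
built by sampling non-CpG genes and greedily pairing each with the unused CpG
gene of most similar log expression, accepting a pair only when
``|ln(expr_noncpg) - ln(expr_cpg)| <= 0.1``.  Matching controls for the
strong influence of transcription on chromatin so that residual profile
differences can be attributed to promoter type.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionRecord",
    "MatchedGeneSets",
    "rank_records",
    "tier_split",
    "sample_matched",
    "collapse_probes",
    "read_expression_table",
    "write_matched_sets",
    "read_matched_sets",
]

TIER_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene linear-scale expression with its rank (1 = lowest)."""

    gene_id: str
    expr: float
    rank: int = 0

    def __post_init__(self) -> None:
        if not self.expr > 0:
            raise ValueError(f"gene {self.gene_id}: expression must be positive")

    @property
    def ln_expr(self) -> float:
        return float(np.log(self.expr))


@dataclass
class MatchedGeneSets:
    """Expression-matched CpG / non-CpG pairs per tier.

    ``tiers`` maps tier label to a list of
    ``(noncpg_gene_id, cpg_gene_id, abs_delta_ln_expr)`` triples.
    """

    tiers: dict[str, list[tuple[str, str, float]]]
    seed: int
    tolerance: float

    def all_pairs(self) -> list[tuple[str, str, str, float]]:
        return [(t, a, b, d) for t in self.tiers for a, b, d in self.tiers[t]]

    def gene_ids(self, which: str) -> list[str]:
        """All gene ids on one side (``"noncpg"`` or ``"cpg"``), tiers concatenated."""
        col = 0 if which == "noncpg" else 1
        return [trip[col] for t in self.tiers for trip in self.tiers[t]]


def rank_records(records: Sequence[ExpressionRecord]) -> list[ExpressionRecord]:
    """Assign ranks 1..N by increasing expression, ties broken by gene_id."""
    ordered = sorted(records, key=lambda r: (r.expr, r.gene_id))
    return [ExpressionRecord(r.gene_id, r.expr, i + 1) for i, r in enumerate(ordered)]


def tier_split(
    records: Sequence[ExpressionRecord], n_tiers: int = 3
) -> dict[str, str]:
    """Split genes into expression tiers of equal size (remainder to the lowest).

    Returns a mapping gene_id -> tier label; labels are ``low/medium/high``
    for three tiers, ``tier1..tierN`` otherwise.  Membership is monotone in
    rank.
    """
    if len(records) < n_tiers:
        raise ValueError(f"cannot split {len(records)} genes into {n_tiers} tiers")
    labels = TIER_LABELS if n_tiers == 3 else tuple(f"tier{i+1}" for i in range(n_tiers))
    ranked = rank_records(records)
    base, rem = divmod(len(ranked), n_tiers)
    sizes = [base + (rem if i == 0 else 0) for i in range(n_tiers)]
    out: dict[str, str] = {}
    pos = 0
    for label, size in zip(labels, sizes):
        for r in ranked[pos : pos + size]:
            out[r.gene_id] = label
        pos += size
    return out


class _NearestPool:
    """Sorted candidate values supporting nearest-unused queries with removal."""

    def __init__(self, records: Sequence[ExpressionRecord]):
        ordered = sorted(records, key=lambda r: (r.ln_expr, r.gene_id))
        self.values = [r.ln_expr for r in ordered]
        self.ids = [r.gene_id for r in ordered]
        self.used = [False] * len(ordered)
        self.n_free = len(ordered)

    def take_nearest(self, x: float, tol: float) -> tuple[str, float] | None:
        if self.n_free == 0:
            return None
        n = len(self.values)
        i = bisect_left(self.values, x)
        lo, hi = i - 1, i
        best: int | None = None
        best_d = np.inf
        # walk outward from the insertion point, skipping used entries
        while lo >= 0 or hi < n:
            d_lo = x - self.values[lo] if lo >= 0 else np.inf
            d_hi = self.values[hi] - x if hi < n else np.inf
            d = min(d_lo, d_hi)
            if d >= best_d:
                break
            if d_lo <= d_hi:
                j, lo = lo, lo - 1
            else:
                j, hi = hi, hi + 1
            if not self.used[j]:
                best, best_d = j, d
        if best is None or best_d > tol:
            return None
        self.used[best] = True
        self.n_free -= 1
        return self.ids[best], best_d


def sample_matched(
    noncpg: Sequence[ExpressionRecord],
    cpg: Sequence[ExpressionRecord],
    per_tier: int = 500,
    tolerance_ln: float = 0.1,
    seed: int = 0,
    n_tiers: int = 3,
) -> MatchedGeneSets:
    """Build expression-matched CpG / non-CpG gene sets per expression tier.

    Tiers come from :func:`tier_split` on the pooled ranking of both classes.
    Within each tier, non-CpG genes are drawn uniformly without replacement
    (seeded) and each is greedily paired with the unused same-tier CpG gene of
    nearest log expression; a pair is accepted only if the absolute log-
    expression difference is at most ``tolerance_ln``.  Unmatched draws are
    replaced by fresh ones until ``per_tier`` pairs exist or the tier is
    exhausted, mirroring the removal of genes with extreme expression for
    which no similarly expressed partner of the other class exists.
    """
    pooled = list(noncpg) + list(cpg)
    if len(set(r.gene_id for r in pooled)) != len(pooled):
        raise ValueError("duplicate gene_id across expression records")
    tiers = tier_split(pooled, n_tiers)
    labels = TIER_LABELS if n_tiers == 3 else tuple(f"tier{i+1}" for i in range(n_tiers))

    rng = np.random.default_rng(seed)
    result: dict[str, list[tuple[str, str, float]]] = {}
    for label in labels:
        nc_pool = sorted(
            (r for r in noncpg if tiers[r.gene_id] == label), key=lambda r: r.gene_id
        )
        cpg_pool = [r for r in cpg if tiers[r.gene_id] == label]
        pool = _NearestPool(cpg_pool)
        order = rng.permutation(len(nc_pool))
        pairs: list[tuple[str, str, float]] = []
        for idx in order:
            if len(pairs) >= per_tier:
                break
            rec = nc_pool[idx]
            hit = pool.take_nearest(rec.ln_expr, tolerance_ln)
            if hit is not None:
                pairs.append((rec.gene_id, hit[0], hit[1]))
        if len(pairs) < per_tier:
            log.warning(
                "tier %s: only %d of %d requested matched pairs", label, len(pairs), per_tier
            )
        result[label] = pairs
    return MatchedGeneSets(tiers=result, seed=seed, tolerance=tolerance_ln)


def collapse_probes(
    probe_values: Mapping[str, float], probe_to_gene: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Collapse probe-level values to genes.

    Probes mapping to multiple genes are discarded; each gene keeps the value
    of its most sensitive probe, interpreted as the maximum replicate-averaged
    probe value.
    """
    out: dict[str, float] = {}
    for probe, value in probe_values.items():
        genes = probe_to_gene.get(probe, ())
        if len(genes) != 1:
            continue
        g = genes[0]
        if g not in out or value > out[g]:
            out[g] = value
    return out


# ---------------------------------------------------------------------------
# file I/O


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a tab-delimited ``gene_id expr`` table (linear-scale values)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "expr" not in df.columns:
        raise ValueError(f"expression table {path} must have columns gene_id, expr")
    return rank_records(
        [ExpressionRecord(r.gene_id, float(r.expr)) for r in df.itertuples(index=False)]
    )


def write_matched_sets(sets_: MatchedGeneSets, path: str | Path) -> None:
    rows = [(t, a, b, f"{d:.6f}") for t, a, b, d in sets_.all_pairs()]
    pd.DataFrame(rows, columns=["tier", "noncpg_id", "cpg_id", "delta_ln"]).to_csv(
        path, sep="\t", index=False
    )


def read_matched_sets(path: str | Path, seed: int = -1, tolerance: float = 0.1) -> MatchedGeneSets:
    df = pd.read_csv(path, sep="\t", dtype={"noncpg_id": str, "cpg_id": str})
    tiers: dict[str, list[tuple[str, str, float]]] = {}
    for row in df.itertuples(index=False):
        tiers.setdefault(row.tier, []).append((row.noncpg_id, row.cpg_id, float(row.delta_ln)))
    return MatchedGeneSets(tiers=tiers, seed=seed, tolerance=tolerance)
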