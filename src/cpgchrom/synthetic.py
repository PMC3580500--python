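"""Synthetic genomes, gene sets, expression, and chromatin reads.

Generates miniature datasets with the statistical structure the analysis
assumes: isolated genes >= 3 kb on alternating strands, CpG islands over a
designated fraction of promoters, CpG-rich (HCP) versus CpG-poor (LCP)
promoter sequences from first-order Markov chains, heavy-tailed (lognormal)
expression independent of promoter class, and mapped reads drawn from
parameterised nucleosome-occupancy and modification-placement models
(uniform background, phased nucleosome array, nucleosome-depleted region,
expression-tier-dependent gene-body modification peak, asymmetric promoter
peaks).  Every stage of the pipeline is thereby testable without downloads.

All randomness flows from a single seed through spawned per-component and
per-gene substreams, so regenerating one track or one gene is stable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    GeneModel,
    GenomicInterval,
    IslandClass,
    WeberClass,
    classify_weber,
)
from .expression import ExpressionRecord, rank_records
from .reads import MappedRead
from .profiles import reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "ChromatinModel",
    "SyntheticData",
    "make_genes",
    "simulate_reads",
    "default_models",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# first-order Markov transition rows (A, C, G, T): CpG-rich promoters have
# elevated GC and a high C->G transition; CpG-poor promoters suppress C->G.
_TRANS_CPG_RICH = np.array(
    [
        [0.20, 0.30, 0.30, 0.20],
        [0.15, 0.25, 0.40, 0.20],
        [0.20, 0.30, 0.30, 0.20],
        [0.20, 0.30, 0.30, 0.20],
    ]
)
_TRANS_CPG_POOR = np.array(
    [
        [0.30, 0.20, 0.20, 0.30],
        [0.40, 0.24, 0.02, 0.34],
        [0.30, 0.20, 0.20, 0.30],
        [0.30, 0.20, 0.20, 0.30],
    ]
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    ``gene_spacing_bp`` minus ``gene_length_bp`` must leave more than the
    isolation margin so that ``filter_genes`` retains every gene;
    ``fragment_len_bp`` defaults to 151 so a 75 bp shift recovers the dyad
    from either strand.
    """

    n_genes: int = 200
    frac_cpg: float = 0.5
    gene_length_bp: int = 5000
    gene_spacing_bp: int = 9500
    margin_bp: int = 4000
    expression_lognormal: tuple[float, float] = (5.0, 1.5)
    read_depth: float = 50.0
    fragment_len_bp: int = 151
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.gene_spacing_bp - self.gene_length_bp < 1500:
            raise ValueError("gene spacing leaves less than 1.5 kb between genes")
        if self.fragment_len_bp < 1:
            raise ValueError("fragment length must be positive")
        if not 0 <= self.frac_cpg <= 1:
            raise ValueError("frac_cpg must be in [0, 1]")

    @property
    def chrom_length_bp(self) -> int:
        return 2 * self.margin_bp + self.n_genes * self.gene_spacing_bp


@dataclass
class SyntheticData:
    """Everything :func:`make_genes` produces, plus lookup tables."""

    genes: list[GeneModel]
    islands: list[GenomicInterval]
    promoters: dict[str, str]
    expression: list[ExpressionRecord]
    genome: dict[str, str]
    island_classes: dict[str, IslandClass]
    config: SyntheticConfig


@dataclass(frozen=True)
class ChromatinModel:
    """Per-gene dyad placement rates in a strand-oriented TSS window.

    The rate over ``window`` mixes a uniform background, a phased Gaussian
    nucleosome array starting ``nuc_first_bp`` downstream with ``nuc_spacing_bp``
    periodicity, a nucleosome-depleted-region multiplier over ``ndr_window``
    (constitutive for CpG promoters, gated to ``ndr_gate_tiers`` for non-CpG),
    an expression-tier-dependent gene-body modification peak, and a pair of
    promoter-proximal peaks whose upstream weight ``w_up`` sets the promoter
    asymmetry.  Component masses are chosen so a typical gene's rate sums to
    about 1; the expected read count per gene is ``read_depth`` times the
    rate mass.
    """

    name: str = "model"
    window: tuple[int, int] = (-1000, 3000)
    background_mass: float = 0.1
    nuc_mass: float = 0.0
    nuc_first_bp: int = 50
    nuc_spacing_bp: int = 185
    nuc_sigma_bp: float = 40.0
    n_nucleosomes: int = 12
    ndr_depth: float = 1.0
    ndr_window: tuple[int, int] = (-200, 0)
    ndr_gate_tiers: tuple[str, ...] = ("high",)
    mod_sigma_bp: float = 150.0
    mod_center: Mapping[str, Mapping[str, float]] | None = None  # class -> tier -> bp
    mod_mass: Mapping[str, float] | None = None  # tier -> mass
    prom_offset_bp: int = 250
    prom_sigma_bp: float = 75.0
    prom_mass: float = 0.0
    w_up: float = 0.5
    w_up_noncpg: float | None = None  # None: same weight for both classes
    spike_at: int | None = None

    def positions(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)

    def rate(self, island_class: IslandClass, tier: str) -> np.ndarray:
        pos = self.positions().astype(float)
        n = len(pos)
        r = np.full(n, self.background_mass / n)
        if self.spike_at is not None:
            r = np.zeros(n)
            r[int(self.spike_at - self.window[0])] = 1.0
            return r
        if self.nuc_mass > 0:
            per = self.nuc_mass / self.n_nucleosomes
            for k in range(self.n_nucleosomes):
                c = self.nuc_first_bp + k * self.nuc_spacing_bp
                r += per * _gauss(pos, c, self.nuc_sigma_bp)
        if self.ndr_depth != 1.0:
            gated = (
                IslandClass(island_class) == IslandClass.CPG
                or tier in self.ndr_gate_tiers
            )
            if gated:
                inside = (pos >= self.ndr_window[0]) & (pos < self.ndr_window[1])
                r[inside] *= self.ndr_depth
        if self.mod_center is not None:
            centers = self.mod_center[IslandClass(island_class).value]
            mass = (self.mod_mass or {}).get(tier, 1.0)
            r += mass * _gauss(pos, float(centers[tier]), self.mod_sigma_bp)
        if self.prom_mass > 0:
            w = self.w_up
            if self.w_up_noncpg is not None and IslandClass(island_class) != IslandClass.CPG:
                w = self.w_up_noncpg
            r += self.prom_mass * w * _gauss(pos, -self.prom_offset_bp, self.prom_sigma_bp)
            r += self.prom_mass * (1 - w) * _gauss(pos, self.prom_offset_bp, self.prom_sigma_bp)
        return r


def _gauss(pos: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Discretised unit-mass Gaussian over the window."""
    w = np.exp(-0.5 * ((pos - center) / sigma) ** 2)
    return w / (sigma * math.sqrt(2 * math.pi))


def default_models() -> dict[str, ChromatinModel]:
    """The standard synthetic track set: occupancy plus three marks.

    ``occupancy``: phased nucleosomes with a constitutive (CpG) or
    expression-gated (non-CpG) NDR.  ``mark_shift``: gene-body peak whose
    center moves downstream with expression tier (500/800/1100 bp for CpG
    genes, flatter and more distal for non-CpG).  ``mark_asym``: promoter
    dual peak with 0.7 of its mass upstream for CpG genes.  ``mark_body``:
    elongation-type mark peaking earlier in CpG gene bodies.
    """
    return {
        "occupancy": ChromatinModel(
            name="occupancy",
            background_mass=0.3,
            nuc_mass=0.7,
            ndr_depth=0.15,
        ),
        "mark_shift": ChromatinModel(
            name="mark_shift",
            background_mass=0.15,
            mod_center={
                "CPG": {"low": 500.0, "medium": 800.0, "high": 1100.0},
                "NONCPG": {"low": 900.0, "medium": 1200.0, "high": 1500.0},
            },
            mod_mass={"low": 0.4, "medium": 0.8, "high": 1.6},
            mod_sigma_bp=150.0,
        ),
        "mark_asym": ChromatinModel(
            name="mark_asym",
            background_mass=0.05,
            prom_mass=1.0,
            w_up=0.7,
            w_up_noncpg=0.45,
            prom_offset_bp=250,
            prom_sigma_bp=75.0,
        ),
        "mark_body": ChromatinModel(
            name="mark_body",
            background_mass=0.15,
            mod_center={
                "CPG": {"low": 1000.0, "medium": 1000.0, "high": 1000.0},
                "NONCPG": {"low": 2200.0, "medium": 2200.0, "high": 2200.0},
            },
            mod_mass={"low": 0.3, "medium": 0.9, "high": 1.8},
            mod_sigma_bp=400.0,
        ),
    }


# ---------------------------------------------------------------------------
# sequence synthesis


def _markov_seq(rng: np.random.Generator, length: int, trans: np.ndarray) -> np.ndarray:
    """Sample a base-code sequence (0..3) from a first-order Markov chain."""
    cum = np.cumsum(trans, axis=1)
    out = np.empty(length, dtype=np.int64)
    # stationary-ish start: draw from the A row
    state = int(np.searchsorted(cum[0], rng.random(), side="right"))
    out[0] = state
    u = rng.random(length - 1)
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i - 1], side="right"))
        out[i] = state
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _sample_promoter(
    rng: np.random.Generator, cpg_rich: bool, max_tries: int = 25
) -> str:
    """Draw a 1,500 bp promoter sequence of the requested class.

    Resamples (up to ``max_tries``) until the windowed CpG scan classifies it
    as HCP (CpG-rich) or LCP (CpG-poor), so generated classes are consistent
    with the classifier's contract.
    """
    trans = _TRANS_CPG_RICH if cpg_rich else _TRANS_CPG_POOR
    want = WeberClass.HCP if cpg_rich else WeberClass.LCP
    seq = ""
    for _ in range(max_tries):
        seq = _codes_to_str(_markov_seq(rng, 1500, trans))
        if classify_weber(seq, step_bp=5) is want:
            return seq
    log.warning("promoter sampler: classification target not reached, keeping last draw")
    return seq


def make_genes(config: SyntheticConfig) -> SyntheticData:
    """Generate a complete miniature gene annotation set.

    Genes alternate strand along one chromosome, spaced so none is removed by
    the length/isolation filter.  A CpG island of 500-1,500 bp is centred on
    each designated CpG promoter's TSS; CpG promoters carry CpG-rich (HCP)
    sequence and the rest CpG-poor (LCP) sequence, spliced into an otherwise
    i.i.d. 40%-GC background chromosome.  Expression is lognormal and
    independent of promoter class.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_islands, rng_expr, rng_bg, rng_prom = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        left = config.margin_bp + i * config.gene_spacing_bp
        right = left + config.gene_length_bp
        if i % 2 == 0:
            g = GeneModel(f"g{i:04d}", config.chrom, "+", left, right)
        else:
            g = GeneModel(f"g{i:04d}", config.chrom, "-", right, left)
        genes.append(g)

    n_cpg = round(config.n_genes * config.frac_cpg)
    cpg_idx = set(rng_labels.permutation(config.n_genes)[:n_cpg].tolist())
    island_classes = {
        g.gene_id: (IslandClass.CPG if i in cpg_idx else IslandClass.NONCPG)
        for i, g in enumerate(genes)
    }

    islands: list[GenomicInterval] = []
    for i, g in enumerate(genes):
        if i in cpg_idx:
            half = int(rng_islands.integers(250, 751))
            islands.append(
                GenomicInterval(g.chrom, max(0, g.tss - half), g.tss + half)
            )

    # background chromosome: i.i.d. with 40% GC
    bg_codes = rng_bg.choice(4, size=config.chrom_length_bp, p=[0.3, 0.2, 0.2, 0.3])
    chrom_codes = bg_codes.astype(np.uint8)

    promoters: dict[str, str] = {}
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on codes
    for i, g in enumerate(genes):
        seq = _sample_promoter(rng_prom, cpg_rich=(i in cpg_idx))
        promoters[g.gene_id] = seq
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        codes = np.searchsorted(_BASES, codes).astype(np.uint8)
        if g.strand == "+":
            chrom_codes[g.tss - 1200 : g.tss + 300] = codes
        else:
            chrom_codes[g.tss - 299 : g.tss + 1201] = comp[codes][::-1]
    genome = {config.chrom: _codes_to_str(chrom_codes.astype(np.int64))}

    mu, sigma = config.expression_lognormal
    expr_vals = rng_expr.lognormal(mean=mu, sigma=sigma, size=config.n_genes)
    expression = rank_records(
        [ExpressionRecord(g.gene_id, float(v)) for g, v in zip(genes, expr_vals)]
    )
    return SyntheticData(
        genes=genes,
        islands=islands,
        promoters=promoters,
        expression=expression,
        genome=genome,
        island_classes=island_classes,
        config=config,
    )


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genes: Sequence[GeneModel],
    model: ChromatinModel,
    config: SyntheticConfig,
    tiers: Mapping[str, str],
    island_classes: Mapping[str, IslandClass],
    seed: int,
) -> list[MappedRead]:
    """Draw mapped reads whose dyads follow the model's per-gene rate.

    Each gene's read total is Poisson with mean ``read_depth`` times its rate
    mass; dyad offsets are drawn from the normalised rate, mapped back to
    genomic coordinates through the gene's strand, and emitted as
    ``fragment_len_bp`` reads on a uniformly random strand, positioned so
    that a ``(fragment_len_bp - 1) // 2`` shift recovers the dyad exactly.
    """
    place_shift = (config.fragment_len_bp - 1) // 2
    lo = model.window[0]

    cache: dict[tuple[str, str], tuple[np.ndarray, float]] = {}

    def cdf_for(cls: IslandClass, tier: str) -> tuple[np.ndarray, float]:
        key = (IslandClass(cls).value, tier)
        if key not in cache:
            r = model.rate(cls, tier)
            mass = float(r.sum())
            cache[key] = (np.cumsum(r) / mass, mass)
        return cache[key]

    gene_streams = np.random.SeedSequence(seed).spawn(len(genes))
    reads: list[MappedRead] = []
    for g, child in zip(genes, gene_streams):
        rng = np.random.default_rng(child)
        cdf, mass = cdf_for(island_classes[g.gene_id], tiers[g.gene_id])
        n = rng.poisson(config.read_depth * mass)
        if n == 0:
            continue
        rel = lo + np.searchsorted(cdf, rng.random(n), side="right")
        dyads = g.tss + rel if g.strand == "+" else g.tss - rel
        minus = rng.random(n) < 0.5
        for dyad, is_minus in zip(dyads, minus):
            if is_minus:
                end_ = int(dyad) + place_shift + 1
                start = end_ - config.fragment_len_bp
            else:
                start = int(dyad) - place_shift
                end_ = start + config.fragment_len_bp
            if start < 0:
                continue
            reads.append(MappedRead(g.chrom, start, end_, "-" if is_minus else "+"))
    return reads
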