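"""Metagene profile construction, loess smoothing, and derived profiles."""
import shutil
import subprocess

import numpy as np
import pytest

from cpgchrom.annotations import GeneModel, GenomicInterval
from cpgchrom.profiles import (
    AverageProfile,
    ProfileMatrix,
    average_profile,
    background_subtract,
    gc_profile,
    heatmap_matrix,
    interval_density_profile,
    loess_smooth,
    profile_matrix,
    read_average_profile,
    read_profile_matrix,
    write_average_profile,
    write_profile_matrix,
)
from cpgchrom.reads import DyadTrack, MappedRead, build_track


def track_from_dyads(dyads, size=20_000, chrom="chr1", target=None):
    counts = np.zeros(size, dtype=np.int64)
    for d in dyads:
        counts[d] += 1
    n = int(counts.sum())
    target = target if target is not None else n
    return DyadTrack({chrom: counts}, n_reads=n, scale=target / n, target_total=target)


# ---------------------------------------------------------------------------
# profile_matrix


def test_profile_matrix_orientation():
    plus = GeneModel("p", "chr1", "+", 1000, 6000)
    minus = GeneModel("m", "chr1", "-", 6000, 1000)
    track = track_from_dyads([1010, 5990])
    pm = profile_matrix(track, [plus, minus], upstream_bp=100, downstream_bp=100)
    col = pm.column(10)
    assert pm.values[0, col] == pytest.approx(1 * track.scale)  # plus: tss+10
    assert pm.values[1, col] == pytest.approx(1 * track.scale)  # minus: tss-10
    # dyads outside the window contribute nowhere
    far = track_from_dyads([1000 + 5000])
    pm2 = profile_matrix(far, [plus], upstream_bp=500, downstream_bp=3000)
    assert pm2.values.sum() == 0


def test_profile_matrix_missing_chromosome_gives_zero_row(caplog):
    g = GeneModel("g", "chrZ", "+", 1000, 6000)
    track = track_from_dyads([50])
    pm = profile_matrix(track, [g], 100, 100)
    assert pm.values.sum() == 0
    assert not pm.valid.any()


def test_profile_matrix_mass_conservation(rng):
    genes = [GeneModel("a", "chr1", "+", 2000, 8000), GeneModel("b", "chr1", "-", 9000, 3000)]
    dyads = rng.integers(0, 12_000, size=2000)
    track = track_from_dyads(dyads, size=12_000, target=10_000)
    pm = profile_matrix(track, genes, 500, 3000)
    counts = np.bincount(dyads, minlength=12_000)
    for i, g in enumerate(genes):
        if g.strand == "+":
            window = counts[g.tss - 500 : g.tss + 3001]
        else:
            window = counts[g.tss - 3000 : g.tss + 501]
        assert pm.values[i].sum() == pytest.approx(track.scale * window.sum())


def test_strand_mirroring_leaves_profiles_invariant(rng):
    """Reverse-complementing the genome (coordinates reflected, strands and
    dyads flipped) must not change sense-oriented profiles."""
    size = 30_000
    genes = [
        GeneModel("a", "chr1", "+", 5000, 11_000),
        GeneModel("b", "chr1", "-", 25_000, 18_000),
    ]
    dyads = rng.integers(1000, size - 1000, size=3000)
    mirror_genes = []
    for g in genes:
        strand = "-" if g.strand == "+" else "+"
        mirror_genes.append(
            GeneModel(g.gene_id, g.chrom, strand, size - 1 - g.tss, size - 1 - g.end_)
        )
    t1 = track_from_dyads(dyads, size=size)
    t2 = track_from_dyads(size - 1 - dyads, size=size)
    pm1 = profile_matrix(t1, genes, 500, 3000)
    pm2 = profile_matrix(t2, mirror_genes, 500, 3000)
    assert np.array_equal(pm1.values / t1.scale, pm2.values / t2.scale)


# ---------------------------------------------------------------------------
# averages and loess


def test_average_profile_examples():
    pm = ProfileMatrix(["a", "b"], np.array([0, 1]), np.array([[1.0, 3.0], [3.0, 1.0]]),
                       np.ones((2, 2), dtype=bool))
    assert np.allclose(average_profile(pm).mean, [2.0, 2.0])
    single = ProfileMatrix(["a"], np.array([0, 1]), np.array([[4.0, 7.0]]),
                           np.ones((1, 2), dtype=bool))
    assert np.allclose(average_profile(single).mean, [4.0, 7.0])
    with pytest.raises(ValueError):
        average_profile(ProfileMatrix([], np.array([0]), np.zeros((0, 1)),
                                      np.zeros((0, 1), dtype=bool)))


def test_average_profile_matches_column_mean(rng):
    values = rng.poisson(3.0, size=(100, 50)).astype(float)
    pm = ProfileMatrix([f"g{i}" for i in range(100)], np.arange(50), values,
                       np.ones_like(values, dtype=bool))
    assert np.allclose(average_profile(pm).mean, values.mean(axis=0))


def test_loess_constant_linear_spike():
    n = 400
    const = loess_smooth(AverageProfile(np.arange(n), np.full(n, 2.5), n_genes=1))
    assert np.allclose(const.smooth, 2.5, atol=1e-9)
    assert np.allclose(const.se_band[1] - const.smooth, 0.0, atol=1e-9)
    lin = loess_smooth(AverageProfile(np.arange(n), 0.7 * np.arange(n) - 3, n_genes=1))
    assert np.max(np.abs(lin.smooth - lin.mean)) <= 1e-6 * np.max(np.abs(lin.mean))
    spike = np.zeros(n)
    spike[137] = 1.0
    sm = loess_smooth(AverageProfile(np.arange(n), spike, n_genes=1))
    assert int(np.argmax(sm.smooth)) == 137


def test_loess_band_ordering_and_span_guard(rng):
    y = rng.normal(size=300)
    out = loess_smooth(AverageProfile(np.arange(300), y, n_genes=1))
    lo, hi = out.se_band
    assert np.all(lo <= out.smooth + 1e-12) and np.all(out.smooth <= hi + 1e-12)
    with pytest.raises(ValueError):
        loess_smooth(AverageProfile(np.arange(300), y, n_genes=1), span_bp=8)


def test_loess_matches_weighted_least_squares_oracle(rng):
    """The smoothed value equals a direct tricube-weighted quadratic fit."""
    n, span = 600, 180
    y = np.sin(np.arange(n) / 35) + rng.normal(0, 0.3, n)
    out = loess_smooth(AverageProfile(np.arange(n), y, n_genes=1), span_bp=span)
    for i in rng.integers(0, n, size=20):
        start = int(np.clip(i - (span - 1) // 2, 0, n - span))
        d = np.arange(start, start + span) - i
        w = (1 - (np.abs(d) / np.abs(d).max()) ** 3) ** 3
        X = np.vander(d.astype(float), 3, increasing=True)
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[start : start + span])
        assert out.smooth[i] == pytest.approx(beta[0], rel=1e-8, abs=1e-10)


def test_loess_agrees_with_r_loess(tmp_path):
    """Cross-check against the reference loess implementation in R."""
    rng = np.random.default_rng(8)
    n = 300
    y = np.cos(np.arange(n) / 25) + rng.normal(0, 0.25, n)
    yfile = tmp_path / "y.txt"
    np.savetxt(yfile, y)
    script = (
        f"y <- scan('{yfile}', quiet=TRUE); n <- length(y); x <- 0:(n-1);"
        f"fit <- loess(y ~ x, span={180 / n}, degree=2, surface='direct');"
        "cat(sprintf('%.12g\\n', predict(fit)))"
    )
    res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
    r_fit = np.array([float(v) for v in res.stdout.split()])
    out = loess_smooth(AverageProfile(np.arange(n), y, n_genes=1), span_bp=180)
    assert np.max(np.abs(out.smooth - r_fit)) < 1e-8


# ---------------------------------------------------------------------------
# background subtraction


def test_background_subtract_identical_tracks_zero(rng):
    genes = [GeneModel("a", "chr1", "+", 2000, 8000)]
    dyads = rng.integers(0, 12_000, size=1500)
    t = track_from_dyads(dyads, size=12_000, target=10_000)
    out = background_subtract(t, t, genes * 1, upstream_bp=200, downstream_bp=500)
    assert np.allclose(out.mean, 0.0)


def test_background_subtract_linearity_matches_window_sums(rng):
    genes = [GeneModel("a", "chr1", "+", 2000, 8000), GeneModel("b", "chr1", "-", 9000, 3000)]
    dyads = rng.integers(500, 11_500, size=1200)
    nuc = track_from_dyads(dyads, size=12_000, target=2400)  # scale 2
    doubled = np.repeat(dyads, 2)
    mod = track_from_dyads(doubled, size=12_000, target=2400)  # scale 1, counts x2
    out = background_subtract(mod, nuc, genes, window_bp=75,
                              upstream_bp=200, downstream_bp=500)
    # mod = 2x nuc in raw counts; after scaling both sum to target, difference 0
    assert np.allclose(out.mean, 0.0, atol=1e-9)
    # brute-force window sums for the unscaled difference
    counts = np.bincount(dyads, minlength=12_000)
    out2 = background_subtract(nuc, mod, genes, window_bp=75,
                               upstream_bp=100, downstream_bp=100)
    assert np.allclose(out2.mean, 0.0, atol=1e-9)


def test_background_subtract_brute_force_windows(rng):
    g = GeneModel("a", "chr1", "+", 2000, 8000)
    d_mod = rng.integers(1000, 9000, size=400)
    d_nuc = rng.integers(1000, 9000, size=700)
    mod = track_from_dyads(d_mod, size=12_000, target=1000)
    nuc = track_from_dyads(d_nuc, size=12_000, target=1000)
    out = background_subtract(mod, nuc, [g, g], window_bp=75,
                              upstream_bp=300, downstream_bp=300)
    cm = np.bincount(d_mod, minlength=12_000) * mod.scale
    cn = np.bincount(d_nuc, minlength=12_000) * nuc.scale
    for rel in (-300, -100, 0, 150, 300):
        pos = g.tss + rel
        expected = cm[pos - 37 : pos + 38].sum() - cn[pos - 37 : pos + 38].sum()
        got = out.mean[np.searchsorted(out.rel_positions, rel)]
        assert got == pytest.approx(expected)


def test_background_subtract_requires_matching_targets(rng):
    g = GeneModel("a", "chr1", "+", 2000, 8000)
    t1 = track_from_dyads([3000], size=12_000, target=10)
    t2 = track_from_dyads([3000], size=12_000, target=20)
    with pytest.raises(ValueError):
        background_subtract(t1, t2, [g])


def test_background_subtract_single_gene_has_no_band(rng, caplog):
    g = GeneModel("a", "chr1", "+", 2000, 8000)
    t = track_from_dyads(rng.integers(0, 12_000, 100), size=12_000)
    out = background_subtract(t, t, [g], upstream_bp=100, downstream_bp=100)
    assert np.all(np.isnan(out.se_band[0]))


# ---------------------------------------------------------------------------
# sequence and interval profiles


@pytest.mark.parametrize("base,expected", [("GC", 1.0), ("AT", 0.0), ("ACGT", 0.5)])
def test_gc_profile_uniform_genomes(base, expected):
    n = 20_000
    genome = {"chr1": (base * n)[:n]}
    genes = [GeneModel("a", "chr1", "+", 8000, 12_000), GeneModel("b", "chr1", "-", 12_000, 8000)]
    prof = gc_profile(genes, genome, flank_bp=1000)
    # a 75 bp window over a period-4 genome carries 37 or 38 G+C bases, so
    # allow the 1/150 discretisation wobble around the exact fraction
    assert np.allclose(prof.mean, expected, atol=1 / 150)
    assert prof.mean.mean() == pytest.approx(expected, abs=1e-3)


def test_gc_profile_masks_n_only_windows():
    genome = {"chr1": "N" * 20_000}
    g = GeneModel("a", "chr1", "+", 8000, 12_000)
    prof = gc_profile([g], genome, flank_bp=500)
    assert np.all(np.isnan(prof.mean))


def test_interval_density_profile():
    genes = [GeneModel("a", "chr1", "+", 5000, 9000), GeneModel("b", "chr1", "+", 20_000, 24_000)]
    full = [GenomicInterval("chr1", 0, 30_000)]
    assert np.allclose(interval_density_profile(genes, full, 500).mean, 1.0)
    assert np.allclose(interval_density_profile(genes, [], 500).mean, 0.0)
    # only the first gene covered at +100
    iv = [GenomicInterval("chr1", 5100, 5101)]
    prof = interval_density_profile(genes, iv, 500)
    assert prof.mean[np.searchsorted(prof.rel_positions, 100)] == pytest.approx(0.5)


def test_heatmap_ordering():
    pm = ProfileMatrix(["a", "b", "c"], np.arange(2),
                       np.array([[1.0, 2], [3, 4], [5, 6]]), np.ones((3, 2), dtype=bool))
    ident = heatmap_matrix(pm, {"a": 1, "b": 2, "c": 3})
    assert ident.gene_ids == ["a", "b", "c"]
    rev = heatmap_matrix(pm, {"a": 3, "b": 2, "c": 1})
    assert rev.gene_ids == ["c", "b", "a"]
    assert np.array_equal(rev.values, pm.values[::-1])
    tied = heatmap_matrix(pm, {"a": 1, "b": 1, "c": 0})
    assert tied.gene_ids == ["c", "a", "b"]
    with pytest.raises(ValueError):
        heatmap_matrix(pm, {"a": 1})


def test_profile_io_roundtrip(tmp_path, rng):
    values = rng.poisson(2.0, (5, 11)).astype(float)
    pm = ProfileMatrix([f"g{i}" for i in range(5)], np.arange(-5, 6), values,
                       np.ones_like(values, dtype=bool))
    path = tmp_path / "pm.tsv.gz"
    write_profile_matrix(pm, path)
    back = read_profile_matrix(path)
    assert back.gene_ids == pm.gene_ids
    assert np.array_equal(back.rel_positions, pm.rel_positions)
    assert np.allclose(back.values, pm.values)

    prof = loess_smooth(AverageProfile(np.arange(200), rng.normal(size=200), n_genes=3))
    ap_path = tmp_path / "avg.tsv"
    write_average_profile(prof, ap_path)
    back2 = read_average_profile(ap_path)
    assert np.allclose(back2.smooth, prof.smooth, atol=1e-4)
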