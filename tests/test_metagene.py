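"""Scaled meta-gene profiles and TSS-centred matrices."""

import numpy as np
import pytest

from chromtrans import GeneModel, SignalTrack, metagene_profile, tss_matrix

GENOME = {"Chr1": 100000}


def _constant_track(c=3.5):
    return SignalTrack.from_intervals([("Chr1", 0, 100000, c)])


def test_constant_track_gives_constant_profile():
    genes = [GeneModel("g", "Chr1", "+", 20000, 24000)]
    prof = metagene_profile(_constant_track(), genes, flank_bp=1000, flank_bins=10, body_bins=20)
    assert np.allclose(prof.means, 3.5)


def test_strand_mirror_symmetry():
    # a + gene and its exact - strand mirror with mirrored signal profile
    vals = [("Chr1", 19000, 20500, 2.0), ("Chr1", 20500, 24000, 5.0)]
    track_fwd = SignalTrack.from_intervals(vals)
    # mirror around the interval [19000, 25000)
    lo, hi = 18000, 26000
    mirrored = [("Chr1", lo + hi - e, lo + hi - s, v) for (_, s, e, v) in vals]
    track_rev = SignalTrack.from_intervals(mirrored)
    gp = GeneModel("gp", "Chr1", "+", 20000, 24000)
    gm = GeneModel("gm", "Chr1", "-", lo + hi - 24000, lo + hi - 20000)
    p1 = metagene_profile(track_fwd, [gp], flank_bp=1000, flank_bins=10, body_bins=30)
    p2 = metagene_profile(track_rev, [gm], flank_bp=1000, flank_bins=10, body_bins=30)
    assert np.allclose(p1.means, p2.means)


def _oracle_profile(track, genes, flank_bp, flank_bins, body_bins):
    """Naive per-base averaging loop."""
    rows = []
    for g in genes:
        if g.length < body_bins:
            continue
        up = [track.window_mean(g.chrom, p, p + 1) for p in range(g.start - flank_bp, g.start)]
        body = [track.window_mean(g.chrom, p, p + 1) for p in range(g.start, g.end)]
        down = [track.window_mean(g.chrom, p, p + 1) for p in range(g.end, g.end + flank_bp)]
        if g.strand == "-":
            up, body, down = down[::-1], body[::-1], up[::-1]

        def bins(vals, n):
            edges = [int(np.floor(i * len(vals) / n)) for i in range(n + 1)]
            return [float(np.mean(vals[edges[i]: edges[i + 1]])) for i in range(n)]

        rows.append(bins(up, flank_bins) + bins(body, body_bins) + bins(down, flank_bins))
    return np.mean(rows, axis=0)


def test_profile_matches_per_base_oracle():
    rng = np.random.default_rng(5)
    intervals = []
    pos = 0
    while pos < 99000:
        w = int(rng.integers(100, 800))
        if rng.random() < 0.5:
            intervals.append(("Chr1", pos, min(pos + w, 100000), float(rng.integers(1, 20))))
        pos += w
    track = SignalTrack.from_intervals(intervals)
    genes = []
    for i in range(20):
        s = int(rng.integers(3000, 90000))
        genes.append(GeneModel(f"g{i}", "Chr1", rng.choice(["+", "-"]), s, s + int(rng.integers(150, 3000))))
    prof = metagene_profile(track, genes, flank_bp=1000, flank_bins=5, body_bins=12)
    oracle = _oracle_profile(track, genes, 1000, 5, 12)
    assert np.allclose(prof.means, oracle)


def test_linearity():
    rng = np.random.default_rng(9)
    t1 = SignalTrack.from_intervals([("Chr1", 10000, 30000, 2.0)])
    t2 = SignalTrack.from_intervals([("Chr1", 15000, 40000, 7.0)])
    combo = SignalTrack.from_intervals(
        [("Chr1", 10000, 15000, 3 * 2.0), ("Chr1", 15000, 30000, 3 * 2.0 + 2 * 7.0), ("Chr1", 30000, 40000, 2 * 7.0)]
    )
    genes = [GeneModel(f"g{i}", "Chr1", "+", s := int(rng.integers(12000, 35000)), s + 2000) for i in range(5)]
    p1 = metagene_profile(t1, genes, 1000, 10, 20).means
    p2 = metagene_profile(t2, genes, 1000, 10, 20).means
    pc = metagene_profile(combo, genes, 1000, 10, 20).means
    assert np.allclose(pc, 3 * p1 + 2 * p2)


def test_short_genes_skipped_not_padded():
    genes = [
        GeneModel("long", "Chr1", "+", 20000, 24000),
        GeneModel("short", "Chr1", "+", 30000, 30010),
    ]
    prof = metagene_profile(_constant_track(), genes, flank_bp=500, flank_bins=5, body_bins=60)
    assert prof.n_genes == 1 and prof.n_skipped == 1


def test_invalid_bin_counts_rejected():
    genes = [GeneModel("g", "Chr1", "+", 20000, 24000)]
    with pytest.raises(ValueError):
        metagene_profile(_constant_track(), genes, flank_bp=500, flank_bins=0, body_bins=10)


class TestTssMatrix:
    def test_zero_track_all_zero(self):
        genes = [GeneModel("g", "Chr1", "+", 20000, 24000)]
        hm = tss_matrix(SignalTrack({}), genes, ["g"], flank_bp=1000, bin_bp=100)
        assert (hm.values.values == 0).all()

    def test_delta_signal_lands_in_first_downstream_bin(self):
        genes = [GeneModel("g", "Chr1", "+", 20000, 24000)]
        track = SignalTrack.from_intervals([("Chr1", 20010, 20011, 50.0)])
        hm = tss_matrix(track, genes, ["g"], flank_bp=1000, bin_bp=50)
        nonzero = hm.values.columns[(hm.values.values[0] > 0)]
        assert list(nonzero) == [0]

    def test_row_means_match_window_oracle(self):
        rng = np.random.default_rng(13)
        intervals = [("Chr1", s := int(rng.integers(0, 99000)), s + int(rng.integers(50, 500)), float(rng.integers(1, 9))) for _ in range(30)]
        # drop overlaps
        clean, last = [], -1
        for c, s, e, v in sorted(intervals):
            if s > last:
                clean.append((c, s, e, v))
                last = e
        track = SignalTrack.from_intervals(clean)
        genes = [GeneModel("g", "Chr1", "-", 50000, 52000)]
        hm = tss_matrix(track, genes, ["g"], flank_bp=2000, bin_bp=200)
        tss = 51999
        # oracle: direct window means, reversed for the - strand
        expected = [
            track.window_mean("Chr1", lo, lo + 200)
            for lo in range(tss + 1 - 2000, tss + 1 + 2000, 200)
        ][::-1]
        assert np.allclose(hm.values.values[0], expected)

    def test_translation_invariance(self):
        track1 = SignalTrack.from_intervals([("Chr1", 20000, 21000, 4.0)])
        track2 = SignalTrack.from_intervals([("Chr1", 50000, 51000, 4.0)])
        g1 = GeneModel("g", "Chr1", "+", 20500, 23000)
        g2 = GeneModel("g", "Chr1", "+", 50500, 53000)
        h1 = tss_matrix(track1, [g1], ["g"], flank_bp=1000, bin_bp=100)
        h2 = tss_matrix(track2, [g2], ["g"], flank_bp=1000, bin_bp=100)
        assert np.allclose(h1.values.values, h2.values.values)

    def test_unknown_gene_id_rejected(self):
        genes = [GeneModel("g", "Chr1", "+", 20000, 24000)]
        with pytest.raises(ValueError, match="absent"):
            tss_matrix(SignalTrack({}), genes, ["nope"], flank_bp=1000, bin_bp=100)

    def test_bin_width_must_divide_window(self):
        genes = [GeneModel("g", "Chr1", "+", 20000, 24000)]
        with pytest.raises(ValueError, match="divide"):
            tss_matrix(SignalTrack({}), genes, ["g"], flank_bp=1000, bin_bp=300)

    def test_clipped_window_flagged_and_zero_filled(self):
        genes = [GeneModel("g", "Chr1", "+", 200, 4000)]
        track = SignalTrack.from_intervals([("Chr1", 0, 5000, 1.0)])
        hm = tss_matrix(track, genes, ["g"], flank_bp=1000, bin_bp=100, genome=GENOME)
        assert bool(hm.clipped["g"])
        assert hm.values.values[0][:8].sum() == 0  # bases before the chromosome
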