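import numpy as np
import pytest

from flcs2d import (
    Map2D,
    PhotonStream,
    correlation_ratio,
    emission_delay_map,
    intensity_correlation,
    lifetime_weighted_correlation,
    log_binned_edges,
    log_windows,
    rebin_microtime,
    subtract_uncorrelated,
    uncorrelated_map_outer,
)

from conftest import poisson_two_channel_stream


def brute_force_pairs(stream, lo, hi):
    """O(n^2) oracle: ordered cross-channel pairs with lag in [lo, hi)."""
    t, ch, u = stream.macrotimes, stream.channels, stream.microtimes
    n_pairs, wsum = 0, 0.0
    pairs = []
    for i in range(len(t)):
        for j in range(len(t)):
            if t[j] - t[i] >= lo and t[j] - t[i] < hi and j > i and ch[i] != ch[j]:
                n_pairs += 1
                wsum += u[i] * u[j]
                pairs.append((i, j))
    return n_pairs, wsum, pairs


@pytest.fixture(scope="module")
def tiny_stream():
    return poisson_two_channel_stream(rate=1e3, duration=0.8, seed=7)


class TestPairCountingOracle:
    @pytest.mark.parametrize("window", [(1e-4, 1e-3), (1e-3, 5e-3), (5e-3, 0.05)])
    def test_intensity_counts_match_brute_force(self, tiny_stream, window):
        n_pairs, wsum, _ = brute_force_pairs(tiny_stream, *window)
        gi = intensity_correlation(tiny_stream, [window])
        n0 = np.sum(tiny_stream.channels == 0)
        n1 = np.sum(tiny_stream.channels == 1)
        lo, hi = window
        expected = (2.0 * n0 * n1 * (hi - lo) / tiny_stream.duration
                    * (1 - 0.5 * (lo + hi) / tiny_stream.duration))
        assert gi.values[0] + 1.0 == pytest.approx(n_pairs / expected, rel=1e-12)

    @pytest.mark.parametrize("window", [(1e-4, 1e-3), (1e-3, 5e-3)])
    def test_lifetime_weighted_matches_brute_force(self, tiny_stream, window):
        n_pairs, wsum, _ = brute_force_pairs(tiny_stream, *window)
        gl = lifetime_weighted_correlation(tiny_stream, [window])
        ch = tiny_stream.channels
        u = tiny_stream.microtimes
        u0, u1 = u[ch == 0].mean(), u[ch == 1].mean()
        n0, n1 = np.sum(ch == 0), np.sum(ch == 1)
        lo, hi = window
        expected = (2.0 * n0 * n1 * (hi - lo) / tiny_stream.duration
                    * (1 - 0.5 * (lo + hi) / tiny_stream.duration))
        assert gl.values[0] + 1.0 == pytest.approx(
            wsum / (u0 * u1) / expected, rel=1e-12)

    @pytest.mark.parametrize("window", [(1e-4, 1e-3), (1e-3, 5e-3)])
    def test_map_matches_brute_force(self, tiny_stream, window):
        edges = np.linspace(0, 12.288, 17)
        _, _, pairs = brute_force_pairs(tiny_stream, *window)
        expect = np.zeros((16, 16))
        u = tiny_stream.microtimes
        for i, j in pairs:
            bi = min(int(u[i] / 12.288 * 16), 15)
            bj = min(int(u[j] / 12.288 * 16), 15)
            expect[bi, bj] += 1
        m = emission_delay_map(tiny_stream, window, edges)
        assert m.pair_count == len(pairs)
        assert np.array_equal(m.counts, expect + expect.T)


class TestCorrelationProperties:
    def test_poisson_stream_is_uncorrelated(self, poisson_stream):
        gi = intensity_correlation(poisson_stream, log_windows(1e-4, 0.1, 10))
        assert np.all(np.abs(gi.values) < 5 * np.maximum(gi.errors, 1e-3))

    def test_single_species_ratio_is_one(self, poisson_stream):
        wins = log_windows(1e-4, 0.1, 8)
        gi = intensity_correlation(poisson_stream, wins)
        gl = lifetime_weighted_correlation(poisson_stream, wins)
        gr = correlation_ratio(gl, gi)
        # homogeneous sample: G_R = G_L/G_I = 1 within counting error
        assert np.all(np.abs(gr.values) < 0.02)

    def test_static_two_species_mixture_raises_ratio(self):
        """A static 70 ps / 3.3 ns mixture is lifetime-heterogeneous, so
        G_R > 1 at short lag: bursts of one molecule share a lifetime."""
        rng = np.random.default_rng(42)
        recs = []
        t = 0.0
        while t < 2.0:
            t += rng.exponential(2e-3)
            tau = 0.07 if rng.random() < 0.5 else 3.3
            n_b = rng.poisson(12)
            times = t + np.sort(rng.uniform(0, 2e-4, n_b))
            for tt in times:
                recs.append((tt, rng.exponential(tau)))
        recs.sort()
        mac = np.array([r[0] for r in recs])
        mic = np.clip(np.array([r[1] for r in recs]), 0, 12.287)
        ch = (rng.random(mac.size) < 0.5).astype(np.int8)
        st = PhotonStream(mac, mic, ch, 2.0 + 1e-3, {})
        wins = [(1e-5, 1e-4)]
        gi = intensity_correlation(st, wins)
        gl = lifetime_weighted_correlation(st, wins)
        gr = correlation_ratio(gl, gi)
        assert gr.values[0] > 0.1

    def test_single_channel_stream_rejected(self):
        st = PhotonStream(np.sort(np.random.default_rng(0).uniform(0, 1, 100)),
                          np.ones(100), np.zeros(100, dtype=np.int8), 1.0, {})
        with pytest.raises(ValueError, match="afterpuls"):
            intensity_correlation(st, [(1e-3, 1e-2)])


class TestMap2D:
    def test_three_photon_toy_single_pair(self):
        # photons at 0 ms (ch0), 1.5 ms (ch1), 30 ms (ch0); window 1-2 ms
        # pairs only (photon0, photon1): one count
        st = PhotonStream(np.array([0.0, 1.5e-3, 30e-3]),
                          np.array([0.1, 5.0, 9.0]),
                          np.array([0, 1, 0], dtype=np.int8), 0.05, {})
        edges = np.linspace(0, 12.288, 13)
        m = emission_delay_map(st, (1e-3, 2e-3), edges)
        assert m.pair_count == 1
        bi = int(0.1 / 12.288 * 12)
        bj = int(5.0 / 12.288 * 12)
        expect = np.zeros((12, 12))
        expect[bi, bj] += 1
        assert np.array_equal(m.counts, expect + expect.T)

    def test_static_species_map_is_outer_product(self, static_dye_stream):
        """With one static emitter the microtime pairs are independent draws
        from the same decay, so the map matches the outer product of the 1D
        histogram (chi^2 consistency)."""
        edges = np.linspace(0, 12.288, 33)
        m = emission_delay_map(static_dye_stream, (1e-5, 1e-4), edges)
        h, _ = np.histogram(static_dye_stream.microtimes, bins=edges)
        p = h / h.sum()
        expect = m.counts.sum() * np.outer(p, p)
        mask = expect > 15
        chi2 = np.sum((m.counts[mask] - expect[mask]) ** 2 / expect[mask])
        assert chi2 < 2.5 * mask.sum()

    def test_symmetrization_idempotent(self, tiny_stream):
        m = emission_delay_map(tiny_stream, (1e-4, 1e-3),
                               np.linspace(0, 12.288, 17))
        m2 = m.symmetrized()
        assert np.allclose(m2.counts, m.counts)
        assert np.allclose(m2.symmetrized().counts, m2.counts)

    def test_map_minus_itself_is_zero(self, tiny_stream):
        edges = np.linspace(0, 12.288, 17)
        m = emission_delay_map(tiny_stream, (1e-4, 1e-3), edges)
        bg = emission_delay_map(tiny_stream, (5e-3, 1e-2), edges)
        # same map subtracted from itself (bypassing the window-overlap check
        # by rebuilding it as a background at another window)
        bg.counts = m.counts.copy()
        bg.expected_pairs = m.expected_pairs
        diff = subtract_uncorrelated(m, bg)
        assert np.allclose(diff.counts, 0.0)
        assert diff.is_background_subtracted

    def test_poisson_subtracted_map_is_noise(self, poisson_stream):
        edges = np.linspace(0, 12.288, 33)
        m = emission_delay_map(poisson_stream, (1e-4, 1e-3), edges)
        bg = emission_delay_map(poisson_stream, (2e-2, 8e-2), edges)
        diff = subtract_uncorrelated(m, bg)
        # mean residual within counting error of zero
        resid = diff.counts.sum() / np.sqrt(np.maximum(m.counts.sum(), 1))
        assert abs(resid) < 5.0

    def test_outer_product_background_agrees_with_windowed(self, poisson_stream):
        edges = np.linspace(0, 12.288, 33)
        m = emission_delay_map(poisson_stream, (1e-4, 1e-3), edges)
        outer = uncorrelated_map_outer(poisson_stream, edges)
        diff = subtract_uncorrelated(m, outer)
        resid = diff.counts.sum() / np.sqrt(np.maximum(m.counts.sum(), 1))
        assert abs(resid) < 5.0

    def test_overlapping_background_window_rejected(self, tiny_stream):
        edges = np.linspace(0, 12.288, 17)
        m = emission_delay_map(tiny_stream, (1e-4, 1e-3), edges)
        bg = emission_delay_map(tiny_stream, (5e-4, 2e-3), edges)
        with pytest.raises(ValueError, match="overlap"):
            subtract_uncorrelated(m, bg)


class TestRebinning:
    def test_uniform_rebin_conserves_counts(self, tiny_stream):
        m = emission_delay_map(tiny_stream, (1e-4, 5e-3),
                               np.linspace(0, 12.288, 257))
        r = rebin_microtime(m, 16)
        assert r.counts.sum() == pytest.approx(m.counts.sum())
        assert r.n_bins == 16

    def test_log24_rebin_conserves_counts_in_range(self, tiny_stream):
        edges = np.linspace(0, 12.288, 257)
        m = emission_delay_map(tiny_stream, (1e-4, 5e-3), edges)
        r = rebin_microtime(m, "log24")
        assert r.n_bins == 24
        in_range = m.edges[1:] <= 6.144 + 1e-9
        sub = m.counts[np.ix_(in_range, in_range)]
        assert r.counts.sum() == pytest.approx(sub.sum())

    def test_log24_edges_widen_monotonically(self):
        edges = log_binned_edges(np.linspace(0, 12.288, 257), 24, 6.144)
        widths = np.diff(edges)
        assert edges.size == 25
        assert edges[0] == 0.0
        assert edges[-1] == pytest.approx(6.144)
        # nondecreasing widths, strictly wider overall
        assert np.all(np.diff(widths) >= -1e-9)
        assert widths[-1] > 2 * widths[0]

    def test_rebin_zero_map_is_zero(self):
        edges = np.linspace(0, 12.288, 257)
        m = Map2D((0.0, 1.0), edges, np.zeros((256, 256)), 0, 1.0)
        r = rebin_microtime(m, "log24")
        assert np.all(r.counts == 0)

    def test_finer_target_rejected(self, tiny_stream):
        m = emission_delay_map(tiny_stream, (1e-4, 5e-3),
                               np.linspace(0, 12.288, 17))
        with pytest.raises(ValueError):
            rebin_microtime(m, 16)
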