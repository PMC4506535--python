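import numpy as np
import pytest

from flcs2d import (
    Map2D,
    LifetimeDistribution,
    decay_basis,
    default_lifetime_grid,
    distribution_peaks,
    ilt_1d,
    laplace_decay,
    lifetime_map,
    log_binned_edges,
    mem_2d,
    purify_decomposition,
    refit_amplitudes,
    select_species_number,
)

GRID = default_lifetime_grid()
EDGES_1D = np.linspace(0.0, 9.5, 199)
EDGES_2D = log_binned_edges(np.linspace(0, 12.288, 257), 24, 6.144)
E2D = decay_basis(GRID, EDGES_2D)

FIXTURE_TAUS = np.array([0.07, 0.28, 1.7, 3.3])
FIXTURE_AMPS = np.array([4e4, 3e4, 1.5e4, 2e4])


def four_exp_decay():
    return decay_basis(FIXTURE_TAUS, EDGES_1D) @ FIXTURE_AMPS


def unit_species(tau):
    a = np.zeros(GRID.size)
    a[np.argmin(np.abs(GRID - tau))] = 1.0
    f = E2D @ a
    return f / f.sum()


def synthetic_map(Y, scale=3e5):
    return Map2D((1e-6, 2e-6), EDGES_2D, Y * scale, 10 ** 6, scale,
                 is_background_subtracted=True,
                 variance=np.abs(Y * scale) + 1.0)


class TestIlt1d:
    def test_default_grid(self):
        assert GRID.size == 40
        assert GRID[0] == pytest.approx(0.05)
        assert GRID[-1] == pytest.approx(10.0)

    def test_single_exponential_identity(self):
        y = decay_basis(np.array([3.3]), EDGES_1D) @ np.array([1e5])
        dist, _ = ilt_1d(y, EDGES_1D, eta=1e-6)
        peaks = distribution_peaks(dist)
        assert len(peaks) == 1
        nearest = GRID[np.argmin(np.abs(GRID - 3.3))]
        # within one grid step of the true lifetime
        step = GRID[1] / GRID[0]
        assert nearest / step <= peaks[0][0] <= nearest * step

    def test_four_exponential_fixture_resolved(self):
        dist, _ = ilt_1d(four_exp_decay(), EDGES_1D, eta=1e-6)
        peaks = [p[0] for p in distribution_peaks(dist)]
        assert len(peaks) == 4
        step = GRID[1] / GRID[0]
        for tau_true, tau_found in zip(FIXTURE_TAUS, peaks):
            assert tau_true / step <= tau_found <= tau_true * step

    def test_laplace_round_trip_under_one_percent(self):
        y = four_exp_decay()
        dist, _ = ilt_1d(y, EDGES_1D, eta=1e-6)
        back = laplace_decay(dist, EDGES_1D)
        assert np.abs(back - y).sum() / y.sum() < 0.01

    def test_entropy_regularization_moves_toward_prior(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(four_exp_decay()).astype(float)
        neg_entropies = []
        for eta in (1e-4, 1e-2, 1.0):
            _, diag = ilt_1d(y, EDGES_1D, eta=eta, restarts=1)
            neg_entropies.append(-diag["entropy"])
        # larger eta pulls the solution toward the prior (entropy -> 0)
        assert neg_entropies[0] >= neg_entropies[1] >= neg_entropies[2] >= 0

    def test_grid_refinement_stability(self):
        y = decay_basis(np.array([0.28]), EDGES_1D) @ np.array([1e5])
        peaks = []
        for npts in (40, 80):
            g = default_lifetime_grid(npts)
            dist, _ = ilt_1d(y, EDGES_1D, grid=g, eta=1e-6)
            peaks.append(distribution_peaks(dist)[0][0])
        step = GRID[1] / GRID[0]
        assert peaks[0] / step < peaks[1] < peaks[0] * step

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError):
            ilt_1d(-np.ones(EDGES_1D.size - 1), EDGES_1D)


class TestMem2d:
    def test_two_species_recovery(self):
        f1, f2 = unit_species(0.07), unit_species(0.28)
        Y = 0.8 * np.outer(f1, f1) + 0.3 * np.outer(f2, f2)
        dec = mem_2d(synthetic_map(Y), 2, seed=1, restarts=4)
        # species ordered by lifetime; peaks at the two inputs
        step = GRID[1] / GRID[0]
        p1 = distribution_peaks(dec.distributions[0])[0][0]
        p2 = max(p[0] for p in distribution_peaks(dec.distributions[1]))
        assert 0.07 / step < p1 < 0.07 * step
        assert 0.28 / step < p2 < 0.28 * step
        # diagonal-dominant amplitudes, off-diagonal ~ 0
        C = dec.C
        assert C[0, 1] < 0.1 * min(C[0, 0], C[1, 1])

    def test_amplitude_refit_recovers_exact_matrix(self):
        f1, f2 = unit_species(0.07), unit_species(0.28)
        C_true = np.array([[0.8, 0.05], [0.05, 0.3]])
        Y = (C_true[0, 0] * np.outer(f1, f1) + C_true[1, 1] * np.outer(f2, f2)
             + C_true[0, 1] * (np.outer(f1, f2) + np.outer(f2, f1)))
        D = np.stack([f1, f2], axis=1)
        C_fit, cov = refit_amplitudes(synthetic_map(Y), D, return_cov=True)
        assert np.allclose(C_fit, C_true, rtol=1e-6, atol=1e-9)
        assert cov.shape == (3, 3)

    def test_model_map_consistency_self_audit(self):
        f1, f2 = unit_species(0.07), unit_species(3.3)
        Y = 0.5 * np.outer(f1, f1) + 0.5 * np.outer(f2, f2)
        m = synthetic_map(Y)
        dec = mem_2d(m, 2, seed=1, restarts=2)
        # model_map() is in the map's pair-expectation normalization
        resid = dec.model_map() - m.normalized()
        chi2 = np.sum(m.expected_pairs ** 2 * resid ** 2 / np.maximum(m.variance, 1.0))
        assert chi2 == pytest.approx(dec.diagnostics["chi2"], rel=1e-6)

    def test_single_species_map_matches_ilt1d(self):
        """n=1 inversion of an outer-product map reproduces the 1D inverse
        transform of its marginal (2% L1)."""
        f1 = unit_species(0.28)
        Y = np.outer(f1, f1)
        m = synthetic_map(Y)
        dec = mem_2d(m, 1, seed=0, restarts=2, eta=1e-8)
        d1d, _ = ilt_1d(Y.sum(axis=0) * 3e5, EDGES_2D, eta=1e-8)
        a2 = dec.distributions[0].amplitudes
        a1 = d1d.amplitudes
        assert np.abs(a2 / a2.sum() - a1 / a1.sum()).sum() < 0.02

    def test_species_sorted_by_lifetime(self):
        f1, f2 = unit_species(0.07), unit_species(3.3)
        Y = 0.5 * np.outer(f1, f1) + 0.5 * np.outer(f2, f2)
        dec = mem_2d(synthetic_map(Y), 2, seed=3, restarts=4)
        taus = [d.mean_lifetime for d in dec.distributions]
        assert taus == sorted(taus)

    def test_invalid_species_count(self):
        with pytest.raises(ValueError):
            mem_2d(synthetic_map(np.outer(unit_species(1.0), unit_species(1.0))), 0)


class TestSelection:
    def test_two_species_map_selects_two(self):
        f1, f2 = unit_species(0.28), unit_species(3.3)
        Y = 0.7 * np.outer(f1, f1) + 0.4 * np.outer(f2, f2)
        n_star, dec = select_species_number(synthetic_map(Y), seed=0, restarts=4)
        assert n_star == 2

    def test_single_species_map_selects_one(self):
        f1 = unit_species(0.28)
        n_star, dec = select_species_number(synthetic_map(np.outer(f1, f1)),
                                            seed=0, restarts=4)
        assert n_star == 1

    def test_fast_exchanging_pair_is_one_species(self):
        """Fully exchange-averaged pair: every photon pair draws its two
        microtimes independently from the same mixture, so one species with
        two lifetime peaks describes the map."""
        mix = 0.5 * unit_species(0.3) + 0.5 * unit_species(1.7)
        n_star, dec = select_species_number(synthetic_map(np.outer(mix, mix)),
                                            seed=0, restarts=4)
        assert n_star == 1
        peaks = [p[0] for p in distribution_peaks(dec.distributions[0],
                                                  min_rel_height=0.15)]
        assert len(peaks) == 2

    def test_n_max_validation(self):
        with pytest.raises(ValueError):
            select_species_number(synthetic_map(np.eye(24)), n_max=1)


class TestPurification:
    def test_removes_cross_contamination(self):
        a_pure1 = np.zeros(40); a_pure1[5] = 1.0
        a_pure2 = np.zeros(40); a_pure2[20] = 1.0
        dists = [
            LifetimeDistribution(GRID, a_pure1 + 0.2 * a_pure2),
            LifetimeDistribution(GRID, a_pure2 + 0.3 * a_pure1),
        ]
        from flcs2d.ilt import SpeciesDecomposition
        E = decay_basis(GRID, EDGES_2D)
        f = E @ np.stack([d.amplitudes for d in dists]).T
        dec = SpeciesDecomposition(GRID, dists, np.eye(2), EDGES_2D,
                                   f / f.sum(0), {})
        pure = purify_decomposition(dec)
        A = np.stack([d.amplitudes for d in pure.distributions])
        assert A[0][20] == pytest.approx(0.0, abs=1e-12)
        assert A[1][5] == pytest.approx(0.0, abs=1e-12)


class TestLifetimeMap:
    def test_diagonal_and_cross_peaks(self):
        a1 = np.zeros(40); a1[5] = 1.0
        a2 = np.zeros(40); a2[25] = 1.0
        from flcs2d.ilt import SpeciesDecomposition
        dists = [LifetimeDistribution(GRID, a1), LifetimeDistribution(GRID, a2)]
        E = decay_basis(GRID, EDGES_2D)
        f = E @ np.stack([a1, a2]).T
        C = np.array([[1.0, 0.0], [0.0, 0.5]])
        dec = SpeciesDecomposition(GRID, dists, C, EDGES_2D, f / f.sum(0), {})
        tau_d, surf = lifetime_map(dec, smooth=False)
        assert surf[5, 5] == pytest.approx(1.0)
        assert surf[25, 25] == pytest.approx(0.5)
        assert surf[5, 25] == 0.0
        # switching on a cross amplitude creates symmetric cross peaks
        dec.C = np.array([[1.0, 0.3], [0.3, 0.5]])
        _, surf2 = lifetime_map(dec, smooth=False)
        assert surf2[5, 25] == pytest.approx(0.3)
        assert surf2[25, 5] == pytest.approx(0.3)

    def test_smoothed_surface_shape(self):
        a1 = np.exp(-0.5 * ((np.arange(40) - 12) / 2.0) ** 2)
        from flcs2d.ilt import SpeciesDecomposition
        dists = [LifetimeDistribution(GRID, a1)]
        E = decay_basis(GRID, EDGES_2D)
        f = E @ a1[:, None]
        dec = SpeciesDecomposition(GRID, dists, np.array([[1.0]]), EDGES_2D,
                                   f / f.sum(0), {})
        tau_d, surf = lifetime_map(dec, n_dense=201)
        assert surf.shape == (201, 201)
        assert np.all(surf >= 0)
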