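"""Maximum-entropy inverse Laplace transforms (1D decays and 2D maps).

The forward model expands fluorescence decays on a fixed logarithmic lifetime
grid (40 points over 0.05–10 ns by default): a decay is
I(t) = sum_k a(tau_k) exp(-t/tau_k) convolved with the Gaussian instrument
response, and a background-subtracted 2D emission-delay map is

    M(t', t'') = sum_ij C_ij I_i(t') I_j(t'')

with nonnegative species lifetime distributions a_i(tau) and a symmetric
nonnegative amplitude matrix C. Inversion minimizes Q = chi^2/2 - eta*S where
S is the Skilling entropy of the a_i relative to a prior m(tau); the entropy
regularizes the otherwise ill-posed inverse Laplace transform. Nonnegativity
is enforced by exponential reparameterization, and the regularization
constant is chosen by the classical maximum-entropy criterion chi^2 ~ number
of fitted bins unless fixed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.special import erfc, erfcx

__all__ = [
    "default_lifetime_grid",
    "decay_basis",
    "LifetimeDistribution",
    "SpeciesDecomposition",
    "ilt_1d",
    "mem_2d",
    "select_species_number",
    "refit_amplitudes",
    "lifetime_map",
    "distribution_peaks",
]


def default_lifetime_grid(n: int = 40, tau_min: float = 0.05, tau_max: float = 10.0) -> np.ndarray:
    """Log-spaced lifetime grid (ns)."""
    return np.geomspace(tau_min, tau_max, n)


def _exp_irf_decay(t: np.ndarray, tau: float, sigma: float, center: float) -> np.ndarray:
    """exp(-t/tau) (unit amplitude, t >= 0) convolved with a Gaussian IRF."""
    x = np.asarray(t, dtype=float) - center
    a = sigma / (np.sqrt(2.0) * tau) - x / (np.sqrt(2.0) * sigma)
    # 0.5*erfc(a)*exp(sigma^2/2tau^2 - x/tau) == 0.5*erfcx(a)*exp(-x^2/2sigma^2);
    # the erfcx form avoids overflow on the rising edge (a >> 0), the direct
    # form on the decay tail (a << 0 where erfcx would overflow)
    with np.errstate(over="ignore", invalid="ignore"):
        rise = 0.5 * erfcx(np.clip(a, -1.0, None)) * np.exp(-(x * x) / (2.0 * sigma * sigma))
        tail = 0.5 * erfc(np.clip(a, None, 1.0)) * np.exp(
            sigma * sigma / (2.0 * tau * tau) - x / tau)
    return np.where(a > 0.0, rise, tail)


def decay_basis(
    tau_grid: np.ndarray,
    edges_ns: np.ndarray,
    irf_sigma_ns: float = 0.02123,
    irf_center_ns: float = 0.25,
) -> np.ndarray:
    """Bin-integrated IRF-convolved single-exponential decays.

    Returns E with shape (n_bins, n_tau); column k is the decay with lifetime
    tau_k integrated over each microtime bin (Simpson rule, 8 panels/bin).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    edges = np.asarray(edges_ns, dtype=float)
    n_sub = 8
    E = np.empty((edges.size - 1, tau_grid.size))
    w_simp = np.ones(n_sub + 1)
    w_simp[1:-1:2] = 4.0
    w_simp[2:-1:2] = 2.0
    for b in range(edges.size - 1):
        t_sub = np.linspace(edges[b], edges[b + 1], n_sub + 1)
        h = (edges[b + 1] - edges[b]) / n_sub
        for k, tau in enumerate(tau_grid):
            y = _exp_irf_decay(t_sub, tau, irf_sigma_ns, irf_center_ns)
            E[b, k] = h / 3.0 * np.dot(w_simp, y)
    return E


# ---------------------------------------------------------------------------
# containers


@dataclass
class LifetimeDistribution:
    """Nonnegative lifetime amplitude distribution a(tau) on a log grid."""

    grid: np.ndarray
    amplitudes: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.grid.size != self.amplitudes.size:
            raise ValueError("grid and amplitudes differ in length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("lifetime grid must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes)) or np.any(self.amplitudes < -1e-12):
            raise ValueError("amplitudes must be finite and nonnegative")

    @property
    def mean_lifetime(self) -> float:
        a = self.amplitudes
        return float(a @ self.grid / a.sum()) if a.sum() > 0 else np.nan


def distribution_peaks(dist: LifetimeDistribution, min_rel_height: float = 0.05):
    """Local maxima of a lifetime distribution.

    Each peak is refined by a log-tau centroid over its contiguous support
    (down to 20% of the peak height) and reported as
    (tau_ns, grid_index, height), sorted by lifetime.
    """
    a = dist.amplitudes
    tau = dist.grid
    if a.max() <= 0:
        return []
    thresh = min_rel_height * a.max()
    peaks = []
    for i in range(a.size):
        left = a[i - 1] if i > 0 else -np.inf
        right = a[i + 1] if i < a.size - 1 else -np.inf
        if a[i] >= thresh and a[i] > left and a[i] >= right:
            # contiguous support above 20% of this peak
            lo = i
            while lo > 0 and a[lo - 1] > 0.2 * a[i] and a[lo - 1] <= a[lo]:
                lo -= 1
            hi = i
            while hi < a.size - 1 and a[hi + 1] > 0.2 * a[i] and a[hi + 1] <= a[hi]:
                hi += 1
            seg = slice(lo, hi + 1)
            w = a[seg]
            tau_c = float(np.exp(np.sum(w * np.log(tau[seg])) / np.sum(w)))
            peaks.append((tau_c, i, float(a[i])))
    peaks.sort(key=lambda p: p[0])
    return peaks


@dataclass
class SpeciesDecomposition:
    """n species lifetime distributions plus a symmetric amplitude matrix.

    ``decays`` are the photon-normalized species decay profiles on the map's
    microtime bins (columns sum to 1); ``C`` is scaled accordingly, so the
    model map is sum_ij C_ij decays_i(t') decays_j(t'') with the off-diagonal
    convention C_ij = C_ji (each unordered pair contributes both orders).
    """

    grid: np.ndarray
    distributions: list[LifetimeDistribution]
    C: np.ndarray
    edges: np.ndarray
    decays: np.ndarray                  # (n_bins, n_species)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.distributions)

    def model_map(self) -> np.ndarray:
        F = self.decays @ self.C @ self.decays.T
        return F

    def similarity_matrix(self) -> np.ndarray:
        A = np.stack([d.amplitudes for d in self.distributions])
        norm = np.linalg.norm(A, axis=1, keepdims=True)
        A = A / np.maximum(norm, 1e-300)
        return A @ A.T


# ---------------------------------------------------------------------------
# MEM core


def _entropy(a: np.ndarray, m: np.ndarray) -> float:
    return float(np.sum(a - m - a * np.log(a / m)))


def _mem2d_objective(theta, E, Y, W, m_prior, eta, n, tri):
    K = m_prior.size
    u = theta[: n * K].reshape(n, K)
    v = theta[n * K:]
    a = m_prior[None, :] * np.exp(u)                   # (n, K)
    f = E @ a.T                                        # (bins, n)
    C = np.zeros((n, n))
    C[tri] = np.exp(v)
    C = np.triu(C) + np.triu(C, 1).T                   # symmetric
    F = f @ C @ f.T
    R = 2.0 * W * (F - Y)
    chi2 = float(np.sum(W * (F - Y) ** 2))
    S = _entropy(a, m_prior[None, :].repeat(n, 0))
    Q = 0.5 * chi2 - eta * S
    # gradients
    Gf = R @ f @ C                                     # (bins, n); d(chi2)/df = 2*Gf
    Ga = Gf.T @ E                                      # (n, K); 0.5*d(chi2)/da
    dQ_da = Ga + eta * np.log(a / m_prior[None, :])
    gu = (a * dQ_da).ravel()
    M = f.T @ R @ f                                    # (n, n); d(chi2)/dC full
    gC = np.zeros_like(M)
    iu, ju = tri
    for idx in range(iu.size):
        i, j = iu[idx], ju[idx]
        gC_val = M[i, j] if i == j else M[i, j] + M[j, i]
        gC[i, j] = gC_val
    gv = 0.5 * gC[tri] * np.exp(v)
    return Q, np.concatenate([gu, gv])


def _solve_mem2d(E, Y, W, m_prior, eta, n, u0, v0, maxiter=2000):
    """Minimize Q in two stages: a uniform-weight warm-up (well-conditioned
    for the quasi-Newton line search) followed by the full chi^2 weights."""
    K = m_prior.size
    tri = np.triu_indices(n)
    theta0 = np.concatenate([u0.ravel(), v0])
    bounds = [(-40.0, 40.0)] * theta0.size
    w_unif = np.full_like(W, 1.0 / max((Y ** 2).mean(), 1e-300) / Y.size)
    warm = minimize(
        _mem2d_objective, theta0, args=(E, Y, w_unif, m_prior, eta, n, tri),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-12},
    )
    res = minimize(
        _mem2d_objective, warm.x, args=(E, Y, W, m_prior, eta, n, tri),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-12},
    )
    u = res.x[: n * K].reshape(n, K)
    v = res.x[n * K:]
    a = m_prior[None, :] * np.exp(u)
    C = np.zeros((n, n))
    C[tri] = np.exp(v)
    C = np.triu(C) + np.triu(C, 1).T
    return a, C, res


def _chi2_of(E, Y, W, a, C, tri_mask=None):
    f = E @ a.T
    F = f @ C @ f.T
    r2 = W * (F - Y) ** 2
    if tri_mask is not None:
        r2 = r2[tri_mask]
    return float(np.sum(r2))


def _mem2d_once(E, Y, W, m_prior, eta, n, rng, restarts, jitter=0.6,
                warm=None):
    """Multi-start solve: the first start is the prior itself, odd restarts
    localize each species on a contiguous block of the lifetime grid (helps
    escape the all-species-alike local minimum), even restarts jitter.
    ``warm`` optionally supplies an (a, C) solution with n-1 species; a
    greedy start extends it with one fresh prior-shaped species, which
    prevents the spurious collapse of the extra species into zero amplitude.
    """
    best = None
    K = m_prior.size
    f0 = E @ m_prior
    c0 = max(np.sum(np.abs(Y)) / max(n * np.sum(f0) ** 2, 1e-300), 1e-12)
    tri = np.triu_indices(n)
    blocks = np.array_split(np.arange(K), n)
    starts = []
    if warm is not None and warm[0].shape[0] == n - 1 and n > 1:
        a_prev, C_prev = warm
        u0 = np.zeros((n, K))
        u0[:-1] = np.log(np.maximum(a_prev, 1e-17 * max(a_prev.max(), 1e-300))
                         / m_prior[None, :])
        C0 = np.full((n, n), c0 / 10.0)
        C0[:-1, :-1] = np.maximum(C_prev, c0 / 100.0)
        C0[-1, -1] = max(np.diag(C_prev).mean(), c0 / 10.0)
        starts.append((np.clip(u0, -30, 30), np.log(C0[tri])))
    for r in range(restarts):
        if r == 0:
            u0 = np.zeros((n, K))
        elif r % 2 == 1 and n > 1:
            u0 = np.full((n, K), -6.0)
            for i, blk in enumerate(blocks):
                u0[i, blk] = 0.0
            u0 = u0 + rng.normal(0.0, 0.3, size=(n, K))
        else:
            u0 = rng.normal(0.0, jitter, size=(n, K))
        v0 = np.full(tri[0].size, np.log(c0))
        v0[tri[0] != tri[1]] = np.log(c0 / 10.0)
        if r:
            v0 = v0 + rng.normal(0.0, jitter, size=v0.size)
        starts.append((u0, v0))
    for u0, v0 in starts:
        a, C, res = _solve_mem2d(E, Y, W, m_prior, eta, n, u0, v0)
        if best is None or res.fun < best[2].fun:
            best = (a, C, res)
    return best


def _auto_eta_2d(E, Y, W, m_prior, n, rng, restarts, warm=None):
    """Discrepancy-principle choice of eta.

    The map is symmetrized, so only the upper triangle carries independent
    information; the statistical target is (independent bins - parameters),
    floored at 1.25x the unregularized misfit in case the per-bin variance
    model is conservative. Bisection on log10(eta) with chi^2 increasing in
    eta; each probe is warm-limited (2 restarts), the endpoints use the full
    restart budget.
    """
    nb = Y.shape[0]
    tri_mask = np.triu(np.ones_like(Y, dtype=bool))
    n_indep = nb * (nb + 1) // 2
    n_params = n * m_prior.size + n * (n + 1) // 2
    lo, hi = -8.0, 6.0
    a, C, res = _mem2d_once(E, Y, W, m_prior, 10.0 ** lo, n, rng, restarts,
                            warm=warm)
    chi_min = _chi2_of(E, Y, W, a, C, tri_mask)
    target = max(n_indep - n_params, n_indep / 2.0, 1.25 * chi_min)
    if chi_min >= target:
        return 10.0 ** lo, (a, C, res)
    best_lo = (a, C, res)
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        a, C, res = _mem2d_once(E, Y, W, m_prior, 10.0 ** mid, n, rng,
                                restarts=2, warm=warm)
        chi = _chi2_of(E, Y, W, a, C, tri_mask)
        if chi < target:
            lo, best_lo = mid, (a, C, res)
        else:
            hi = mid
        if hi - lo < 0.15:
            break
    return 10.0 ** lo, best_lo


def _map_weights(map2d, mode: str = "empirical"):
    """(normalized map, chi^2 weights).

    ``mode='empirical'`` uses the block-resampled variances (appropriate for
    the many-parameter inversion, where burst noise must be damped);
    ``mode='poisson'`` uses the counting-statistics variances (appropriate
    for few-parameter amplitude fits, where data-estimated weights correlate
    with the noise and bias the fit).
    """
    Y = map2d.normalized()
    var = map2d.variance if mode == "empirical" else map2d.poisson_variance
    if var is None and mode == "poisson":
        var = map2d.variance
    if var is not None:
        W = map2d.expected_pairs ** 2 / np.maximum(var, 1.0)
    else:
        # Poisson-like weighting in normalized units for synthetic maps
        y_max = max(np.abs(Y).max(), 1e-300)
        W = 1.0 / np.maximum(np.abs(Y) * y_max, (1e-3 * y_max) ** 2)
    return Y, W


def mem_2d(
    map2d,
    n: int,
    prior: LifetimeDistribution | None = None,
    eta: float | str = "auto",
    grid: np.ndarray | None = None,
    irf_sigma_ns: float = 0.02123,
    irf_center_ns: float = 0.25,
    restarts: int = 8,
    seed: int = 0,
    warm_start=None,
) -> SpeciesDecomposition:
    """Decompose a background-subtracted 2D emission-delay map into ``n``
    species lifetime distributions and a correlation amplitude matrix.

    The map should be background-subtracted and rebinned (log24 recommended).
    ``prior`` is typically the 1D inverse transform of the ensemble decay; a
    flat prior is used if omitted. Species are returned ordered by mean
    lifetime, with photon-normalized decay profiles and C scaled to the
    map's pair-expectation normalization.
    """
    if n < 1:
        raise ValueError("species count must be >= 1")
    grid = np.asarray(grid, dtype=float) if grid is not None else default_lifetime_grid()
    if prior is not None and prior.grid.size != grid.size:
        raise ValueError("prior grid does not match the lifetime grid")
    E = decay_basis(grid, map2d.edges, irf_sigma_ns, irf_center_ns)
    Y, W = _map_weights(map2d)
    # work in units where the map is O(1); chi^2 is invariant under this
    scale = max(np.abs(Y).max(), 1e-300)
    Y = Y / scale
    W = W * scale ** 2
    if prior is None:
        m_prior = np.full(grid.size, 1.0 / grid.size)
    else:
        m_prior = np.maximum(prior.amplitudes, 1e-8 * max(prior.amplitudes.max(), 1e-300))
        m_prior = m_prior / m_prior.sum()
    rng = np.random.default_rng(seed)
    if eta == "auto":
        eta_val, (a, C, res) = _auto_eta_2d(E, Y, W, m_prior, n, rng, restarts,
                                            warm=warm_start)
    else:
        eta_val = float(eta)
        a, C, res = _mem2d_once(E, Y, W, m_prior, eta_val, n, rng, restarts,
                                warm=warm_start)
    chi2 = _chi2_of(E, Y, W, a, C)
    S = _entropy(a, m_prior[None, :].repeat(n, 0))

    # photon-normalize decays and fold the scales into C
    f = E @ a.T
    s = f.sum(axis=0)
    s = np.maximum(s, 1e-300)
    decays = f / s[None, :]
    C_norm = C * np.outer(s, s) * scale
    order = np.argsort([(a[i] @ grid) / a[i].sum() for i in range(n)])
    a = a[order]
    decays = decays[:, order]
    C_norm = C_norm[np.ix_(order, order)]
    dists = [LifetimeDistribution(grid, a[i], label=f"sp{i + 1}") for i in range(n)]
    return SpeciesDecomposition(
        grid=grid,
        distributions=dists,
        C=C_norm,
        edges=map2d.edges,
        decays=decays,
        diagnostics={
            "chi2": chi2, "entropy": S, "Q": 0.5 * chi2 - eta_val * S,
            "eta": eta_val, "n_iter": int(res.nit), "converged": bool(res.success),
            "n_bins": int(Y.size),
            "irf_sigma_ns": irf_sigma_ns, "irf_center_ns": irf_center_ns,
            "_raw_a": a, "_raw_C": C,
        },
    )


def select_species_number(
    map2d,
    prior: LifetimeDistribution | None = None,
    eta: float | str = "auto",
    n_max: int = 5,
    redundancy_threshold: float = 0.98,
    weight_threshold: float = 1e-3,
    **mem_kwargs,
) -> tuple[int, SpeciesDecomposition]:
    """Smallest species count that describes a 2D map without redundancy.

    Runs the decomposition for n = 2..n_max; the first n at which a species
    becomes redundant indicates that n-1 species are necessary and
    sufficient. A species is redundant when it repeats another's lifetime
    pattern (cosine similarity >= ``redundancy_threshold``) or carries a
    negligible share of the model map's correlation amplitude
    (< ``weight_threshold``; redundant species collapse to amplitudes orders
    of magnitude below any statistically supported one). If no redundancy appears up to n_max, returns
    n_max with a warning flag in the diagnostics.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    cache: dict[int, SpeciesDecomposition] = {}
    similarity: dict[int, np.ndarray] = {}
    for n in range(2, n_max + 1):
        dec = mem_2d(map2d, n, prior=prior, eta=eta, **mem_kwargs)
        cache[n] = dec
        sim = dec.similarity_matrix()
        similarity[n] = sim
        off = sim[np.triu_indices(n, 1)]
        weights = dec.C.sum(axis=1)
        weights = weights / max(weights.sum(), 1e-300)
        if weights.min() < weight_threshold or (
                off.size and off.max() >= redundancy_threshold):
            n_star = n - 1
            best = cache.get(n_star) or mem_2d(map2d, n_star, prior=prior,
                                               eta=eta, **mem_kwargs)
            best.diagnostics["n_star"] = n_star
            best.diagnostics["similarity_by_n"] = similarity
            return n_star, best
    best = cache[n_max]
    best.diagnostics["n_star"] = n_max
    best.diagnostics["similarity_by_n"] = similarity
    best.diagnostics["redundancy_not_reached"] = True
    return n_max, best


# ---------------------------------------------------------------------------
# 1D MEM inverse Laplace transform


def ilt_1d(
    decay: np.ndarray,
    edges_ns: np.ndarray,
    grid: np.ndarray | None = None,
    eta: float | str = "auto",
    prior: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    irf_sigma_ns: float = 0.02123,
    irf_center_ns: float = 0.25,
    restarts: int = 4,
    seed: int = 0,
) -> tuple[LifetimeDistribution, dict]:
    """Maximum-entropy lifetime distribution of a 1D fluorescence decay.

    ``decay`` holds nonnegative histogram counts on microtime bins
    ``edges_ns``; weights default to the Poisson approximation
    1/max(counts, 1). Returns the distribution and a diagnostics dict
    (chi2, entropy, eta, residuals).
    """
    y = np.asarray(decay, dtype=float)
    if np.any(y < 0):
        raise ValueError("decay histogram must be nonnegative")
    grid = np.asarray(grid, dtype=float) if grid is not None else default_lifetime_grid()
    E = decay_basis(grid, np.asarray(edges_ns, dtype=float), irf_sigma_ns, irf_center_ns)
    w = weights if weights is not None else 1.0 / np.maximum(y, 1.0)
    # amplitude scale for the flat prior from a quick nonnegative LS solve
    a_ls, _ = nnls(E * np.sqrt(w)[:, None], y * np.sqrt(w))
    total = max(a_ls.sum(), y.max() / max(E.max(), 1e-300), 1e-12)
    if prior is None:
        m_prior = np.full(grid.size, total / grid.size)
    else:
        m_prior = np.maximum(np.asarray(prior, dtype=float), 1e-10 * total)

    # 1D problem as a single-species map-free solve
    def solve(eta_val, u0):
        def obj(u):
            a = m_prior * np.exp(u)
            r = E @ a - y
            chi2 = float(np.sum(w * r * r))
            S = _entropy(a, m_prior)
            g_a = 2.0 * (E.T @ (w * r))
            g = a * (0.5 * g_a + eta_val * np.log(a / m_prior))
            return 0.5 * chi2 - eta_val * S, g

        res = minimize(obj, u0, jac=True, method="L-BFGS-B",
                       bounds=[(-40, 40)] * grid.size,
                       options={"maxiter": 3000, "ftol": 1e-14, "gtol": 1e-12})
        return m_prior * np.exp(res.x), res

    rng = np.random.default_rng(seed)
    target = y.size
    # warm start from the nonnegative LS solution (sharp, unregularized)
    u_init = np.log(np.maximum(a_ls, 1e-8 * total) / m_prior)
    u_init = np.clip(u_init, -39.0, 39.0)

    def chi2_of(a):
        r = E @ a - y
        return float(np.sum(w * r * r))

    if eta == "auto":
        lo, hi = -8.0, 6.0
        a_best, res = solve(10.0 ** lo, u_init)
        if chi2_of(a_best) < target:
            u_prev = np.log(a_best / m_prior)
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                a_mid, res_mid = solve(10.0 ** mid, u_prev)
                if chi2_of(a_mid) < target:
                    lo, a_best, res = mid, a_mid, res_mid
                    u_prev = np.log(a_mid / m_prior)
                else:
                    hi = mid
                if hi - lo < 0.1:
                    break
        eta_val = 10.0 ** lo
    else:
        eta_val = float(eta)
        best = None
        for r in range(max(restarts, 1)):
            u0 = u_init + rng.normal(0, 0.5, grid.size) if r else u_init
            a_r, res_r = solve(eta_val, u0)
            if best is None or res_r.fun < best[1].fun:
                best = (a_r, res_r)
        a_best, res = best
    if not np.isfinite(res.fun):
        raise RuntimeError(
            f"1D MEM diverged after {res.nit} iterations (Q={res.fun:.4g})")
    chi2 = chi2_of(a_best)
    diag = {
        "chi2": chi2, "entropy": _entropy(a_best, m_prior), "eta": eta_val,
        "residuals": E @ a_best - y, "n_iter": int(res.nit),
        "model": E @ a_best, "converged": bool(res.success),
    }
    return LifetimeDistribution(grid, a_best, label="ilt1d"), diag


def laplace_decay(dist: LifetimeDistribution, edges_ns: np.ndarray,
                  irf_sigma_ns: float = 0.02123, irf_center_ns: float = 0.25) -> np.ndarray:
    """Forward Laplace transform of a lifetime distribution onto microtime
    bins (IRF-convolved), the round-trip partner of :func:`ilt_1d`."""
    E = decay_basis(dist.grid, np.asarray(edges_ns, dtype=float),
                    irf_sigma_ns, irf_center_ns)
    return E @ dist.amplitudes


def refit_amplitudes(map2d, decays: np.ndarray, return_cov: bool = False):
    """Re-fit only the amplitude matrix C of a background-subtracted map with
    fixed species decay profiles (weighted nonnegative least squares).

    This is the per-lag step of species-correlation extraction: the
    distributions are determined once at a reference lag and held fixed, and
    each lag window refits C. Weights are the counting-statistics variances
    (see ``_map_weights``). Returns (C, cov) where cov is the Gaussian
    covariance of the stacked upper-triangle coefficients (None unless
    requested).
    """
    Y, W = _map_weights(map2d, mode="poisson")
    n = decays.shape[1]
    tri = np.triu_indices(n)
    cols = []
    for i, j in zip(*tri):
        S = np.outer(decays[:, i], decays[:, j])
        if i != j:
            S = S + S.T
        cols.append(S.ravel())
    A = np.stack(cols, axis=1)
    sw = np.sqrt(W.ravel())
    c, _ = nnls(A * sw[:, None], Y.ravel() * sw)
    C = np.zeros((n, n))
    C[tri] = c
    C = np.triu(C) + np.triu(C, 1).T
    cov = None
    if return_cov:
        Aw = A * sw[:, None]
        H = Aw.T @ Aw
        cov = np.linalg.pinv(H)
    return C, cov


def purify_decomposition(
    dec: SpeciesDecomposition,
    map2d=None,
    support_threshold: float = 0.05,
) -> SpeciesDecomposition:
    """Resolve the rotational ambiguity of a species decomposition.

    A decomposition is only defined up to mixing: replacing a_i by
    nonnegative combinations (with C transformed accordingly) reproduces the
    same map, and the entropy bias toward the common prior tends to leave a
    little of each species in the others. The mixing is removed by reducing
    each distribution to its extreme ray: the largest multiple of every other
    distribution that keeps it nonnegative is subtracted (evaluated on bins
    above ``support_threshold`` of the other's maximum). If ``map2d`` is
    given, C is refit to it with the purified profiles.
    """
    A = np.stack([d.amplitudes for d in dec.distributions])
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if i == j or A[j].max() <= 0:
                continue
            mask = A[j] > support_threshold * A[j].max()
            if not mask.any():
                continue
            beta = float(np.min(A[i][mask] / A[j][mask]))
            if beta > 0:
                A[i] = np.clip(A[i] - beta * A[j], 0.0, None)
    E = decay_basis(dec.grid, dec.edges,
                    dec.diagnostics.get("irf_sigma_ns", 0.02123),
                    dec.diagnostics.get("irf_center_ns", 0.25))
    f = E @ A.T
    s = np.maximum(f.sum(axis=0), 1e-300)
    decays = f / s[None, :]
    C = dec.C
    if map2d is not None:
        C, _ = refit_amplitudes(map2d, decays)
    dists = [LifetimeDistribution(dec.grid, A[i], label=d.label)
             for i, d in enumerate(dec.distributions)]
    diag = dict(dec.diagnostics)
    diag["purified"] = True
    return SpeciesDecomposition(dec.grid, dists, C, dec.edges, decays, diag)


def lifetime_map(dec: SpeciesDecomposition, n_dense: int = 201,
                 smooth: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Dense 2D lifetime correlation surface sum_ij C_ij a_i(tau')a_j(tau'').

    Returns (tau_dense, surface); with ``smooth`` the distributions are
    spline-interpolated on the log-lifetime axis for display.
    """
    tau = dec.grid
    if smooth and n_dense > tau.size:
        from scipy.interpolate import make_interp_spline

        tau_d = np.geomspace(tau[0], tau[-1], n_dense)
        A = []
        for d in dec.distributions:
            sp = make_interp_spline(np.log(tau), d.amplitudes, k=3)
            A.append(np.clip(sp(np.log(tau_d)), 0.0, None))
        A = np.stack(A)
    else:
        tau_d = tau
        A = np.stack([d.amplitudes for d in dec.distributions])
    surface = A.T @ dec.C @ A
    return tau_d, surface
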