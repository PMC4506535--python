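"""High-level 2D FLCS analysis recipes.

These functions chain the building blocks into the standard workflow:
photon stream -> lag-windowed 2D emission-delay maps -> background
subtraction and logarithmic microtime rebinning -> maximum-entropy species
decomposition at a reference lag -> per-lag amplitude refits (the
species-resolved correlation curves) -> kinetic model fits.

Species correlations are normalized so that the refit amplitude C_ij(dT),
divided by the corresponding coefficient of the uncorrelated background map
(which factorizes into photon fractions beta_i beta_j), gives the
fluctuation correlation G_ij(dT) on the same scale as the closed-form
models; in particular the ratio of the two diagonal amplitudes at the
shortest lag estimates the equilibrium constant of a two-state pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlate import (
    DEFAULT_BACKGROUND_WINDOW,
    CorrelationCurve,
    Map2D,
    default_map_windows,
    emission_delay_map,
    intensity_correlation,
    log_binned_edges,
    log_windows,
    rebin_microtime,
    subtract_uncorrelated,
)
from .ilt import (
    LifetimeDistribution,
    ilt_1d,
    mem_2d,
    purify_decomposition,
    refit_amplitudes,
)
from .kinetics import (
    compare_diffusion_models,
    fit_diffusion_only,
    fit_two_state,
)
from .photons import PhotonStream

__all__ = [
    "ensemble_decay",
    "ensemble_prior",
    "MapSeries",
    "build_map_series",
    "extract_species_correlations",
    "estimate_equilibrium_constant",
    "correct_equilibrium_constant",
    "dye_reference_analysis",
    "two_state_analysis",
    "bright_dark_analysis",
]


def _irf_params(stream: PhotonStream) -> tuple[float, float]:
    inst = stream.metadata.get("instrument", {})
    fwhm = inst.get("irf_fwhm_ps", 50.0)
    sigma = fwhm * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return sigma, inst.get("irf_center_ns", 0.25)


def ensemble_decay(stream: PhotonStream, edges_ns: np.ndarray) -> np.ndarray:
    """Microtime histogram over all photons (the ensemble fluorescence decay)."""
    h, _ = np.histogram(stream.microtimes, bins=edges_ns)
    return h.astype(float)


def ensemble_prior(stream: PhotonStream, edges_ns: np.ndarray,
                   grid: np.ndarray | None = None) -> LifetimeDistribution:
    """Lifetime distribution of the ensemble decay, used as the MEM prior.

    The ensemble decay contains every lifetime component of the correlated
    species, which is what makes it a sensible bias for the 2D inversion.
    """
    sigma, center = _irf_params(stream)
    dist, _ = ilt_1d(ensemble_decay(stream, edges_ns), edges_ns, grid=grid,
                     irf_sigma_ns=sigma, irf_center_ns=center)
    return dist


@dataclass
class MapSeries:
    """Background-subtracted, log-rebinned 2D maps over a lag ladder."""

    windows: list[tuple[float, float]]
    maps: list[Map2D]            # subtracted, on analysis bins
    background: Map2D            # raw (unsubtracted) background, same bins
    edges: np.ndarray


def build_map_series(
    stream: PhotonStream,
    windows: list[tuple[float, float]] | None = None,
    n_channels: int = 256,
    analysis_bins: str | np.ndarray = "log24",
    background_window: tuple[float, float] = DEFAULT_BACKGROUND_WINDOW,
    max_background_pairs: float = 2e7,
) -> MapSeries:
    """2D emission-delay maps for each lag window, background-subtracted.

    Maps are histogrammed at ``n_channels`` uniform microtime channels,
    rebinned onto the analysis bins (logarithmically widening bins over
    0–6.144 ns by default) and the uncorrelated part — the map at the
    ``background_window`` lag, scaled by the window-size ratio — subtracted.
    The background pair loop is subsampled to at most ``max_background_pairs``
    pairs.
    """
    windows = windows if windows is not None else default_map_windows()
    inst = stream.metadata.get("instrument", {})
    span = inst.get("microtime_channels", 4096) * inst.get(
        "microtime_resolution_ps", 3.0) * 1e-3
    edges_src = np.linspace(0.0, span, n_channels + 1)
    if isinstance(analysis_bins, str) and analysis_bins == "log24":
        target = log_binned_edges(edges_src, 24, 6.144)
    elif isinstance(analysis_bins, str):
        raise ValueError(f"unknown analysis binning {analysis_bins!r}")
    else:
        target = np.asarray(analysis_bins, dtype=float)

    n0 = int(np.sum(stream.channels == 0))
    n1 = int(np.sum(stream.channels == 1))
    bg_lo, bg_hi = background_window
    expected_bg = 2.0 * n0 * n1 * (bg_hi - bg_lo) / stream.duration
    stride = max(1, int(np.ceil(expected_bg / max_background_pairs)))
    bg = rebin_microtime(
        emission_delay_map(stream, background_window, edges_src, stride=stride),
        target,
    )
    maps = []
    for w in windows:
        m = rebin_microtime(emission_delay_map(stream, w, edges_src), target)
        maps.append(subtract_uncorrelated(m, bg))
    return MapSeries(list(windows), maps, bg, target)


def extract_species_correlations(
    series: MapSeries, decays: np.ndarray
) -> dict[tuple[int, int], CorrelationCurve]:
    """Species-resolved correlation curves G_ij(dT) from a map series.

    The species decay profiles (columns of ``decays``, photon-normalized, as
    produced by the reference-lag decomposition) are held fixed; each lag
    window refits only the amplitude matrix. Amplitudes are normalized by the
    corresponding coefficients of the uncorrelated background map, which
    converts them to fluctuation correlations comparable across species and
    lags. Returns curves keyed by species-index pairs (i <= j).
    """
    n = decays.shape[1]
    b, _ = refit_amplitudes(series.background, decays)
    if np.any(np.diag(b) <= 0):
        raise ValueError(
            "background decomposition assigns zero weight to a species; "
            "the distribution set is inconsistent with this stream"
        )
    centers = np.array([np.sqrt(lo * hi) for lo, hi in series.windows])
    widths = np.array([hi - lo for lo, hi in series.windows])
    vals = {k: [] for k in [(i, j) for i in range(n) for j in range(i, n)]}
    errs = {k: [] for k in vals}
    for m in series.maps:
        C, cov = refit_amplitudes(m, decays, return_cov=True)
        tri = np.triu_indices(n)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_mat = np.zeros((n, n))
        se_mat[tri] = se
        for (i, j) in vals:
            denom = b[i, j] if b[i, j] > 0 else np.sqrt(b[i, i] * b[j, j])
            vals[(i, j)].append(C[i, j] / denom)
            errs[(i, j)].append(se_mat[i, j] / denom)
    out = {}
    for (i, j) in vals:
        kind = "species_auto" if i == j else "species_cross"
        out[(i, j)] = CorrelationCurve(centers, widths, np.array(vals[(i, j)]),
                                       np.array(errs[(i, j)]), kind)
    return out


def estimate_equilibrium_constant(
    decomposition,
    shortest_map: Map2D,
    background: Map2D,
    split_tau_ns: float | None = None,
) -> float:
    """Equilibrium constant of a two-state pair from the diagonal peak
    volumes of the shortest-lag 2D lifetime correlation surface.

    The total surface sum_ij C_ij a_i(tau')a_j(tau'') is invariant under the
    rotation ambiguity of the species decomposition, so the peak volumes are
    integrated over the short- and long-lifetime regions of the *total*
    surface (split at ``split_tau_ns``, default the geometric mean of the two
    species' mean lifetimes). Each volume is normalized by the matching
    region of the uncorrelated-background surface, which removes the photon
    fractions (brightness x population), leaving the normalized species
    autocorrelations; their ratio tends to K = [B]/[A] as the lag window
    shrinks below the exchange time, since G_AA(0)/G_BB(0) = (1+K)/(1+1/K).
    """
    dec = decomposition
    C, _ = refit_amplitudes(shortest_map, dec.decays)
    b, _ = refit_amplitudes(background, dec.decays)
    taus = [d.mean_lifetime for d in dec.distributions]
    if split_tau_ns is None:
        if len(taus) < 2:
            raise ValueError("need at least two species to estimate K")
        split_tau_ns = float(np.sqrt(taus[0] * taus[-1]))
    A = np.stack([d.amplitudes for d in dec.distributions])   # (n, n_tau)
    grid = dec.grid
    a_short = A[:, grid < split_tau_ns].sum(axis=1)
    a_long = A[:, grid >= split_tau_ns].sum(axis=1)
    v = {}
    for name, region in (("short", a_short), ("long", a_long)):
        vf = float(region @ C @ region)
        vb = float(region @ b @ region)
        if vf <= 0 or vb <= 0:
            raise ValueError(f"nonpositive {name}-lifetime diagonal peak volume")
        v[name] = vf / vb
    return v["short"] / v["long"]


# ---------------------------------------------------------------------------
# end-to-end recipes


def _window_exchange_factor(window: tuple[float, float], tau_R_s: float) -> float:
    """Average of exp(-dT/tau_R) over a lag window (uniform pair density)."""
    lo, hi = window
    if tau_R_s <= 0 or not np.isfinite(tau_R_s):
        return 1.0
    return float(tau_R_s / (hi - lo)
                 * (np.exp(-lo / tau_R_s) - np.exp(-hi / tau_R_s)))


def correct_equilibrium_constant(ratio: float, exchange_factor: float) -> float:
    """Invert the finite-window two-state diagonal ratio for K.

    At a finite lag window the diagonal-amplitude ratio is
    R = (1 + K e)/(1 + e/K) with e the window-averaged exchange factor; R -> K
    only as e -> 1. Solving the quadratic K^2 e + K(1-R) - R e = 0 for the
    positive root removes the residual exchange bias.
    """
    e = float(np.clip(exchange_factor, 1e-9, 1.0))
    b = 1.0 - ratio
    return float((-b + np.sqrt(b * b + 4.0 * ratio * e * e)) / (2.0 * e))


def dye_reference_analysis(
    stream: PhotonStream,
    windows: list[tuple[float, float]] | None = None,
    p0: tuple[float, float, float] = (1.0, 5e-4, 0.1),
):
    """Reference fit of a single-species dye stream: the intensity
    correlation over a wide lag range fitted with the diffusion-only model,
    with free (N, tau_diff, w). Returns (curve, fit)."""
    windows = windows if windows is not None else log_windows(2e-6, 0.08, 40)
    gi = intensity_correlation(stream, windows)
    fit = fit_diffusion_only(gi, fit_window=None, w_fixed=None, p0=p0)
    return gi, fit


def two_state_analysis(
    stream: PhotonStream,
    w: float,
    windows: list[tuple[float, float]] | None = None,
    reference_window: tuple[float, float] = (0.2e-6, 4e-6),
    prior: LifetimeDistribution | None = None,
    restarts: int = 6,
    seed: int = 0,
    eta: float | str = "auto",
) -> dict:
    """Full two-state 2D FLCS pipeline for a stream with two bright species.

    Builds the map series, decomposes the reference-lag map into two species
    with the maximum-entropy inversion (prior = ensemble-decay lifetime
    distribution), extracts species auto/cross correlations across the lag
    ladder, estimates K from the shortest-lag diagonal ratio and fits the
    two-state exchange + diffusion model with (K, w) fixed.
    """
    windows = windows if windows is not None else default_map_windows()
    series = build_map_series(stream, [reference_window] + list(windows))
    ref_map, series.maps = series.maps[0], series.maps[1:]
    series.windows = series.windows[1:]
    sigma, center = _irf_params(stream)
    if prior is None:
        prior = ensemble_prior(stream, series.edges)
    dec = mem_2d(ref_map, 2, prior=prior, irf_sigma_ns=sigma,
                 irf_center_ns=center, restarts=restarts, seed=seed, eta=eta)
    dec = purify_decomposition(dec, ref_map)
    curves = extract_species_correlations(series, dec.decays)
    curve_set = {"AA": curves[(0, 0)], "BB": curves[(1, 1)], "AB": curves[(0, 1)]}
    # K from the diagonal peak-volume ratio of the shortest lag window,
    # corrected in one pass for the finite-window exchange factor with the
    # fitted equilibration time, then the final fit with K fixed.
    ratio = estimate_equilibrium_constant(dec, series.maps[0], series.background)
    fit = fit_two_state(curve_set, K=ratio, w=w)
    e_hat = _window_exchange_factor(series.windows[0], fit.tau_R_us * 1e-6)
    K = correct_equilibrium_constant(ratio, e_hat)
    fit = fit_two_state(curve_set, K=K, w=w)
    return {"decomposition": dec, "curves": curves, "K": K,
            "K_ratio_raw": ratio, "fit": fit, "prior": prior,
            "series": series}


def bright_dark_analysis(
    stream: PhotonStream,
    tau_diff_ms: float,
    w: float,
    windows: list[tuple[float, float]] | None = None,
    reference_window: tuple[float, float] = (0.2e-6, 4e-6),
    restarts: int = 4,
    seed: int = 0,
) -> dict:
    """Pipeline for an emissive state exchanging with a dark state.

    The dark state is invisible in the lifetime maps, so the decomposition
    has one species; its autocorrelation across the lag ladder is tested
    against diffusion-only vs diffusion-plus-relaxation models, with the
    diffusion parameters fixed from a reference-dye fit.
    """
    windows = windows if windows is not None else default_map_windows()
    series = build_map_series(stream, [reference_window] + list(windows))
    ref_map, series.maps = series.maps[0], series.maps[1:]
    series.windows = series.windows[1:]
    sigma, center = _irf_params(stream)
    prior = ensemble_prior(stream, series.edges)
    dec = mem_2d(ref_map, 1, prior=prior, irf_sigma_ns=sigma,
                 irf_center_ns=center, restarts=restarts, seed=seed)
    curves = extract_species_correlations(series, dec.decays)
    auto = curves[(0, 0)]
    comparison = compare_diffusion_models(auto, tau_diff_ms, w)
    return {"decomposition": dec, "curve": auto, "comparison": comparison,
            "fit": comparison["relaxation"]}
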