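"""Kinetic models and fits for species-resolved correlation curves.

The model family describes freely diffusing molecules whose conformational
state exchanges while they cross a 3D-Gaussian confocal volume:

* translational diffusion: g_D(dT) = (1 + dT/tau_diff)^-1 (1 + w^2 dT/tau_diff)^-1/2
  with radial-axial ratio w;
* two-state exchange A<->B with equilibrium constant K = [B]/[A] and
  equilibration time tau_R = 1/(k_AB + k_BA):

      G_AA = g_D/N (1 + K  e^{-dT/tau_R})
      G_BB = g_D/N (1 + K^-1 e^{-dT/tau_R})
      G_AB = g_D/N (1 - e^{-dT/tau_R})

  (fluctuation parts; all three converge to g_D/N for dT >> tau_R, and the
  population-weighted sum f_A^2 G_AA + f_B^2 G_BB + 2 f_A f_B G_AB equals
  g_D/N identically);
* bright/dark blinking appears in an emissive component's autocorrelation as
  g_D/N (1 + A e^{-dT/tau_R}).

All correlation values here are fluctuation parts (G - 1 convention of the
correlators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares, nnls

from .correlate import CorrelationCurve
from .ilt import decay_basis

__all__ = [
    "diffusion_correlation",
    "two_state_models",
    "diffusion_only",
    "diffusion_plus_relaxation",
    "TwoStateFitResult",
    "RelaxationFitResult",
    "DiffusionFitResult",
    "fit_diffusion_only",
    "fit_relaxation",
    "fit_two_state",
    "compare_diffusion_models",
    "fret_efficiency",
    "forster_distance",
    "global_decay_fit",
    "truncated_exponential_moments",
    "truncated_brightness",
    "scheme_total_correlation",
]


# ---------------------------------------------------------------------------
# closed-form models


def diffusion_correlation(delta_T, tau_diff: float, w: float):
    """Normalized diffusion correlation g_D(dT) for a 3D-Gaussian focus.

    ``tau_diff`` in the same time units as ``delta_T``; g_D(0) = 1 and the
    function decreases monotonically.
    """
    if tau_diff <= 0 or not (0 < w < 1):
        raise ValueError("require tau_diff > 0 and 0 < w < 1")
    x = np.asarray(delta_T, dtype=float) / tau_diff
    return 1.0 / (1.0 + x) / np.sqrt(1.0 + w * w * x)


def two_state_models(delta_T, N_pair: float, K: float, tau_R: float,
                     tau_diff: float, w: float):
    """Species auto/cross correlations (G_AA, G_BB, G_AB) of a two-state
    exchanging pair; K = [B]/[A], times in consistent units."""
    if min(N_pair, K, tau_R, tau_diff) <= 0:
        raise ValueError("parameters must be positive")
    g = diffusion_correlation(delta_T, tau_diff, w) / N_pair
    e = np.exp(-np.asarray(delta_T, dtype=float) / tau_R)
    return g * (1.0 + K * e), g * (1.0 + e / K), g * (1.0 - e)


def diffusion_only(delta_T, N: float, tau_diff: float, w: float):
    """Autocorrelation of a freely diffusing species: g_D/N."""
    return diffusion_correlation(delta_T, tau_diff, w) / N


def diffusion_plus_relaxation(delta_T, N: float, A: float, tau_R: float,
                              tau_diff: float, w: float):
    """Diffusion with a conformational-relaxation term:
    (g_D/N)(1 + A exp(-dT/tau_R)), A >= 0."""
    if A < 0:
        raise ValueError("relaxation amplitude must be >= 0")
    g = diffusion_only(delta_T, N, tau_diff, w)
    return g * (1.0 + A * np.exp(-np.asarray(delta_T, dtype=float) / tau_R))


def exchange_rates(tau_R_us: float, K: float) -> tuple[float, float]:
    """(k_AB, k_BA) in 1/us from the equilibration time and K = [B]/[A]."""
    total = 1.0 / tau_R_us
    return total * K / (1.0 + K), total / (1.0 + K)


# ---------------------------------------------------------------------------
# fit results


@dataclass
class DiffusionFitResult:
    N: float
    tau_diff_ms: float
    w: float
    chi2: float
    n_points: int
    n_free: int
    stderr: dict = field(default_factory=dict)


@dataclass
class RelaxationFitResult:
    N: float
    amplitude: float
    tau_R_us: float
    tau_diff_ms: float
    w: float
    chi2: float
    n_points: int
    n_free: int
    stderr: dict = field(default_factory=dict)


@dataclass
class TwoStateFitResult:
    """Joint fit of G_AA, G_BB, G_AB for a two-state exchanging pair."""

    N_pair: float
    K: float
    tau_R_us: float
    tau_diff_ms: float
    w: float
    chi2: float
    n_points: int
    n_free: int
    stderr: dict = field(default_factory=dict)

    @property
    def k_ab_per_us(self) -> float:
        return exchange_rates(self.tau_R_us, self.K)[0]

    @property
    def k_ba_per_us(self) -> float:
        return exchange_rates(self.tau_R_us, self.K)[1]


def _curve_window(curve: CorrelationCurve, window):
    m = np.ones(curve.delta_T.size, dtype=bool)
    if window is not None:
        m = (curve.delta_T >= window[0]) & (curve.delta_T <= window[1])
    if m.sum() < 3:
        raise ValueError("fit window leaves fewer than 3 points")
    err = np.where(curve.errors[m] > 0, curve.errors[m],
                   max(curve.errors[m].max(), 1e-12))
    return curve.delta_T[m], curve.values[m], err


def _stderr_from_jac(res, names):
    # Gaussian errors from the weighted Jacobian at the optimum
    try:
        J = res.jac
        dof = max(J.shape[0] - J.shape[1], 1)
        cov = np.linalg.pinv(J.T @ J) * 2.0 * res.cost / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return dict(zip(names, se))
    except Exception:  # pragma: no cover
        return {}


def fit_diffusion_only(
    curve: CorrelationCurve,
    fit_window: tuple[float, float] | None = (10e-6, 1e-3),
    w_fixed: float | None = None,
    p0: tuple[float, float, float] = (1.0, 5e-4, 0.1),
) -> DiffusionFitResult:
    """Fit the diffusion-only model g_D/N to an autocorrelation curve.

    The default fit window 10 us–1 ms restricts the fit to lags where
    translational diffusion dominates; pass ``fit_window=None`` (or a wider
    window) to constrain the axial ratio w, whose signature lies at
    dT >> tau_diff.
    """
    t, y, err = _curve_window(curve, fit_window)

    def unpack(p):
        if w_fixed is None:
            return np.exp(p[0]), np.exp(p[1]), 1.0 / (1.0 + np.exp(-p[2]))
        return np.exp(p[0]), np.exp(p[1]), w_fixed

    def resid(p):
        N, td, w = unpack(p)
        return (diffusion_only(t, N, td, w) - y) / err

    x0 = [np.log(p0[0]), np.log(p0[1])]
    names = ["N", "tau_diff"]
    if w_fixed is None:
        x0.append(np.log(p0[2] / (1 - p0[2])))
        names.append("w")
    res = least_squares(resid, x0, method="lm", max_nfev=20000)
    N, td, w = unpack(res.x)
    se = _stderr_from_jac(res, names)
    # delta-method transform of log/logit-scale errors
    stderr = {"N": N * se.get("N", np.nan), "tau_diff_ms": td * 1e3 * se.get("tau_diff", np.nan)}
    if w_fixed is None:
        stderr["w"] = w * (1 - w) * se.get("w", np.nan)
    return DiffusionFitResult(N, td * 1e3, w, 2.0 * res.cost, t.size,
                              len(x0), stderr)


def fit_relaxation(
    curve: CorrelationCurve,
    tau_diff_ms: float,
    w: float,
    fit_window: tuple[float, float] | None = None,
    p0: tuple[float, float, float] = (1.0, 0.5, 5e-6),
) -> RelaxationFitResult:
    """Fit (g_D/N)(1 + A e^{-dT/tau_R}) with the diffusion parameters held
    fixed (taken from a free-dye reference fit)."""
    t, y, err = _curve_window(curve, fit_window)
    td = tau_diff_ms * 1e-3

    def resid(p):
        N, A, tr = np.exp(p)
        return (diffusion_plus_relaxation(t, N, A, tr, td, w) - y) / err

    res = least_squares(resid, np.log(p0), method="lm", max_nfev=20000)
    N, A, tr = np.exp(res.x)
    se = _stderr_from_jac(res, ["N", "A", "tau_R"])
    stderr = {"N": N * se.get("N", np.nan), "amplitude": A * se.get("A", np.nan),
              "tau_R_us": tr * 1e6 * se.get("tau_R", np.nan)}
    return RelaxationFitResult(N, A, tr * 1e6, tau_diff_ms, w,
                               2.0 * res.cost, t.size, 3, stderr)


def fit_two_state(
    curves: dict[str, CorrelationCurve],
    K: float,
    w: float,
    fit_window: tuple[float, float] | None = None,
    p0: tuple[float, float] = (1.0, 5e-6),
    tau_diff_ms0: float = 0.5,
) -> TwoStateFitResult:
    """Joint two-state fit of species auto/cross correlations.

    ``curves`` maps 'AA', 'BB', 'AB' to extracted correlation curves (A the
    shorter-lifetime state); K = [B]/[A] and the focal ratio w are held fixed
    (determined from the shortest-lag map decomposition and the reference-dye
    fit respectively). Free parameters: N_pair, tau_R, tau_diff.
    """
    for key in ("AA", "BB", "AB"):
        if key not in curves:
            raise ValueError(f"missing curve {key!r}")
    data = {k: _curve_window(curves[k], fit_window) for k in ("AA", "BB", "AB")}

    def resid(p):
        N, tr, td = np.exp(p)
        out = []
        for k in ("AA", "BB", "AB"):
            t, y, err = data[k]
            gaa, gbb, gab = two_state_models(t, N, K, tr, td, w)
            model = {"AA": gaa, "BB": gbb, "AB": gab}[k]
            out.append((model - y) / err)
        return np.concatenate(out)

    x0 = np.log([p0[0], p0[1], tau_diff_ms0 * 1e-3])
    res = least_squares(resid, x0, method="lm", max_nfev=40000)
    N, tr, td = np.exp(res.x)
    se = _stderr_from_jac(res, ["N", "tau_R", "tau_diff"])
    stderr = {"N_pair": N * se.get("N", np.nan),
              "tau_R_us": tr * 1e6 * se.get("tau_R", np.nan),
              "tau_diff_ms": td * 1e3 * se.get("tau_diff", np.nan)}
    n_pts = sum(d[0].size for d in data.values())
    return TwoStateFitResult(N, K, tr * 1e6, td * 1e3, w,
                             2.0 * res.cost, n_pts, 3, stderr)


def compare_diffusion_models(
    curve: CorrelationCurve, tau_diff_ms: float, w: float,
    alpha: float = 0.01,
    diffusion_fit_window: tuple[float, float] | None = (10e-6, 1e-3),
) -> dict:
    """F-test of diffusion-only against diffusion-plus-relaxation.

    The diffusion-only candidate is evaluated over the full lag range of the
    curve (its restricted fit window is where it is *fitted*); the relaxation
    model adds (A, tau_R). Returns the two fits, the F statistic and whether
    the relaxation term is required at level ``alpha``.
    """
    simple = fit_diffusion_only(curve, fit_window=diffusion_fit_window,
                                w_fixed=w)
    t, y, err = _curve_window(curve, None)
    rss0 = float(np.sum(((diffusion_only(t, simple.N, simple.tau_diff_ms * 1e-3,
                                         simple.w) - y) / err) ** 2))
    rich = fit_relaxation(curve, tau_diff_ms, w)
    rss1 = rich.chi2
    df1, df0 = 3, 2
    dof = max(t.size * 0 + rich.n_points - df1, 1)
    F = ((rss0 - rss1) / (df1 - df0)) / (rss1 / dof)
    p = float(stats.f.sf(max(F, 0.0), df1 - df0, dof))
    return {
        "diffusion_only": simple, "relaxation": rich,
        "rss_diffusion_only": rss0, "rss_relaxation": rss1,
        "F": float(F), "p_value": p, "relaxation_required": p < alpha,
    }


# ---------------------------------------------------------------------------
# FRET arithmetic


def fret_efficiency(tau_da: float, tau_d: float) -> float:
    """FRET efficiency E = 1 - tau_DA/tau_D from donor lifetimes."""
    if not (0 < tau_da <= tau_d):
        raise ValueError("require 0 < tau_DA <= tau_D (nonnegative efficiency)")
    return 1.0 - tau_da / tau_d


def forster_distance(tau_da: float, tau_d: float, R0: float = 41.0) -> float:
    """Donor-acceptor distance r = R0 ((1-E)/E)^(1/6) from donor lifetimes.

    R0 defaults to 41 A, the Forster distance of the Alexa546/haem pair.
    """
    if R0 <= 0:
        raise ValueError("R0 must be > 0")
    E = fret_efficiency(tau_da, tau_d)
    if E <= 0:
        raise ValueError("zero efficiency: distance undefined")
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# decay fitting and truncated brightness


def global_decay_fit(
    decays: list[np.ndarray],
    lifetimes_ns: np.ndarray,
    edges_ns: np.ndarray,
    irf_sigma_ns: float = 0.02123,
    irf_center_ns: float = 0.25,
) -> np.ndarray:
    """Amplitudes of fixed-lifetime components for each decay curve.

    With the lifetimes fixed, each decay is a linear problem solved by
    weighted nonnegative least squares. Returns an array of shape
    (n_decays, n_lifetimes).
    """
    lifetimes_ns = np.asarray(lifetimes_ns, dtype=float)
    E = decay_basis(lifetimes_ns, np.asarray(edges_ns, dtype=float),
                    irf_sigma_ns, irf_center_ns)
    if np.linalg.cond(E) > 1e8:
        warnings.warn("near-degenerate lifetime set: amplitudes are poorly "
                      "determined", RuntimeWarning, stacklevel=2)
    out = np.empty((len(decays), lifetimes_ns.size))
    for i, y in enumerate(decays):
        y = np.asarray(y, dtype=float)
        sw = 1.0 / np.sqrt(np.maximum(y, 1.0))
        a, _ = nnls(E * sw[:, None], y * sw)
        out[i] = a
    return out


def truncated_exponential_moments(tau_ns: float, t_max_ns: float) -> tuple[float, float]:
    """(effective lifetime, integrated intensity) of exp(-t/tau) truncated to
    [0, t_max]: the first moment of the truncated normalized decay and its
    unnormalized integral tau (1 - e^{-t_max/tau})."""
    if t_max_ns <= 0:
        raise ValueError("t_max must be > 0")
    x = t_max_ns / tau_ns
    if x > 700:
        return tau_ns, tau_ns
    z = -tau_ns * np.expm1(-x)
    if x < 1e-4:
        # uniform limit: series in x avoids catastrophic cancellation
        mean = t_max_ns * (0.5 - x / 12.0)
    else:
        mean = tau_ns - t_max_ns * np.exp(-x) / (-np.expm1(-x))
    return float(mean), float(z)


def truncated_brightness(
    decay, t_max_ns: float = 9.5, tau_reference_ns: float = 4.0,
    edges_ns: np.ndarray | None = None,
) -> tuple[float, float]:
    """Effective lifetime and relative brightness of a truncated decay.

    ``decay`` is either a scalar lifetime (closed-form truncated-exponential
    moments) or a decay histogram on ``edges_ns``. The effective lifetime is
    the first moment of the decay truncated to the microtime detection window
    [0, t_max]; the relative brightness is the truncated intensity integral
    against a reference lifetime (equal extinction assumed across states).
    """
    _, z_ref = truncated_exponential_moments(tau_reference_ns, t_max_ns)
    if np.isscalar(decay):
        mean, z = truncated_exponential_moments(float(decay), t_max_ns)
        return mean, z / z_ref
    y = np.asarray(decay, dtype=float)
    if edges_ns is None:
        raise ValueError("edges_ns required for a histogram decay")
    centers = 0.5 * (np.asarray(edges_ns)[:-1] + np.asarray(edges_ns)[1:])
    widths = np.diff(np.asarray(edges_ns, dtype=float))
    m = centers <= t_max_ns
    z = float(np.sum(y[m] * widths[m]))
    mean = float(np.sum(y[m] * centers[m] * widths[m]) / z)
    return mean, z / z_ref


# ---------------------------------------------------------------------------
# full-scheme total correlation


def scheme_total_correlation(delta_T, scheme, weighting: str = "intensity"):
    """Total (ensemble) fluorescence correlation of a multi-state scheme whose
    exchange network decomposes into disjoint two-state pairs sharing one
    diffusion time.

    Each pair contributes a relaxation term with its equilibration time and
    amplitude set by the within-pair populations and brightnesses; unpaired
    states contribute only diffusion. Dark states carry population but zero
    brightness. With ``weighting='lifetime'`` each state's brightness q_P is
    replaced by tau_P q_P, giving the lifetime-weighted correlation.
    """
    if weighting not in ("intensity", "lifetime"):
        raise ValueError("weighting must be 'intensity' or 'lifetime'")
    pops = scheme.populations
    q = scheme.brightnesses_hz.astype(float).copy()
    if weighting == "lifetime":
        q = q * scheme.lifetimes_ns
    names = scheme.state_names
    in_pair: dict[int, int] = {}
    groups = []
    for p in scheme.exchange_pairs:
        ia, ib = scheme.state_index(p.state_a), scheme.state_index(p.state_b)
        if ia in in_pair or ib in in_pair:
            raise ValueError(
                f"state {names[ia]} or {names[ib]} appears in more than one "
                "pair; the total-correlation model needs disjoint two-state systems"
            )
        in_pair[ia] = len(groups)
        in_pair[ib] = len(groups)
        groups.append((ia, ib, p.equilibration_time_us * 1e-6))
    singles = [i for i in range(len(names)) if i not in in_pair]

    q_mean = float(pops @ q)
    if q_mean <= 0:
        raise ValueError("scheme has no emission")
    dT = np.asarray(delta_T, dtype=float)
    g = diffusion_correlation(dT, scheme.diffusion.diffusion_time_ms * 1e-3,
                              scheme.diffusion.radial_axial_ratio)
    total = np.zeros_like(dT, dtype=float)
    for ia, ib, tau_s in groups:
        gamma = pops[ia] + pops[ib]
        phi = np.array([pops[ia], pops[ib]]) / gamma
        qq = np.array([q[ia], q[ib]])
        mean_q = float(phi @ qq)
        var_q = float(phi @ qq ** 2) - mean_q ** 2
        total = total + gamma * (mean_q ** 2 + var_q * np.exp(-dT / tau_s))
    for i in singles:
        total = total + pops[i] * q[i] ** 2
    return g * total / (scheme.mean_occupancy * q_mean ** 2)
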