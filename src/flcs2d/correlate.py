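"""Photon-pair correlators and 2D emission-delay correlation maps.

All correlators pair photons strictly across the two detector channels (both
orders), which removes detector afterpulsing from the correlation. Lags are
evaluated over finite windows [dT, dT + ddT): a photon pair contributes to a
window when its macrotime difference falls inside it.

Correlation values are stored as the fluctuation part G(dT) - 1, i.e. an
uncorrelated (Poisson) stream gives 0 and correlations decay to 0 at large
lag; add 1 for the conventional display normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .photons import PhotonStream

__all__ = [
    "CorrelationCurve",
    "Map2D",
    "intensity_correlation",
    "lifetime_weighted_correlation",
    "correlation_ratio",
    "emission_delay_map",
    "subtract_uncorrelated",
    "uncorrelated_map_outer",
    "rebin_microtime",
    "log_binned_edges",
    "default_map_windows",
    "log_windows",
    "DEFAULT_BACKGROUND_WINDOW",
]

#: lag window used for the uncorrelated background map (s); correlation is
#: practically lost at these lags for millisecond-scale diffusion
DEFAULT_BACKGROUND_WINDOW = (0.1, 0.3)


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorrelationCurve:
    """G(dT) - 1 on a ladder of lag windows, with jackknife errors."""

    delta_T: np.ndarray          # window centres (geometric mean), s
    widths: np.ndarray           # window widths ddT, s
    values: np.ndarray           # G - 1
    errors: np.ndarray
    kind: str = "intensity"

    def __post_init__(self) -> None:
        for name in ("delta_T", "widths", "values", "errors"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.delta_T.size == self.widths.size == self.values.size
                == self.errors.size):
            raise ValueError("correlation curve arrays have mismatched lengths")
        if self.delta_T.size > 1 and np.any(np.diff(self.delta_T) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if np.any(self.errors < 0):
            raise ValueError("errors must be nonnegative")

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.delta_T, self.widths, self.values, self.errors]),
            header=f"kind={self.kind}\ndelta_T_s\twidth_s\tG_minus_1\terror",
        )


@dataclass
class Map2D:
    """dT-windowed 2D emission-delay histogram.

    ``counts`` is the symmetrized pair histogram (earlier-photon microtime
    along axis 0 plus its transpose); ``pair_count`` the number of ordered
    cross-channel pairs entering it, and ``expected_pairs`` the Poisson
    expectation used for normalization.
    """

    window: tuple[float, float]
    edges: np.ndarray                # microtime bin edges, ns
    counts: np.ndarray
    pair_count: int
    expected_pairs: float
    is_background_subtracted: bool = False
    variance: np.ndarray | None = None
    poisson_variance: np.ndarray | None = None
    stride: int = 1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("map must be square")
        if self.counts.shape[0] != self.edges.size - 1:
            raise ValueError("edges do not match the counts matrix")
        if not self.is_background_subtracted and np.any(self.counts < -1e-9):
            raise ValueError("raw map counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def symmetrized(self) -> "Map2D":
        c = 0.5 * (self.counts + self.counts.T)
        out = Map2D(self.window, self.edges, c, self.pair_count,
                    self.expected_pairs, self.is_background_subtracted,
                    None if self.variance is None else
                    0.5 * (self.variance + self.variance.T),
                    None if self.poisson_variance is None else
                    0.5 * (self.poisson_variance + self.poisson_variance.T),
                    self.stride)
        return out

    def normalized(self) -> np.ndarray:
        """Counts divided by the Poisson pair expectation."""
        return self.counts / self.expected_pairs


# ---------------------------------------------------------------------------
# lag ladders


def default_map_windows() -> list[tuple[float, float]]:
    """Log-spaced dT windows (s) for the 2D-map ladder, 0.2 us to 1 ms."""
    edges_us = [0.2, 1, 2, 4, 8, 12, 20, 35, 60, 100, 180, 320, 560, 1000]
    return [(a * 1e-6, b * 1e-6) for a, b in zip(edges_us[:-1], edges_us[1:])]


def log_windows(lo: float, hi: float, n: int) -> list[tuple[float, float]]:
    """Contiguous geometric lag windows from lo to hi (s)."""
    e = np.geomspace(lo, hi, n + 1)
    return [(float(a), float(b)) for a, b in zip(e[:-1], e[1:])]


# ---------------------------------------------------------------------------
# numba pair kernels


@njit(cache=True)
def _pair_counts(t, ch, u, seg, n_seg, lo, hi, stride):
    """Cross-channel pair count and microtime-product sum per time segment.

    ``stride`` subsamples the earlier photon of each pair; counts must be
    rescaled by the caller (the expectation is divided by the stride).
    """
    n = t.shape[0]
    cnt = np.zeros(n_seg)
    wsum = np.zeros(n_seg)
    j_lo = 0
    j_hi = 0
    for i in range(n):
        tlo = t[i] + lo
        thi = t[i] + hi
        if j_lo < i + 1:
            j_lo = i + 1
        while j_lo < n and t[j_lo] < tlo:
            j_lo += 1
        if j_hi < j_lo:
            j_hi = j_lo
        while j_hi < n and t[j_hi] < thi:
            j_hi += 1
        if i % stride != 0:
            continue
        s = seg[i]
        for j in range(j_lo, j_hi):
            if ch[j] != ch[i]:
                cnt[s] += 1.0
                wsum[s] += u[i] * u[j]
    return cnt, wsum


@njit(cache=True)
def _pair_map(t, ch, b, seg, n_seg, lo, hi, n_bins, stride):
    """Ordered (earlier, later) cross-channel microtime-pair histogram,
    resolved by macrotime segment of the earlier photon."""
    n = t.shape[0]
    counts = np.zeros((n_seg, n_bins, n_bins))
    n_pairs = 0
    j_lo = 0
    j_hi = 0
    for i in range(n):
        tlo = t[i] + lo
        thi = t[i] + hi
        if j_lo < i + 1:
            j_lo = i + 1
        while j_lo < n and t[j_lo] < tlo:
            j_lo += 1
        if j_hi < j_lo:
            j_hi = j_lo
        while j_hi < n and t[j_hi] < thi:
            j_hi += 1
        if i % stride != 0 or b[i] < 0:
            continue
        s = seg[i]
        for j in range(j_lo, j_hi):
            if ch[j] != ch[i] and b[j] >= 0:
                counts[s, b[i], b[j]] += 1.0
                n_pairs += 1
    return counts, n_pairs


# ---------------------------------------------------------------------------
# 1D correlators


def _check_two_channels(stream: PhotonStream) -> tuple[int, int]:
    n0 = int(np.sum(stream.channels == 0))
    n1 = int(np.sum(stream.channels == 1))
    if n0 == 0 or n1 == 0:
        raise ValueError(
            "correlators pair photons across two detector channels to avoid "
            "afterpulsing artifacts; this stream has a single channel"
        )
    return n0, n1


def _correlate(stream, windows, weighted, n_segments, max_pairs=2e7):
    n0, n1 = _check_two_channels(stream)
    t = stream.macrotimes
    ch = stream.channels
    u = stream.microtimes
    T0 = stream.duration
    seg = np.minimum((t / T0 * n_segments).astype(np.int64), n_segments - 1)
    u0 = u[ch == 0].mean()
    u1 = u[ch == 1].mean()
    centers, widths, vals, errs = [], [], [], []
    for lo, hi in windows:
        if not (0 < lo < hi < T0):
            raise ValueError(f"lag window ({lo}, {hi}) outside (0, T0)")
        width = hi - lo
        center = float(np.sqrt(lo * hi))
        # expectation for an uncorrelated stream; the end-of-trace availability
        # factor uses the arithmetic window mean (exact for uniform lag density)
        edge = max(1.0 - 0.5 * (lo + hi) / T0, 1e-12)
        expected_full = 2.0 * n0 * n1 * width / T0 * edge
        stride = max(1, int(np.ceil(expected_full / max_pairs)))
        cnt_s, wsum_s = _pair_counts(t, ch, u, seg, n_segments, lo, hi, stride)
        expected = expected_full / stride
        per_seg = wsum_s / (u0 * u1) if weighted else cnt_s
        total = per_seg.sum()
        g = total / expected - 1.0
        # delete-one jackknife over macrotime segments
        g_del = (total - per_seg) / (expected * (n_segments - 1) / n_segments) - 1.0
        err = float(np.sqrt((n_segments - 1) / n_segments
                            * np.sum((g_del - g_del.mean()) ** 2)))
        centers.append(center)
        widths.append(width)
        vals.append(g)
        errs.append(err)
    kind = "lifetime_weighted" if weighted else "intensity"
    return CorrelationCurve(np.array(centers), np.array(widths),
                            np.array(vals), np.array(errs), kind)


def intensity_correlation(
    stream: PhotonStream,
    windows: Sequence[tuple[float, float]] | None = None,
    n_segments: int = 32,
) -> CorrelationCurve:
    """Cross-channel fluorescence intensity correlation G_I(dT) - 1."""
    windows = windows if windows is not None else log_windows(1e-6, 0.05, 36)
    return _correlate(stream, windows, weighted=False, n_segments=n_segments)


def lifetime_weighted_correlation(
    stream: PhotonStream,
    windows: Sequence[tuple[float, float]] | None = None,
    n_segments: int = 32,
) -> CorrelationCurve:
    """Lifetime-weighted correlation G_L(dT) - 1.

    Each photon pair is weighted by the product of its microtimes and the sum
    normalized by the product of channel-mean microtimes, so a homogeneous
    single-lifetime sample gives G_L = G_I.
    """
    windows = windows if windows is not None else log_windows(1e-6, 0.05, 36)
    return _correlate(stream, windows, weighted=True, n_segments=n_segments)


def correlation_ratio(gl: CorrelationCurve, gi: CorrelationCurve) -> CorrelationCurve:
    """Pointwise ratio G_R = G_L / G_I (stored as G_R - 1), with errors."""
    if gl.delta_T.size != gi.delta_T.size or not np.allclose(gl.delta_T, gi.delta_T):
        raise ValueError("correlation ratio requires matching lag grids")
    L = gl.values + 1.0
    I = gi.values + 1.0
    r = L / I
    err = r * np.sqrt((gl.errors / np.maximum(np.abs(L), 1e-300)) ** 2
                      + (gi.errors / np.maximum(np.abs(I), 1e-300)) ** 2)
    return CorrelationCurve(gl.delta_T, gl.widths, r - 1.0, err, "ratio")


# ---------------------------------------------------------------------------
# 2D emission-delay maps


def _default_edges(stream: PhotonStream, n_channels: int = 256) -> np.ndarray:
    inst = stream.metadata.get("instrument", {})
    span = inst.get("microtime_channels", 4096) * inst.get(
        "microtime_resolution_ps", 3.0) * 1e-3
    return np.linspace(0.0, span, n_channels + 1)


def emission_delay_map(
    stream: PhotonStream,
    window: tuple[float, float],
    edges: np.ndarray | None = None,
    stride: int = 1,
    n_segments: int = 16,
) -> Map2D:
    """Histogram of microtime pairs (t' earlier, t'' later) for cross-channel
    photon pairs with macrotime difference inside ``window``, symmetrized.

    ``stride`` subsamples the earlier photon of each pair (every stride-th),
    which keeps wide background windows tractable; the pair expectation is
    scaled accordingly. Per-bin variances are estimated empirically from the
    scatter across ``n_segments`` macrotime blocks (floored at the Poisson
    value), which captures the super-Poissonian burst noise of single-
    molecule transits.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    n0, n1 = _check_two_channels(stream)
    edges = np.asarray(edges, dtype=float) if edges is not None else _default_edges(stream)
    b = np.searchsorted(edges, stream.microtimes, side="right") - 1
    b[(stream.microtimes < edges[0]) | (stream.microtimes >= edges[-1])] = -1
    seg = np.minimum((stream.macrotimes / stream.duration * n_segments).astype(np.int64),
                     n_segments - 1)
    counts_seg, n_pairs = _pair_map(
        stream.macrotimes, stream.channels, b.astype(np.int64),
        seg, n_segments, lo, hi, edges.size - 1, stride,
    )
    counts = counts_seg.sum(axis=0)
    edge = max(1.0 - 0.5 * (lo + hi) / stream.duration, 1e-12)
    expected = 2.0 * n0 * n1 * (hi - lo) / stream.duration * edge / stride
    sym = counts + counts.T
    # Empirical per-bin variance from the block scatter, floored at Poisson:
    # single-molecule pair counts are strongly super-Poissonian (burst
    # noise), and these variances keep the many-parameter map inversion from
    # chasing it. Data-estimated weights correlate with the noise, so
    # few-parameter amplitude fits use ``poisson_variance`` instead.
    sym_seg = counts_seg + counts_seg.transpose(0, 2, 1)
    mean_seg = sym_seg.mean(axis=0)
    var_emp = n_segments / max(n_segments - 1, 1) * np.sum(
        (sym_seg - mean_seg[None]) ** 2, axis=0)
    var = np.maximum(var_emp, sym + 1.0)
    return Map2D((lo, hi), edges, sym, int(n_pairs), expected,
                 variance=var, poisson_variance=sym + 1.0, stride=stride)


def uncorrelated_map_outer(stream: PhotonStream, edges: np.ndarray | None = None) -> Map2D:
    """Uncorrelated-background map built from the outer product of the
    per-channel 1D microtime histograms (the large-dT limit of the map)."""
    n0, n1 = _check_two_channels(stream)
    edges = np.asarray(edges, dtype=float) if edges is not None else _default_edges(stream)
    h0, _ = np.histogram(stream.microtimes[stream.channels == 0], bins=edges)
    h1, _ = np.histogram(stream.microtimes[stream.channels == 1], bins=edges)
    p0 = h0 / max(h0.sum(), 1)
    p1 = h1 / max(h1.sum(), 1)
    scale = n0 * n1 / stream.duration   # pseudo window width of 1 s
    counts = (np.outer(p0, p1) + np.outer(p1, p0)) * scale
    # normalized like the windowed maps: counts / expected sums to ~2
    # (both pair orders), matching the symmetrized histograms
    return Map2D((np.inf, np.inf), edges, counts, int(h0.sum() + h1.sum()),
                 scale, variance=np.abs(counts) + 1.0,
                 poisson_variance=np.abs(counts) + 1.0)


def subtract_uncorrelated(fore: Map2D, background: Map2D, scale: str = "expected") -> Map2D:
    """Subtract the uncorrelated part of a 2D map.

    The background map (built at a lag where correlation has decayed, or from
    the marginal outer product) is scaled to the foreground by the ratio of
    Poisson pair expectations — equivalently by the temporal window sizes —
    and subtracted. ``scale='pair_count'`` scales by observed pair counts
    instead. The result may contain negative noise values.
    """
    if fore.counts.shape != background.counts.shape or not np.allclose(
            fore.edges, background.edges):
        raise ValueError("foreground and background maps have different binning")
    if np.isfinite(background.window[0]):
        if fore.window[1] > background.window[0] and fore.window[0] < background.window[1]:
            raise ValueError("background window overlaps the foreground window")
    if scale == "expected":
        s = fore.expected_pairs / background.expected_pairs
    elif scale == "pair_count":
        s = fore.pair_count / max(background.pair_count, 1)
    else:
        raise ValueError(f"unknown scale mode {scale!r}")
    counts = fore.counts - s * background.counts
    var_f = fore.variance if fore.variance is not None else np.abs(fore.counts) + 1.0
    var_b = (background.variance if background.variance is not None
             else np.abs(background.counts) + 1.0)
    var = var_f + s ** 2 * var_b
    pvar_f = (fore.poisson_variance if fore.poisson_variance is not None
              else np.abs(fore.counts) + 1.0)
    pvar_b = (background.poisson_variance if background.poisson_variance is not None
              else np.abs(background.counts) + 1.0)
    return Map2D(fore.window, fore.edges, counts, fore.pair_count,
                 fore.expected_pairs, is_background_subtracted=True,
                 variance=var, poisson_variance=pvar_f + s ** 2 * pvar_b,
                 stride=fore.stride)


# ---------------------------------------------------------------------------
# microtime rebinning


def log_binned_edges(
    source_edges: np.ndarray, n_out: int = 24, t_max_ns: float = 6.144
) -> np.ndarray:
    """Logarithmically widening microtime bins over [0, t_max], snapped to the
    source channel grid so that rebinning conserves counts exactly."""
    source_edges = np.asarray(source_edges, dtype=float)
    dt = source_edges[1] - source_edges[0]
    n_src = int(round(t_max_ns / dt))
    if n_src > source_edges.size - 1:
        raise ValueError("analysis range exceeds the source map range")
    if n_out >= n_src:
        raise ValueError("target binning must be coarser than the source")

    # widths w_i = r^i (channels); solve sum w_i = n_src for the growth factor
    from scipy.optimize import brentq

    def excess(r):
        return (r ** n_out - 1.0) / (r - 1.0) - n_src

    r = brentq(excess, 1.0 + 1e-9, 4.0)
    cum = np.cumsum(r ** np.arange(n_out))
    idx = np.round(cum / cum[-1] * n_src).astype(int)
    idx = np.concatenate([[0], idx])
    # enforce strictly increasing integer channel edges
    for i in range(1, idx.size):
        if idx[i] <= idx[i - 1]:
            idx[i] = idx[i - 1] + 1
    idx[-1] = n_src
    if np.any(np.diff(idx) <= 0):
        raise ValueError("cannot build strictly increasing log bin edges")
    # rounding can make a width momentarily shrink; sorting the widths keeps
    # the same channel coverage while enforcing monotone widening
    widths = np.sort(np.diff(idx))
    idx = np.concatenate([[0], np.cumsum(widths)])
    return source_edges[0] + idx * dt


def _target_edges(m: Map2D, target) -> np.ndarray:
    if isinstance(target, (int, np.integer)):
        n_src = m.n_bins
        if n_src % int(target) != 0:
            raise ValueError(f"cannot rebin {n_src} channels into {target}")
        step = n_src // int(target)
        return m.edges[::step]
    if isinstance(target, str):
        if target == "log24":
            return log_binned_edges(m.edges, 24, 6.144)
        raise ValueError(f"unknown rebinning target {target!r}")
    return np.asarray(target, dtype=float)


def rebin_microtime(m: Map2D, target) -> Map2D:
    """Rebin a map onto coarser microtime bins; counts are conserved exactly
    over the covered range. ``target`` is an integer divisor binning (e.g.
    256), the string ``'log24'`` (logarithmically widening bins over
    0–6.144 ns) or an explicit edge array aligned with the source grid."""
    new_edges = _target_edges(m, target)
    if new_edges.size - 1 >= m.n_bins:
        raise ValueError("target binning must be coarser than the source")
    # map each source bin centre to a target bin (or drop it)
    centers = 0.5 * (m.edges[:-1] + m.edges[1:])
    dest = np.searchsorted(new_edges, centers, side="right") - 1
    dest[(centers < new_edges[0]) | (centers > new_edges[-1])] = -1
    dest[dest == new_edges.size - 1] = -1
    # verify alignment: every target edge must coincide with a source edge
    for e in new_edges:
        if np.min(np.abs(m.edges - e)) > 1e-9 * max(1.0, abs(e)):
            raise ValueError("target edges are not aligned with source edges")
    n_new = new_edges.size - 1
    keep = dest >= 0
    ii = np.nonzero(keep)[0]
    di = dest[ii]
    rows = di[:, None].repeat(ii.size, 1)
    cols = di[None, :].repeat(ii.size, 0)

    def _rebin(mat):
        if mat is None:
            return None
        out = np.zeros((n_new, n_new))
        np.add.at(out, (rows, cols), mat[np.ix_(ii, ii)])
        return out

    return Map2D(m.window, new_edges, _rebin(m.counts), m.pair_count,
                 m.expected_pairs, m.is_background_subtracted,
                 _rebin(m.variance), _rebin(m.poisson_variance), m.stride)
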