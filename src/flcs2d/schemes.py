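"""Kinetic schemes for multi-state fluorescent molecules.

A :class:`KineticScheme` bundles everything the simulator and the fitting
models need to know about a molecule: the photophysical states (fluorescence
lifetime, brightness, equilibrium population), the conformational exchange
network (pairwise equilibration times and equilibrium constants), the
translational diffusion through the confocal volume and the mean number of
molecules in the focus.

Exchange pairs form disjoint two-state systems or explicit chains (trees).
The rate matrix built from them obeys detailed balance with the declared
populations; inconsistencies raise :class:`SchemeValidationError` naming the
offending pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "State",
    "ExchangePair",
    "Diffusion",
    "KineticScheme",
    "SchemeValidationError",
    "build_rate_matrix",
    "stationary_distribution",
    "fixture_scheme",
    "FIXTURE_NAMES",
]

#: donor (unquenched) fluorescence lifetime used to scale FRET brightnesses, ns
DONOR_LIFETIME_NS = 4.0


class SchemeValidationError(ValueError):
    """A kinetic scheme violates one of its invariants."""


@dataclass(frozen=True)
class State:
    """One photophysical state of the molecule.

    Parameters
    ----------
    name : str
    lifetime_ns : float
        Fluorescence lifetime in ns; 0 denotes a dark (non-emissive) state.
    brightness_hz : float
        Detected count rate (photons/s) of a molecule of this state at the
        focus centre.
    population : float
        Equilibrium occupancy fraction (all states sum to 1).
    """

    name: str
    lifetime_ns: float
    brightness_hz: float
    population: float


@dataclass(frozen=True)
class ExchangePair:
    """Conformational exchange between two states.

    ``equilibrium_constant`` is the population ratio [b]/[a]; together with
    the equilibration time tau (1/(k_ab + k_ba), in microseconds) it fixes
    both rate constants.
    """

    state_a: str
    state_b: str
    equilibration_time_us: float
    equilibrium_constant: float

    @property
    def rates_per_us(self) -> tuple[float, float]:
        """(k_ab, k_bb->a) in 1/us, split by detailed balance."""
        K = self.equilibrium_constant
        total = 1.0 / self.equilibration_time_us
        k_ab = total * K / (1.0 + K)
        k_ba = total / (1.0 + K)
        return k_ab, k_ba


@dataclass(frozen=True)
class Diffusion:
    """Translational diffusion through the confocal volume."""

    diffusion_time_ms: float = 0.5
    radial_axial_ratio: float = 0.078


@dataclass
class KineticScheme:
    states: list[State]
    exchange_pairs: list[ExchangePair] = field(default_factory=list)
    diffusion: Diffusion = field(default_factory=Diffusion)
    mean_occupancy: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- introspection -------------------------------------------------
    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state_index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise SchemeValidationError(f"unknown state {name!r}") from None

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.states])

    @property
    def lifetimes_ns(self) -> np.ndarray:
        return np.array([s.lifetime_ns for s in self.states])

    @property
    def brightnesses_hz(self) -> np.ndarray:
        return np.array([s.brightness_hz for s in self.states])

    def validate(self) -> None:
        if not self.states:
            raise SchemeValidationError("scheme has no states")
        pops = self.populations
        if np.any(pops < 0) or not np.isclose(pops.sum(), 1.0, atol=1e-6):
            raise SchemeValidationError(
                f"state populations must be nonnegative and sum to 1 "
                f"(got sum {pops.sum():.6g})"
            )
        if np.any(self.brightnesses_hz < 0):
            raise SchemeValidationError("brightness must be >= 0")
        seen = set()
        for p in self.exchange_pairs:
            ia, ib = self.state_index(p.state_a), self.state_index(p.state_b)
            if p.equilibration_time_us <= 0:
                raise SchemeValidationError(
                    f"pair {p.state_a}<->{p.state_b}: equilibration time must be > 0"
                )
            if p.equilibrium_constant <= 0:
                raise SchemeValidationError(
                    f"pair {p.state_a}<->{p.state_b}: equilibrium constant must be > 0"
                )
            key = frozenset((ia, ib))
            if ia == ib or key in seen:
                raise SchemeValidationError(
                    f"pair {p.state_a}<->{p.state_b} is degenerate or duplicated"
                )
            seen.add(key)
            # detailed balance against the declared populations
            pa, pb = pops[ia], pops[ib]
            if pa > 0 and pb > 0:
                ratio = pb / pa
                if not np.isclose(ratio, p.equilibrium_constant, rtol=1e-3):
                    raise SchemeValidationError(
                        f"pair {p.state_a}<->{p.state_b}: equilibrium constant "
                        f"{p.equilibrium_constant:.4g} inconsistent with the declared "
                        f"populations (ratio {ratio:.4g})"
                    )
        d = self.diffusion
        if d.diffusion_time_ms <= 0 or not (0 < d.radial_axial_ratio < 1):
            raise SchemeValidationError("diffusion parameters out of range")
        if self.mean_occupancy <= 0:
            raise SchemeValidationError("mean occupancy must be > 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": [asdict(s) for s in self.states],
            "exchange_pairs": [asdict(p) for p in self.exchange_pairs],
            "diffusion": asdict(self.diffusion),
            "mean_occupancy": self.mean_occupancy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            states=[State(**s) for s in d["states"]],
            exchange_pairs=[ExchangePair(**p) for p in d.get("exchange_pairs", [])],
            diffusion=Diffusion(**d.get("diffusion", {})),
            mean_occupancy=d.get("mean_occupancy", 1.0),
            name=d.get("name", ""),
        )


def build_rate_matrix(scheme: KineticScheme) -> np.ndarray:
    """State-transition rate matrix Q (1/us), rows summing to zero.

    Q[i, j] for i != j is the transition rate from state i to state j; each
    exchange pair contributes k_ab + k_ba = 1/tau with k_ab/k_ba equal to its
    equilibrium constant (detailed balance).
    """
    n = len(scheme.states)
    Q = np.zeros((n, n))
    for p in scheme.exchange_pairs:
        ia, ib = scheme.state_index(p.state_a), scheme.state_index(p.state_b)
        k_ab, k_ba = p.rates_per_us
        Q[ia, ib] += k_ab
        Q[ib, ia] += k_ba
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray, populations: np.ndarray | None = None) -> np.ndarray:
    """Stationary distribution of the rate matrix.

    The exchange network may be disconnected; within each connected component
    the stationary weights follow from the rates, while the relative weight of
    each component is taken from ``populations`` (uniform if omitted).
    """
    n = Q.shape[0]
    if populations is None:
        populations = np.full(n, 1.0 / n)
    adj = (Q > 0) | (Q.T > 0)
    np.fill_diagonal(adj, True)
    unassigned = set(range(n))
    pi = np.zeros(n)
    while unassigned:
        root = next(iter(unassigned))
        comp = {root}
        frontier = [root]
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(adj[i])[0]:
                if j not in comp:
                    comp.add(int(j))
                    frontier.append(int(j))
        comp_idx = sorted(comp)
        unassigned -= comp
        sub = Q[np.ix_(comp_idx, comp_idx)]
        if len(comp_idx) == 1:
            w = np.array([1.0])
        else:
            # left null vector of the sub-generator
            vals, vecs = np.linalg.eig(sub.T)
            k = int(np.argmin(np.abs(vals)))
            w = np.real(vecs[:, k])
            w = np.abs(w)
            w = w / w.sum()
        pi[comp_idx] = w * populations[comp_idx].sum()
    return pi


def _fret_brightness(lifetime_ns: float, q_donor_hz: float) -> float:
    """Brightness of a FRET-quenched state, proportional to its lifetime."""
    return q_donor_hz * lifetime_ns / DONOR_LIFETIME_NS


FIXTURE_NAMES = ("scheme1", "scheme2", "dye_only", "bright_dark")


def fixture_scheme(name: str) -> KineticScheme:
    """Documented cytochrome-c-like parameter sets.

    ``scheme1``
        Two-state native/intermediate exchange: lifetimes 70 ps and 280 ps,
        equilibration time 5 us, equilibrium constant K = 0.25.
    ``scheme2``
        Seven substates N, I1, I2, I3, U plus two dark states D1, D2, grouped
        into three ensembles that exchange internally on the microsecond
        timescale (N<->I1 5 us; I2<->I3 0.3 us; I-ensemble<->D1 7 us;
        U<->D2 4 us) and not at all between ensembles on the simulated
        timescale.
    ``dye_only``
        A single bright state with the free-donor lifetime 4.0 ns; the
        focal-geometry reference.
    ``bright_dark``
        One emissive state (1.7 ns) exchanging with one dark state at 7 us,
        the isolated intermediate-ensemble/dark pair.

    All fixtures share the focal geometry w = 0.078 and a diffusion time of
    0.5 ms; brightnesses scale with lifetime (FRET quenching at constant
    extinction) and are chosen so that a trace of order a minute carries the
    photon numbers the downstream statistics need.
    """
    diff = Diffusion(diffusion_time_ms=0.5, radial_axial_ratio=0.078)
    if name == "dye_only":
        return KineticScheme(
            states=[State("dye", 4.0, 1.0e5, 1.0)],
            exchange_pairs=[],
            diffusion=diff,
            mean_occupancy=1.0,
            name="dye_only",
        )
    if name == "scheme1":
        q0 = 4.0e6  # unquenched-donor brightness scale, Hz at focus centre
        K = 0.25
        f_n = 1.0 / (1.0 + K)
        return KineticScheme(
            states=[
                State("N", 0.070, _fret_brightness(0.070, q0), f_n),
                State("I1", 0.280, _fret_brightness(0.280, q0), 1.0 - f_n),
            ],
            exchange_pairs=[ExchangePair("N", "I1", 5.0, K)],
            diffusion=diff,
            mean_occupancy=1.0,
            name="scheme1",
        )
    if name == "bright_dark":
        K = 0.5
        f_b = 1.0 / (1.0 + K)
        return KineticScheme(
            states=[
                State("B", 1.7, 4.25e5, f_b),
                State("D", 0.0, 0.0, 1.0 - f_b),
            ],
            exchange_pairs=[ExchangePair("B", "D", 7.0, K)],
            diffusion=diff,
            mean_occupancy=1.0,
            name="bright_dark",
        )
    if name == "scheme2":
        q0 = 2.0e6
        # ensemble fractions and within-ensemble equilibria
        g_nen, g_ien, g_uen = 0.40, 0.35, 0.25
        K_ni = 0.25            # [I1]/[N]
        K_23 = 1.0             # [I3]/[I2]
        K_id = 0.5             # [D1]/([I2]+[I3])
        K_ud = 0.5             # [D2]/[U]
        a_n = g_nen / (1 + K_ni)
        a_i1 = g_nen - a_n
        a_ibright = g_ien / (1 + K_id)
        a_d1 = g_ien - a_ibright
        a_i2 = a_ibright / (1 + K_23)
        a_i3 = a_ibright - a_i2
        a_u = g_uen / (1 + K_ud)
        a_d2 = g_uen - a_u
        # The D1 edge hangs off I3; choose its pair time so that, with I2/I3
        # pre-equilibrated, the slow I-ensemble<->D1 relaxation is 7 us:
        # relaxation rate = phi3*k_3D + k_D3 with k_3D/k_D3 = a_D1/a_I3.
        tau_id_target = 7.0
        phi3 = a_i3 / (a_i2 + a_i3)
        K_edge = a_d1 / a_i3
        k_d3 = 1.0 / (tau_id_target * (1.0 + phi3 * K_edge))
        k_3d = K_edge * k_d3
        tau_edge = 1.0 / (k_3d + k_d3)
        return KineticScheme(
            states=[
                State("N", 0.070, _fret_brightness(0.070, q0), a_n),
                State("I1", 0.280, _fret_brightness(0.280, q0), a_i1),
                State("I2", 0.300, _fret_brightness(0.300, q0), a_i2),
                State("I3", 1.7, _fret_brightness(1.7, q0), a_i3),
                State("U", 3.3, _fret_brightness(3.3, q0), a_u),
                State("D1", 0.0, 0.0, a_d1),
                State("D2", 0.0, 0.0, a_d2),
            ],
            exchange_pairs=[
                ExchangePair("N", "I1", 5.0, K_ni),
                ExchangePair("I2", "I3", 0.3, K_23),
                ExchangePair("I3", "D1", tau_edge, K_edge),
                ExchangePair("U", "D2", 4.0, K_ud),
            ],
            diffusion=diff,
            mean_occupancy=1.0,
            name="scheme2",
        )
    raise SchemeValidationError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
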