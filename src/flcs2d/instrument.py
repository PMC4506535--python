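"""Instrument model: TCSPC timing, IRF and detector layout."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["InstrumentModel"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class InstrumentModel:
    """Confocal TCSPC detection parameters.

    The defaults follow a two-detector confocal setup with a ~50 ps FWHM
    Gaussian instrument response, a 4096-channel TCSPC module at 3 ps per
    channel and a 9.5 ns usable microtime window. The excitation repetition
    period defaults to 13.16 ns (76 MHz), the usual mode-locked Ti:sapphire
    rate consistent with a 9.5 ns detection span.
    """

    irf_fwhm_ps: float = 50.0
    irf_center_ns: float = 0.25
    tcspc_window_ns: float = 9.5
    microtime_channels: int = 4096
    microtime_resolution_ps: float = 3.0
    excitation_rep_period_ns: float = 13.16
    n_detectors: int = 2
    detector_split_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.irf_fwhm_ps <= 0:
            raise ValueError("IRF FWHM must be > 0")
        span_ns = self.microtime_channels * self.microtime_resolution_ps * 1e-3
        if span_ns < self.tcspc_window_ns:
            raise ValueError(
                f"microtime span {span_ns:.3f} ns does not cover the "
                f"TCSPC window {self.tcspc_window_ns:.3f} ns"
            )
        if self.n_detectors < 2:
            raise ValueError("at least two detectors are required")
        if not (0 < self.detector_split_fraction < 1):
            raise ValueError("detector split fraction must be in (0, 1)")

    @property
    def irf_sigma_ns(self) -> float:
        return self.irf_fwhm_ps * 1e-3 * _FWHM_TO_SIGMA

    @property
    def microtime_span_ns(self) -> float:
        return self.microtime_channels * self.microtime_resolution_ps * 1e-3

    def channel_edges_ns(self, n_channels: int | None = None) -> np.ndarray:
        """Uniform microtime bin edges covering the full channel span."""
        n = n_channels or self.microtime_channels
        return np.linspace(0.0, self.microtime_span_ns, n + 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentModel":
        return cls(**d)
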