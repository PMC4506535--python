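"""Run configuration, checkpointed pipeline orchestration and reports."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (
    bright_dark_analysis,
    dye_reference_analysis,
    two_state_analysis,
)
from .correlate import (
    correlation_ratio,
    intensity_correlation,
    lifetime_weighted_correlation,
    log_windows,
)
from .instrument import InstrumentModel
from .photons import read_photons, write_photons
from .schemes import KineticScheme, fixture_scheme
from .simulate import simulate_stream

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

log = logging.getLogger("flcs2d")

#: default analysis mode per fixture
_ANALYSIS_FOR_SCHEME = {
    "dye_only": "dye",
    "scheme1": "two_state",
    "bright_dark": "bright_dark",
    "scheme2": "species_count",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``scheme`` is a fixture name or an inline scheme dict; every run writes a
    frozen copy of its resolved configuration next to its outputs, and all
    artifact files carry the configuration hash.
    """

    scheme: str | dict = "dye_only"
    instrument: dict = field(default_factory=dict)
    duration_s: float = 5.0
    seed: int = 0
    analysis: str = "auto"           # dye | two_state | bright_dark | none
    map_windows_us: list | None = None
    mem: dict = field(default_factory=lambda: {"eta": "auto", "restarts": 6})
    fit: dict = field(default_factory=dict)
    output_dir: str = "flcs2d_run"

    def resolved_scheme(self) -> KineticScheme:
        if isinstance(self.scheme, str):
            return fixture_scheme(self.scheme)
        return KineticScheme.from_dict(self.scheme)

    def resolved_instrument(self) -> InstrumentModel:
        return InstrumentModel(**self.instrument)

    def resolved_analysis(self) -> str:
        if self.analysis != "auto":
            return self.analysis
        name = self.scheme if isinstance(self.scheme, str) else ""
        return _ANALYSIS_FOR_SCHEME.get(name, "none")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    return RunConfig(**data)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stages: dict
    headline: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


def _stage(outdir: Path, cfg_hash: str, name: str, suffix: str) -> Path:
    return outdir / f"{cfg_hash}_{name}{suffix}"


def run_pipeline(config: RunConfig, force: bool = False) -> RunReport:
    """Execute simulate -> correlate -> maps/ILT -> fit with checkpointing.

    Stage outputs are keyed by the configuration hash; an existing photon
    checkpoint with the right hash is reused unless ``force`` is set.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    with open(outdir / f"{h}_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)

    stages: dict = {}
    t_start = time.time()
    scheme = config.resolved_scheme()
    instrument = config.resolved_instrument()

    photons_path = _stage(outdir, h, "photons", ".h5")
    if photons_path.exists() and not force:
        log.info("stage simulate: reusing %s", photons_path)
        stream = read_photons(photons_path)
    else:
        stream = simulate_stream(scheme, instrument, config.duration_s,
                                 config.seed)
        stream.metadata["config_hash"] = h
        write_photons(stream, photons_path)
    stages["photons"] = str(photons_path)
    log.info("simulate: %d photons in %.1f s trace", len(stream), stream.duration)

    # 1D correlators
    hi_lag = min(0.05, stream.duration / 20.0)
    wins = log_windows(1e-6, hi_lag, 32)
    gi = intensity_correlation(stream, wins)
    gl = lifetime_weighted_correlation(stream, wins)
    gr = correlation_ratio(gl, gi)
    for name, curve in (("GI", gi), ("GL", gl), ("GR", gr)):
        p = _stage(outdir, h, name, ".tsv")
        curve.to_tsv(p)
        stages[name] = str(p)

    headline: dict = {"n_photons": len(stream), "count_rate_hz": stream.count_rate}
    mode = config.resolved_analysis()
    windows = None
    if config.map_windows_us:
        windows = [(a * 1e-6, b * 1e-6) for a, b in config.map_windows_us]

    if mode == "dye":
        _, fit = dye_reference_analysis(stream)
        headline.update({"N": fit.N, "tau_diff_ms": fit.tau_diff_ms, "w": fit.w})
        stages["fit"] = "dye_reference"
    elif mode == "two_state":
        res = two_state_analysis(stream, w=scheme.diffusion.radial_axial_ratio,
                                 windows=windows, seed=config.seed,
                                 restarts=config.mem.get("restarts", 6),
                                 eta=config.mem.get("eta", "auto"))
        fit = res["fit"]
        headline.update({
            "n_species": res["decomposition"].n_species,
            "K": res["K"], "tau_R_us": fit.tau_R_us,
            "tau_diff_ms": fit.tau_diff_ms, "N_pair": fit.N_pair,
        })
        dec_path = _stage(outdir, h, "decomposition", ".json")
        _write_decomposition(res["decomposition"], dec_path)
        stages["decomposition"] = str(dec_path)
    elif mode == "bright_dark":
        res = bright_dark_analysis(
            stream, tau_diff_ms=scheme.diffusion.diffusion_time_ms,
            w=scheme.diffusion.radial_axial_ratio, windows=windows,
            seed=config.seed)
        fit = res["fit"]
        headline.update({
            "tau_R_us": fit.tau_R_us, "amplitude": fit.amplitude,
            "relaxation_required": res["comparison"]["relaxation_required"],
        })
    elif mode == "species_count":
        from .analysis import build_map_series, ensemble_prior
        from .ilt import select_species_number

        wins = windows or [(0.2e-6, 4e-6), (12e-6, 20e-6), (50e-6, 100e-6)]
        series = build_map_series(stream, wins)
        prior = ensemble_prior(stream, series.edges)
        n_star = {}
        for wdw, m in zip(series.windows, series.maps):
            n, _ = select_species_number(
                m, prior=prior, seed=config.seed % 1000,
                restarts=config.mem.get("restarts", 6),
                eta=config.mem.get("eta", "auto"))
            n_star[f"{wdw[0] * 1e6:g}-{wdw[1] * 1e6:g}us"] = n
        headline["n_star_per_window"] = n_star
    elif mode != "none":
        raise ValueError(f"unknown analysis mode {mode!r}")

    log.info("pipeline finished in %.1f s", time.time() - t_start)
    report = RunReport(h, config.seed, __version__, stages, headline)
    report.to_json(outdir / f"{h}_report.json")
    return report


def _write_decomposition(dec, path: Path) -> None:
    payload = {
        "grid_ns": dec.grid.tolist(),
        "distributions": [d.amplitudes.tolist() for d in dec.distributions],
        "C": dec.C.tolist(),
        "edges_ns": dec.edges.tolist(),
        "diagnostics": {k: v for k, v in dec.diagnostics.items()
                        if isinstance(v, (int, float, bool, str))},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
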