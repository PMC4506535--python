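"""Photon-record streams and their on-disk formats.

A :class:`PhotonStream` is the universal currency of the package: per-photon
macrotime (absolute arrival time, seconds), microtime (TCSPC emission delay,
nanoseconds) and detector channel, plus acquisition metadata and — for
simulated streams — the ground-truth state label of the emitting molecule.

Two interchangeable formats are provided: a columnar TSV dialect with
"#"-prefixed header metadata, and an HDF5 layout following Photon-HDF5 field
naming (photon_data/timestamps, photon_data/nanotimes, photon_data/detectors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["PhotonStream", "read_photons", "write_photons", "PhotonFileError"]


class PhotonFileError(IOError):
    """A photon file is malformed or violates stream invariants."""


@dataclass
class PhotonStream:
    """Time-ordered photon records from a confocal TCSPC measurement."""

    macrotimes: np.ndarray          # seconds, non-decreasing
    microtimes: np.ndarray          # ns, in [0, tcspc window)
    channels: np.ndarray            # small integer detector id
    duration: float                 # total measurement time T0, seconds
    metadata: dict = field(default_factory=dict)
    labels: np.ndarray | None = None  # optional ground-truth state index

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=np.float64)
        self.microtimes = np.asarray(self.microtimes, dtype=np.float64)
        self.channels = np.asarray(self.channels, dtype=np.int8)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
        n = self.macrotimes.size
        if not (self.microtimes.size == n and self.channels.size == n):
            raise ValueError("photon record columns have mismatched lengths")
        if n and np.any(np.diff(self.macrotimes) < 0):
            raise ValueError("macrotimes must be non-decreasing")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    def __len__(self) -> int:
        return int(self.macrotimes.size)

    @property
    def n_photons(self) -> int:
        return len(self)

    @property
    def count_rate(self) -> float:
        return len(self) / self.duration

    def channel_mask(self, channel: int) -> np.ndarray:
        return self.channels == channel

    def select(self, mask: np.ndarray) -> "PhotonStream":
        return PhotonStream(
            self.macrotimes[mask],
            self.microtimes[mask],
            self.channels[mask],
            self.duration,
            dict(self.metadata),
            None if self.labels is None else self.labels[mask],
        )

    def time_slice(self, t0: float, t1: float) -> "PhotonStream":
        i0, i1 = np.searchsorted(self.macrotimes, [t0, t1])
        out = PhotonStream(
            self.macrotimes[i0:i1] - t0,
            self.microtimes[i0:i1],
            self.channels[i0:i1],
            t1 - t0,
            dict(self.metadata),
            None if self.labels is None else self.labels[i0:i1],
        )
        return out


# ---------------------------------------------------------------------------
# columnar TSV format


def _write_tsv(stream: PhotonStream, path: Path) -> None:
    meta = dict(stream.metadata)
    meta["duration_s"] = stream.duration
    meta["n_photons"] = len(stream)
    with open(path, "w") as fh:
        fh.write("# flcs2d photon stream v1\n")
        fh.write("# metadata: " + json.dumps(meta, default=str) + "\n")
        cols = ["macrotime_s", "microtime_ns", "channel"]
        if stream.labels is not None:
            cols.append("state")
        fh.write("# columns: " + "\t".join(cols) + "\n")
        for i in range(len(stream)):
            row = f"{stream.macrotimes[i]:.9f}\t{stream.microtimes[i]:.4f}\t{stream.channels[i]:d}"
            if stream.labels is not None:
                row += f"\t{stream.labels[i]:d}"
            fh.write(row + "\n")


def _read_tsv(path: Path) -> PhotonStream:
    meta: dict = {}
    data_rows: list[str] = []
    has_labels = False
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# flcs2d photon stream"):
            raise PhotonFileError(f"{path}: missing photon-stream header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# metadata:"):
                    meta = json.loads(line.split(":", 1)[1])
                elif line.startswith("# columns:"):
                    has_labels = "state" in line
                continue
            data_rows.append(line)
    ncol = 4 if has_labels else 3
    mac = np.empty(len(data_rows))
    mic = np.empty(len(data_rows))
    ch = np.empty(len(data_rows), dtype=np.int8)
    lab = np.empty(len(data_rows), dtype=np.int8) if has_labels else None
    for i, row in enumerate(data_rows):
        parts = row.split("\t")
        if len(parts) != ncol:
            raise PhotonFileError(f"{path}: malformed record {i} ({row!r})")
        mac[i] = float(parts[0])
        mic[i] = float(parts[1])
        ch[i] = int(parts[2])
        if lab is not None:
            lab[i] = int(parts[3])
    if mac.size and np.any(np.diff(mac) < 0):
        bad = int(np.nonzero(np.diff(mac) < 0)[0][0]) + 1
        raise PhotonFileError(f"{path}: non-monotone macrotime at record {bad}")
    duration = float(meta.pop("duration_s", mac[-1] if mac.size else 1.0))
    n_expected = meta.pop("n_photons", None)
    if n_expected is not None and int(n_expected) != mac.size:
        raise PhotonFileError(
            f"{path}: header declares {n_expected} photons, file holds {mac.size} "
            "(truncated file?)"
        )
    return PhotonStream(mac, mic, ch, duration, meta, lab)


# ---------------------------------------------------------------------------
# HDF5 (Photon-HDF5-style field naming)


def _write_hdf5(stream: PhotonStream, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.macrotimes)
        g["timestamps"].attrs["units"] = "s"
        g.create_dataset("nanotimes", data=stream.microtimes)
        g["nanotimes"].attrs["units"] = "ns"
        g.create_dataset("detectors", data=stream.channels)
        if stream.labels is not None:
            g.create_dataset("state_labels", data=stream.labels)
        f.attrs["acquisition_duration"] = stream.duration
        f.attrs["metadata_json"] = json.dumps(stream.metadata, default=str)


def _read_hdf5(path: Path) -> PhotonStream:
    with h5py.File(path, "r") as f:
        if "photon_data" not in f:
            raise PhotonFileError(f"{path}: no photon_data group")
        g = f["photon_data"]
        mac = np.asarray(g["timestamps"])
        mic = np.asarray(g["nanotimes"])
        ch = np.asarray(g["detectors"])
        lab = np.asarray(g["state_labels"]) if "state_labels" in g else None
        duration = float(f.attrs["acquisition_duration"])
        meta = json.loads(f.attrs.get("metadata_json", "{}"))
    if mac.size and np.any(np.diff(mac) < 0):
        bad = int(np.nonzero(np.diff(mac) < 0)[0][0]) + 1
        raise PhotonFileError(f"{path}: non-monotone macrotime at record {bad}")
    return PhotonStream(mac, mic, ch, duration, meta, lab)


def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    if path.suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "tsv"


def write_photons(stream: PhotonStream, path: str | Path, fmt: str | None = None) -> Path:
    """Write a photon stream to TSV (default) or HDF5 (by suffix or ``fmt``)."""
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "tsv":
        _write_tsv(stream, path)
    elif fmt == "hdf5":
        _write_hdf5(stream, path)
    else:
        raise PhotonFileError(f"unknown photon format {fmt!r}")
    return path


def read_photons(path: str | Path, fmt: str | None = None) -> PhotonStream:
    """Read a photon stream, auto-detecting the format from the suffix."""
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise PhotonFileError(f"unknown photon format {fmt!r}")


def stream_summary(path: str | Path) -> dict:
    """Metadata-only query (photon count, duration) without loading records."""
    path = Path(path)
    if _resolve_format(path, None) == "hdf5":
        with h5py.File(path, "r") as f:
            return {
                "n_photons": int(f["photon_data/timestamps"].shape[0]),
                "duration_s": float(f.attrs["acquisition_duration"]),
            }
    with open(path) as fh:
        if not fh.readline().startswith("# flcs2d photon stream"):
            raise PhotonFileError(f"{path}: not a photon stream file")
        for line in fh:
            if line.startswith("# metadata:"):
                meta = json.loads(line.split(":", 1)[1])
                return {
                    "n_photons": int(meta.get("n_photons", -1)),
                    "duration_s": float(meta.get("duration_s", -1.0)),
                }
            if not line.startswith("#"):
                break
    raise PhotonFileError(f"{path}: metadata header not found")
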