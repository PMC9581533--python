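"""Containers and I/O for TCSPC decay histograms and FLIM photon cubes.

A :class:`DecayHistogram` is a single photon-arrival-time histogram (one
cell or one binned pixel); a :class:`PhotonCube` is a full FLIM image with
one histogram per pixel, stored as ``counts[t, y, x]``.  Cubes round-trip
through HDF5; single curves through two-column CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .instrument import InstrumentModel

#: Photon floor below which a per-curve analysis is flagged as unreliable.
LOW_PHOTON_FLOOR = 5000


@dataclass
class DecayHistogram:
    """Photon counts per TCSPC time channel for one decay curve.

    ``truth`` optionally carries the ground-truth simulation parameters
    (a :class:`~tpeflim.synthetic_data.CellSample`) for recovery tests.
    """

    counts: np.ndarray
    instrument: InstrumentModel
    t0_channel: int = 0
    truth: Optional[object] = None
    warn_low_photons: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.counts) != self.instrument.n_channels:
            raise ValueError(
                "counts length does not match instrument.n_channels"
            )
        self.warn_low_photons = self.n_photons < LOW_PHOTON_FLOOR

    @property
    def n_photons(self) -> int:
        return int(round(float(self.counts.sum())))

    @property
    def channel_width(self) -> float:
        return self.instrument.channel_width

    @property
    def times(self) -> np.ndarray:
        """Channel-center times in ps."""
        return self.instrument.channel_centers


@dataclass
class PhotonCube:
    """FLIM image cube of per-pixel TCSPC histograms, ``counts[t, y, x]``."""

    counts: np.ndarray
    instrument: InstrumentModel
    labels: Optional[np.ndarray] = None  # per-pixel ground-truth class, -1 = background

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (t, y, x)")
        if self.counts.shape[0] != self.instrument.n_channels:
            raise ValueError("first axis must match instrument.n_channels")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.counts.shape[1:]:
                raise ValueError("labels shape must match image shape")

    @property
    def shape(self) -> tuple:
        """Image shape ``(ny, nx)``."""
        return self.counts.shape[1:]

    def intensity(self) -> np.ndarray:
        """Total counts per pixel (summed over time channels)."""
        return self.counts.sum(axis=0)

    def pixel_histogram(self, y: int, x: int) -> DecayHistogram:
        return DecayHistogram(self.counts[:, y, x].astype(np.float64),
                              self.instrument)


def write_cube(path, cube: PhotonCube) -> None:
    """Write a :class:`PhotonCube` to HDF5 (``counts[t, y, x]`` + attrs)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=cube.counts.astype(np.uint32))
        d.attrs["time_resolution_ps"] = cube.instrument.channel_width
        d.attrs["repetition_rate_hz"] = cube.instrument.repetition_rate
        d.attrs["irf_fwhm_ps"] = cube.instrument.irf_fwhm
        d.attrs["background_rate"] = cube.instrument.background_rate
        if cube.labels is not None:
            f.create_dataset("truth/label", data=cube.labels.astype(np.int16))


def read_cube(path) -> PhotonCube:
    """Read a :class:`PhotonCube` written by :func:`write_cube`."""
    with h5py.File(path, "r") as f:
        d = f["counts"]
        counts = d[...]
        instrument = InstrumentModel(
            repetition_rate=float(d.attrs["repetition_rate_hz"]),
            n_channels=counts.shape[0],
            irf_fwhm=float(d.attrs["irf_fwhm_ps"]),
            background_rate=float(d.attrs.get("background_rate", 0.0)),
        )
        labels = f["truth/label"][...] if "truth/label" in f else None
    return PhotonCube(counts=counts, instrument=instrument, labels=labels)


def write_curve_csv(path, hist: DecayHistogram) -> None:
    """Write a single decay curve as two-column CSV (time_ps, counts)."""
    times = hist.times
    with open(path, "w", newline="") as f:
        f.write("time_ps,counts\n")
        for t, c in zip(times, hist.counts):
            f.write(f"{t:.6g},{int(round(c))}\n")


def read_curve_csv(path, instrument: Optional[InstrumentModel] = None) -> DecayHistogram:
    """Read a two-column (time_ps, counts) CSV into a :class:`DecayHistogram`.

    When no instrument is given, the repetition rate and channel count are
    inferred from the time axis (assuming the curve spans one full period).
    """
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_ps, counts)")
    times, counts = data[:, 0], data[:, 1]
    if instrument is None:
        n = len(times)
        dt = float(np.median(np.diff(times)))
        instrument = InstrumentModel(
            repetition_rate=1.0e12 / (n * dt), n_channels=n
        )
    return DecayHistogram(counts=counts, instrument=instrument)


__all__ = [
    "DecayHistogram",
    "PhotonCube",
    "LOW_PHOTON_FLOOR",
    "write_cube",
    "read_cube",
    "write_curve_csv",
    "read_curve_csv",
]
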