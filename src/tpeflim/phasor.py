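"""First-harmonic phasor analysis of fluorescence decays.

A decay is mapped to the point ``g + i*s`` given by the first Fourier
component at the laser repetition frequency: ``g`` is the cosine
(in-phase) and ``s`` the sine (quadrature) projection, both normalised by
total intensity.  Single-exponential decays lie on the universal
semicircle ``(g - 1/2)^2 + s^2 = 1/4``; a bi-exponential decay lies on the
chord between its two component points, at the position set by the
intensity fractions ``f_i = a_i tau_i / (a1 tau1 + a2 tau2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decay_fitting import BiExpFit
from .histograms import DecayHistogram, PhotonCube


@dataclass(frozen=True)
class PhasorPoint:
    """One point of the phasor plot."""

    g: float
    s: float
    harmonic: int = 1
    omega: float = 2.0 * math.pi * 8.0e7  # rad/s


def phasor_transform(hist: DecayHistogram, harmonic: int = 1,
                     subtract_offset: Optional[float] = None) -> PhasorPoint:
    """Discrete first-harmonic (or higher) phasor of a measured histogram.

    Uses channel-center times over one excitation period; a known uniform
    background can be subtracted before the projection.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if subtract_offset:
        counts = np.maximum(counts - subtract_offset, 0.0)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    omega_hz = 2.0 * math.pi * harmonic * hist.instrument.repetition_rate
    phase = omega_hz * hist.times * 1e-12  # ps -> s
    g = float(np.sum(counts * np.cos(phase)) / total)
    s = float(np.sum(counts * np.sin(phase)) / total)
    return PhasorPoint(g=g, s=s, harmonic=harmonic, omega=omega_hz)


def phasor_from_lifetime(tau_ps: float, repetition_rate: float = 8.0e7,
                         harmonic: int = 1) -> PhasorPoint:
    """Closed-form phasor of a single-exponential decay (on the semicircle)."""
    omega = 2.0 * math.pi * harmonic * repetition_rate
    wt = omega * tau_ps * 1e-12
    d = 1.0 + wt * wt
    return PhasorPoint(g=1.0 / d, s=wt / d, harmonic=harmonic, omega=omega)


def phasor_from_fit(fit: BiExpFit, repetition_rate: float = 8.0e7,
                    harmonic: int = 1) -> PhasorPoint:
    """Analytic phasor of a fitted bi-exponential decay.

    The intensity-fraction-weighted combination of the two component
    phasors; the point lies on the chord between the tau1 and tau2 points
    of the universal semicircle.
    """
    p1 = phasor_from_lifetime(fit.tau1, repetition_rate, harmonic)
    p2 = phasor_from_lifetime(fit.tau2, repetition_rate, harmonic)
    i1 = fit.a1 * fit.tau1
    i2 = fit.a2 * fit.tau2
    f1 = i1 / (i1 + i2)
    return PhasorPoint(
        g=f1 * p1.g + (1.0 - f1) * p2.g,
        s=f1 * p1.s + (1.0 - f1) * p2.s,
        harmonic=harmonic, omega=p1.omega,
    )


def calibrate(point: PhasorPoint, measured_ref: PhasorPoint,
              true_ref: PhasorPoint) -> PhasorPoint:
    """Correct a measured phasor with a mono-exponential reference.

    The IRF and electronics rotate and scale every phasor by the same
    complex factor; dividing by the measured reference and multiplying by
    its known true position undoes that.
    """
    z = complex(point.g, point.s)
    zm = complex(measured_ref.g, measured_ref.s)
    zt = complex(true_ref.g, true_ref.s)
    if zm == 0:
        raise ValueError("degenerate reference phasor")
    out = z / zm * zt
    return PhasorPoint(g=out.real, s=out.imag, harmonic=point.harmonic,
                       omega=point.omega)


def phasor_intensity_mask(cube: PhotonCube, fraction: float = 0.7) -> np.ndarray:
    """Pixels whose total counts reach ``fraction`` of the image maximum."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    intensity = cube.intensity()
    return intensity >= fraction * intensity.max()


def cube_phasors(cube: PhotonCube, harmonic: int = 1,
                 mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-pixel phasor coordinates of the masked pixels of a cube."""
    if mask is None:
        mask = np.ones(cube.shape, dtype=bool)
    rows = []
    for y, x in zip(*np.nonzero(mask)):
        try:
            p = phasor_transform(cube.pixel_histogram(y, x), harmonic)
        except ValueError:
            continue
        rows.append({"y": int(y), "x": int(x), "g": p.g, "s": p.s,
                     "harmonic": harmonic})
    return pd.DataFrame(rows)


def semicircle(n: int = 256) -> Tuple[np.ndarray, np.ndarray]:
    """The universal semicircle, for plotting."""
    theta = np.linspace(0.0, math.pi, n)
    return 0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta)


def plot_phasor(points: Sequence[PhasorPoint], labels=None, ax=None):
    """Scatter phasor points over the universal semicircle (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    gx, sy = semicircle()
    ax.plot(gx, sy, "k-", lw=0.8)
    g = [p.g for p in points]
    s = [p.s for p in points]
    ax.scatter(g, s, c=labels, s=12)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.02, 0.6)
    return ax
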