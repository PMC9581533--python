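"""Bi-exponential TCSPC decay fitting with IRF convolution.

Model
-----
Fluorescence after each laser pulse decays as
``f(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2)`` with ``a1 + a2 = 1``.  Under
periodic excitation at 80 MHz the long component has not fully decayed at
the end of the 12.5 ns window, so the recorded curve is the periodic
summation of the single-pulse response (incomplete decay).  Each component
convolved with a Gaussian IRF has the closed exponentially-modified-
Gaussian form; the wrap-around of earlier pulses is summed analytically as
a geometric series, making the forward model exact.

Fitting maximises the Poisson likelihood of the observed channel counts
(counting statistics), with multi-start initialisation over a coarse
lifetime grid; goodness of fit is reported as Pearson chi-square per
degree of freedom.  A weighted-least-squares mode is available for
cross-checking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .histograms import DecayHistogram, PhotonCube
from .instrument import InstrumentModel

#: Coarse multi-start grid for (tau1, tau2), ps.
TAU1_STARTS = (100.0, 300.0, 600.0)
TAU2_STARTS = (1200.0, 2000.0, 3000.0)

#: Minimum photons for a fit to be attempted at all.
HARD_PHOTON_FLOOR = 1000


class FitError(RuntimeError):
    """Raised when no optimisation start converges; carries the best attempt."""

    def __init__(self, message: str, best: Optional["BiExpFit"] = None):
        super().__init__(message)
        self.best = best


@dataclass
class BiExpFit:
    """Result of a bi-exponential decay fit (amplitudes on the unit simplex)."""

    a1: float
    a2: float
    tau1: float
    tau2: float
    shift: float
    offset: float
    chi2_reduced: float
    n_photons_used: int
    converged: bool = True
    warn_low_photons: bool = False

    def __post_init__(self) -> None:
        # enforce the tau1 <= tau2 label order by component swap
        if self.tau1 > self.tau2:
            self.tau1, self.tau2 = self.tau2, self.tau1
            self.a1, self.a2 = self.a2, self.a1

    @property
    def amp_ratio(self) -> float:
        return self.a1 / self.a2

    @property
    def taum(self) -> float:
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / (self.a1 + self.a2)

    @property
    def is_degenerate(self) -> bool:
        """True when the two lifetimes coincide (mono-exponential limit),
        in which case the amplitude split a1/a2 is not identifiable."""
        return (self.tau2 - self.tau1) < 0.05 * self.tau2


# ---------------------------------------------------------------------------
# Forward model


def _component_response(t: np.ndarray, tau: float, sigma: float, t0: float,
                        period: float) -> np.ndarray:
    """Periodic single-exponential decay convolved with a Gaussian IRF.

    Exponentially modified Gaussian for the current pulse plus the analytic
    geometric tail sum of all preceding pulses (valid because the IRF width
    is far smaller than the period).  Unit total amplitude per pulse.
    """
    t = np.asarray(t, dtype=np.float64)
    inv_tau = 1.0 / tau
    # EMG: (1/2tau) exp(sigma^2/2tau^2 - (t-t0)/tau) erfc((sigma/tau - (t-t0)/sigma)/sqrt2)
    z = (sigma * inv_tau - (t - t0) / sigma) / math.sqrt(2.0)
    # exp(a)*erfc(z) computed stably via erfcx where z > 0
    a = 0.5 * sigma * sigma * inv_tau * inv_tau - (t - t0) * inv_tau
    with np.errstate(over="ignore"):
        main = np.where(
            z > 0.0,
            np.exp(a - z * z) * special.erfcx(np.maximum(z, 0.0)),
            np.exp(a) * special.erfc(z),
        )
    main *= 0.5 * inv_tau
    # preceding pulses: pure exponential regime (t + k*period - t0 >> sigma)
    x = period * inv_tau
    if x > 50.0:  # wrap contribution negligible; avoid expm1 overflow
        geom = math.exp(0.5 * (sigma * inv_tau) ** 2 - x)
    else:
        geom = math.exp(0.5 * (sigma * inv_tau) ** 2) / math.expm1(x)
    tail = inv_tau * geom * np.exp(-(t - t0) * inv_tau)
    return main + tail


def decay_shape(instrument: InstrumentModel, tau1: float, tau2: float,
                a1: float, a2: Optional[float] = None,
                shift: float = 0.0, t0_channel: int = 0) -> np.ndarray:
    """Normalised expected decay shape over the ADC channels (sums to 1)."""
    if a2 is None:
        a2 = 1.0 - a1
    t = instrument.channel_centers
    t0 = t0_channel * instrument.channel_width + instrument.irf_shift + shift
    s = a1 * _component_response(t, tau1, instrument.irf_sigma, t0,
                                 instrument.window)
    s += a2 * _component_response(t, tau2, instrument.irf_sigma, t0,
                                  instrument.window)
    total = s.sum()
    if total <= 0:
        raise ValueError("degenerate decay shape")
    return s / total


def expected_counts(instrument: InstrumentModel, tau1: float, tau2: float,
                    a1: float, total_photons: float,
                    a2: Optional[float] = None, shift: float = 0.0,
                    offset: float = 0.0, t0_channel: int = 0) -> np.ndarray:
    """Expected channel counts: ``total_photons * shape + offset``."""
    return total_photons * decay_shape(
        instrument, tau1, tau2, a1, a2, shift, t0_channel
    ) + offset


# ---------------------------------------------------------------------------
# Spatial binning and masking


def spatial_bin(cube: PhotonCube, binning: int = 3) -> PhotonCube:
    """Sum each pixel's histogram over its (2*binning+1)^2 square window.

    Windows are truncated at image borders (no padding), so a corner pixel
    at binning=3 sums a 4x4 in-bounds window.  binning=0 is the identity.
    """
    if binning < 0:
        raise ValueError("binning must be >= 0")
    if binning == 0 or 0 in cube.shape:
        return PhotonCube(cube.counts.copy(), cube.instrument,
                          None if cube.labels is None else cube.labels.copy())
    c = cube.counts.astype(np.int64)
    # integral image over (y, x), shared across all time channels
    ii = np.zeros((c.shape[0], c.shape[1] + 1, c.shape[2] + 1), dtype=np.int64)
    ii[:, 1:, 1:] = c.cumsum(axis=1).cumsum(axis=2)
    ny, nx = cube.shape
    y = np.arange(ny)
    x = np.arange(nx)
    y0 = np.clip(y - binning, 0, ny)
    y1 = np.clip(y + binning + 1, 0, ny)
    x0 = np.clip(x - binning, 0, nx)
    x1 = np.clip(x + binning + 1, 0, nx)
    out = (ii[:, y1[:, None], x1[None, :]] - ii[:, y0[:, None], x1[None, :]]
           - ii[:, y1[:, None], x0[None, :]] + ii[:, y0[:, None], x0[None, :]])
    return PhotonCube(out.astype(cube.counts.dtype), cube.instrument,
                      None if cube.labels is None else cube.labels.copy())


def intensity_threshold_mask(cube: PhotonCube, threshold: float) -> np.ndarray:
    """Boolean mask of pixels whose total counts reach ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return cube.intensity() >= threshold


# ---------------------------------------------------------------------------
# Poisson-MLE fitting


def _poisson_deviance(counts: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
    return float(2.0 * np.sum(mu - counts + term))


def _wls_objective(counts: np.ndarray, mu: np.ndarray) -> float:
    w = 1.0 / np.maximum(counts, 1.0)
    return float(np.sum(w * (counts - mu) ** 2))


def _quick_amplitudes(counts: np.ndarray, b1: np.ndarray, b2: np.ndarray):
    """Weighted least-squares (c1, c2, offset) >= 0 for fixed lifetimes."""
    design = np.column_stack([b1, b2, np.ones_like(b1)])
    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    sol, *_ = np.linalg.lstsq(design * w[:, None], counts * w, rcond=None)
    return np.maximum(sol, 0.0)


def fit_biexponential(hist: DecayHistogram, fit_shift: bool = True,
                      fit_offset: bool = True, weighting: str = "poisson",
                      n_polish_starts: int = 2) -> BiExpFit:
    """Fit the periodic bi-exponential + IRF model to a decay histogram.

    Parameters are estimated by minimising the Poisson deviance
    (``weighting="poisson"``, the maximum-likelihood choice for counting
    noise) or a 1/counts weighted sum of squares (``weighting="wls"``).
    Initialisation is multi-start over a coarse (tau1, tau2) grid with a
    fast linear amplitude solve at each start; the best starts are polished
    with L-BFGS-B.  The returned fit has ``tau1 <= tau2`` enforced by
    component swap and Pearson chi-square per degree of freedom.
    """
    counts = np.asarray(hist.counts, dtype=np.float64)
    n_photons = hist.n_photons
    if n_photons == 0:
        raise ValueError("all-zero histogram cannot be fitted")
    if n_photons < HARD_PHOTON_FLOOR:
        raise ValueError(
            f"need at least {HARD_PHOTON_FLOOR} photons, got {n_photons}"
        )
    if weighting not in ("poisson", "wls"):
        raise ValueError("weighting must be 'poisson' or 'wls'")
    objective = _poisson_deviance if weighting == "poisson" else _wls_objective

    instrument = hist.instrument
    cw = instrument.channel_width
    off_unit = max(1.0, float(counts.mean()))

    # internal parameters are all O(1): (f1, tau1 ns, tau2 ns, shift in
    # channels, log amplitude / n_photons, offset / mean counts) so the
    # optimiser's finite-difference gradients are well conditioned
    def unpack(u: np.ndarray):
        f1, t1_ns, t2_ns, sh_ch, lns, off_u = u
        return (f1, 1000.0 * t1_ns, 1000.0 * t2_ns, sh_ch * cw,
                n_photons * math.exp(lns), off_u * off_unit)

    def model(u: np.ndarray) -> np.ndarray:
        f1, tau1, tau2, shift, scale, offset = unpack(u)
        return scale * decay_shape(
            instrument, tau1, tau2, f1, 1.0 - f1, shift, hist.t0_channel
        ) + offset

    def loss(u: np.ndarray) -> float:
        try:
            return objective(counts, model(u))
        except (ValueError, FloatingPointError):
            return 1e30

    # rank coarse grid starts by a cheap linear amplitude solve
    starts = []
    for t1 in TAU1_STARTS:
        for t2 in TAU2_STARTS:
            b1 = decay_shape(instrument, t1, t1, 1.0, 0.0, 0.0,
                             hist.t0_channel)
            b2 = decay_shape(instrument, t2, t2, 1.0, 0.0, 0.0,
                             hist.t0_channel)
            c1, c2, off = _quick_amplitudes(counts, b1, b2)
            tot = c1 + c2
            if tot <= 0:
                c1 = c2 = 0.5 * n_photons
                tot = n_photons
            f1 = min(max(c1 / tot, 0.02), 0.98)
            u0 = np.array([f1, t1 / 1000.0, t2 / 1000.0, 0.0,
                           math.log(max(tot / n_photons, 1e-3)),
                           off / off_unit if fit_offset else 0.0])
            starts.append((loss(u0), u0))
    starts.sort(key=lambda s: s[0])

    sh_bound = 3.0 if fit_shift else 0.0
    hi_off = (max(float(counts.max()), 1.0) / off_unit) if fit_offset else 0.0
    bounds = [
        (1e-3, 1.0 - 1e-3),
        (0.010, 5.0),
        (0.050, 8.0),
        (-sh_bound, sh_bound),
        (math.log(1e-3), math.log(10.0)),
        (0.0, hi_off),
    ]

    best = None
    any_converged = False
    for _, u0 in starts[:max(1, n_polish_starts)]:
        res = optimize.minimize(
            loss, u0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)

    f1, tau1, tau2, shift, scale, offset = unpack(best.x)
    mu = model(best.x)
    n_free = 4 + int(fit_shift) + int(fit_offset)
    dof = max(len(counts) - n_free, 1)
    chi2_red = float(np.sum((counts - mu) ** 2 / np.maximum(mu, 1e-12)) / dof)

    fit = BiExpFit(
        a1=float(f1), a2=float(1.0 - f1), tau1=float(tau1), tau2=float(tau2),
        shift=float(shift), offset=float(offset), chi2_reduced=chi2_red,
        n_photons_used=n_photons, converged=any_converged,
        warn_low_photons=hist.warn_low_photons,
    )
    if not any_converged:
        raise FitError("no optimisation start converged", best=fit)
    return fit


def fit_cube(cube: PhotonCube, mask: Optional[np.ndarray] = None,
             binning: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Fit every masked pixel of a (optionally binned) cube.

    Returns a tidy frame with one row per fitted pixel (columns ``y``,
    ``x`` plus the fit-result columns of :func:`fits_to_frame`).
    """
    binned = spatial_bin(cube, binning) if binning else cube
    if mask is None:
        mask = np.ones(binned.shape, dtype=bool)
    rows = []
    for y, x in zip(*np.nonzero(mask)):
        hist = binned.pixel_histogram(y, x)
        try:
            fit = fit_biexponential(hist, **fit_kwargs)
        except (ValueError, FitError):
            continue
        rows.append({"y": int(y), "x": int(x), **_fit_row(fit)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostics


def check_diagnostic_correlations(fits: Sequence[BiExpFit],
                                  intensities: Sequence[float]) -> pd.DataFrame:
    """Correlation screen of intensity and chi-square against fit parameters.

    An unbiased decay analysis should show no correlation between the
    fluorescence intensity (or the fit quality) and the decay parameters;
    this reports Pearson and Spearman coefficients with p-values for
    intensity and reduced chi-square against tau1, tau2, taum and a1/a2.
    Constant columns yield NaN coefficients (correlation undefined).
    """
    fits = list(fits)
    intensities = np.asarray(intensities, dtype=float)
    if len(fits) < 3:
        raise ValueError("need at least 3 fits for a correlation report")
    if len(intensities) != len(fits):
        raise ValueError("intensities length must match fits")
    params = {
        "tau1": np.array([f.tau1 for f in fits]),
        "tau2": np.array([f.tau2 for f in fits]),
        "taum": np.array([f.taum for f in fits]),
        "amp_ratio": np.array([f.amp_ratio for f in fits]),
    }
    against = {
        "intensity": intensities,
        "chi2_reduced": np.array([f.chi2_reduced for f in fits]),
    }
    rows = []
    for a_name, a in against.items():
        for p_name, p in params.items():
            if np.ptp(a) == 0 or np.ptp(p) == 0:
                rows.append({"x": a_name, "y": p_name, "pearson_r": np.nan,
                             "pearson_p": np.nan, "spearman_r": np.nan,
                             "spearman_p": np.nan, "defined": False})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pr = stats.pearsonr(a, p)
                sr = stats.spearmanr(a, p)
            rows.append({"x": a_name, "y": p_name,
                         "pearson_r": float(pr.statistic),
                         "pearson_p": float(pr.pvalue),
                         "spearman_r": float(sr.statistic),
                         "spearman_p": float(sr.pvalue), "defined": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fit-table I/O

_FIT_COLUMNS = ["cell_id", "a1", "a2", "tau1_ps", "tau2_ps", "shift_ps",
                "offset", "chi2_reduced", "n_photons", "warn_low_photons"]


def _fit_row(fit: BiExpFit) -> dict:
    return {
        "a1": fit.a1, "a2": fit.a2, "tau1_ps": fit.tau1, "tau2_ps": fit.tau2,
        "shift_ps": fit.shift, "offset": fit.offset,
        "chi2_reduced": fit.chi2_reduced, "n_photons": fit.n_photons_used,
        "warn_low_photons": fit.warn_low_photons,
    }


def fits_to_frame(fits: Sequence[BiExpFit],
                  cell_ids: Optional[Sequence] = None) -> pd.DataFrame:
    if cell_ids is None:
        cell_ids = range(len(fits))
    rows = [{"cell_id": cid, **_fit_row(f)} for cid, f in zip(cell_ids, fits)]
    return pd.DataFrame(rows, columns=_FIT_COLUMNS)


def write_fits_csv(path, fits: Sequence[BiExpFit],
                   cell_ids: Optional[Sequence] = None) -> None:
    fits_to_frame(fits, cell_ids).to_csv(path, index=False)


def read_fits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_FIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fit table missing columns: {sorted(missing)}")
    return df
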