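"""Bi-exponential fitting, spatial binning, masking, diagnostics."""

import numpy as np
import pytest

import tpeflim as tf
from tpeflim.decay_fitting import (
    BiExpFit, check_diagnostic_correlations, expected_counts,
    fit_biexponential, fit_cube, fits_to_frame, intensity_threshold_mask,
    read_fits_csv, spatial_bin, write_fits_csv,
)
from tpeflim.histograms import DecayHistogram, PhotonCube
from tpeflim.synthetic_data import simulate_decay


def _hist(instrument, counts):
    return DecayHistogram(np.asarray(counts, float), instrument)


# ---------------------------------------------------------------------------
# spatial_bin


def _uniform_cube(instrument, ny=10, nx=10, value=1):
    counts = np.full((instrument.n_channels, ny, nx), value, dtype=np.uint32)
    return PhotonCube(counts, instrument)


def test_bin_uniform_interior_is_49(instrument):
    out = spatial_bin(_uniform_cube(instrument), binning=3)
    assert np.all(out.counts[:, 5, 5] == 49)


def test_bin_zero_is_identity(instrument):
    cube = _uniform_cube(instrument, value=3)
    out = spatial_bin(cube, binning=0)
    assert np.array_equal(out.counts, cube.counts)


def test_bin_corner_window_truncated_to_16(instrument):
    out = spatial_bin(_uniform_cube(instrument), binning=3)
    assert np.all(out.counts[:, 0, 0] == 16)  # 4x4 in-bounds window
    assert np.all(out.counts[:, 0, 5] == 4 * 7)  # 4 rows x 7 cols


def test_bin_matches_window_enumeration(instrument):
    """Integral-image binning equals direct window sums on random data."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 5, size=(instrument.n_channels, 7, 9)).astype(
        np.uint32)
    cube = PhotonCube(counts, instrument)
    out = spatial_bin(cube, binning=2)
    for y, x in [(0, 0), (3, 4), (6, 8), (2, 0)]:
        y0, y1 = max(y - 2, 0), min(y + 3, 7)
        x0, x1 = max(x - 2, 0), min(x + 3, 9)
        direct = counts[:, y0:y1, x0:x1].sum(axis=(1, 2))
        assert np.array_equal(out.counts[:, y, x], direct)


def test_bin_negative_rejected(instrument):
    with pytest.raises(ValueError):
        spatial_bin(_uniform_cube(instrument), binning=-1)


# ---------------------------------------------------------------------------
# intensity mask


def test_threshold_mask_trivial(instrument):
    cube = _uniform_cube(instrument, value=2)
    assert intensity_threshold_mask(cube, 0).all()
    assert not intensity_threshold_mask(cube, cube.intensity().max() + 1).any()


def test_threshold_mask_two_level(instrument):
    counts = np.ones((instrument.n_channels, 6, 6), dtype=np.uint32)
    counts[:, 2:4, 2:4] = 10
    cube = PhotonCube(counts, instrument)
    bright = intensity_threshold_mask(cube, 5 * instrument.n_channels)
    expected = np.zeros((6, 6), bool)
    expected[2:4, 2:4] = True
    assert np.array_equal(bright, expected)


# ---------------------------------------------------------------------------
# fit_biexponential


def test_fit_rejects_bad_input(instrument):
    with pytest.raises(ValueError):
        fit_biexponential(_hist(instrument, np.zeros(instrument.n_channels)))
    low = np.zeros(instrument.n_channels)
    low[:10] = 50  # 500 photons, below the hard floor
    with pytest.raises(ValueError, match="at least"):
        fit_biexponential(_hist(instrument, low))
    with pytest.raises(ValueError, match="weighting"):
        fit_biexponential(
            _hist(instrument, np.full(instrument.n_channels, 100.0)),
            weighting="huber")


def test_fit_monoexponential_limit(instrument):
    """Noiseless tau1 = tau2 = 1000 ps curve: both lifetimes recovered and
    the degenerate amplitude split flagged."""
    mu = expected_counts(instrument, 1000.0, 1000.0, 0.5, 2e5)
    fit = fit_biexponential(_hist(instrument, np.round(mu)))
    assert fit.tau1 == pytest.approx(1000.0, rel=0.05)
    assert fit.tau2 == pytest.approx(1000.0, rel=0.05)
    assert fit.is_degenerate
    assert fit.chi2_reduced < 0.1  # rounding only, far below noise level


def test_fit_round_trip_m1_like(instrument, m1_cell):
    """Simulated in vivo M1-like decays at 1e5 photons: tau1/tau2 within
    10% and a1/a2 within 15% in the median over replicates."""
    rng = np.random.default_rng(21)
    errs = []
    for _ in range(20):
        hist = simulate_decay(m1_cell, instrument, 100_000, rng)
        fit = fit_biexponential(hist)
        errs.append([abs(fit.tau1 - 196.0) / 196.0,
                     abs(fit.tau2 - 1698.0) / 1698.0,
                     abs(fit.amp_ratio - 5.0) / 5.0])
    med = np.median(errs, axis=0)
    assert med[0] <= 0.10 and med[1] <= 0.10
    assert med[2] <= 0.15


def test_fit_chi2_calibrated_under_true_model(instrument, m2_cell):
    rng = np.random.default_rng(5)
    chis = [fit_biexponential(
        simulate_decay(m2_cell, instrument, 100_000, rng)).chi2_reduced
        for _ in range(15)]
    assert 0.85 < np.mean(chis) < 1.15


def test_fit_label_order_enforced(instrument, m1_cell):
    hist = simulate_decay(m1_cell, instrument, 50_000, seed=3)
    fit = fit_biexponential(hist)
    assert fit.tau1 <= fit.tau2
    # constructing a fit with swapped labels normalises it
    swapped = BiExpFit(a1=0.2, a2=0.8, tau1=1500.0, tau2=200.0, shift=0.0,
                       offset=0.0, chi2_reduced=1.0, n_photons_used=10_000)
    assert (swapped.tau1, swapped.tau2) == (200.0, 1500.0)
    assert (swapped.a1, swapped.a2) == (0.8, 0.2)


def test_fit_consistency_with_photon_count(instrument, m1_cell):
    """Lifetime errors shrink as the photon budget grows (1e4 vs 1e6)."""
    def median_err(photons, seed):
        rng = np.random.default_rng(seed)
        errs = []
        for _ in range(8):
            fit = fit_biexponential(
                simulate_decay(m1_cell, instrument, photons, rng))
            errs.append(abs(fit.tau2 - 1698.0) / 1698.0)
        return np.median(errs)

    assert median_err(1_000_000, 17) < median_err(10_000, 17)


def test_low_photon_warning_propagates(instrument, m1_cell):
    hist = simulate_decay(m1_cell, instrument, 3000, seed=1)
    fit = fit_biexponential(hist)
    assert fit.warn_low_photons


def test_binned_uniform_fit_equals_pooled_histogram_fit(instrument, m1_cell):
    """Fitting the 49-pixel binned center of a uniform scene is the same
    computation as fitting the pooled single histogram."""
    rng = np.random.default_rng(12)
    mu = expected_counts(instrument, m1_cell.true_tau1, m1_cell.true_tau2,
                         m1_cell.true_a1, 2000.0)
    counts = rng.poisson(mu[:, None, None], size=(instrument.n_channels, 7, 7)
                         ).astype(np.uint32)
    cube = PhotonCube(counts, instrument)
    binned = spatial_bin(cube, binning=3)
    pooled = DecayHistogram(counts.sum(axis=(1, 2)).astype(float), instrument)
    assert np.array_equal(binned.counts[:, 3, 3].astype(float), pooled.counts)
    fit_a = fit_biexponential(binned.pixel_histogram(3, 3))
    fit_b = fit_biexponential(pooled)
    assert fit_a.tau1 == fit_b.tau1 and fit_a.tau2 == fit_b.tau2
    assert fit_a.a1 == fit_b.a1


def test_fit_cube_runs_on_masked_pixels(instrument, m1_cell):
    mu = expected_counts(instrument, m1_cell.true_tau1, m1_cell.true_tau2,
                         m1_cell.true_a1, 20_000.0)
    rng = np.random.default_rng(8)
    counts = rng.poisson(mu[:, None, None], size=(instrument.n_channels, 2, 2)
                         ).astype(np.uint32)
    cube = PhotonCube(counts, instrument)
    mask = np.zeros((2, 2), bool)
    mask[0, 0] = mask[1, 1] = True
    df = fit_cube(cube, mask=mask)
    assert len(df) == 2
    assert set(zip(df["y"], df["x"])) == {(0, 0), (1, 1)}
    assert np.allclose(df["tau1_ps"], 196.0, rtol=0.2)


# ---------------------------------------------------------------------------
# diagnostics


def _fits_from(tau1s, tau2s, ratios):
    fits = []
    for t1, t2, r in zip(tau1s, tau2s, ratios):
        a1 = r / (1 + r)
        fits.append(BiExpFit(a1=a1, a2=1 - a1, tau1=t1, tau2=t2, shift=0.0,
                             offset=0.0, chi2_reduced=1.0,
                             n_photons_used=10_000))
    return fits


def test_correlations_null_case():
    rng = np.random.default_rng(0)
    n = 200
    fits = _fits_from(rng.normal(200, 20, n), rng.normal(1700, 100, n),
                      rng.normal(5, 0.5, n))
    intens = rng.normal(700, 100, n)
    rep = check_diagnostic_correlations(fits, intens)
    sub = rep[rep["x"] == "intensity"]
    assert np.all(np.abs(sub["pearson_r"]) < 0.2)


def test_correlations_perfect_dependence():
    tau1 = np.linspace(150, 250, 50)
    fits = _fits_from(tau1, np.full(50, 1700.0), np.full(50, 5.0))
    rep = check_diagnostic_correlations(fits, tau1)  # intensity := tau1
    row = rep[(rep["x"] == "intensity") & (rep["y"] == "tau1")].iloc[0]
    assert row["pearson_r"] == pytest.approx(1.0)


def test_correlations_degenerate_inputs():
    fits = _fits_from([200, 210], [1700, 1710], [5, 5])
    with pytest.raises(ValueError, match="at least 3"):
        check_diagnostic_correlations(fits, [1.0, 2.0])
    fits3 = _fits_from([200, 210, 220], [1700, 1710, 1720], [5, 5, 5])
    rep = check_diagnostic_correlations(fits3, [1.0, 1.0, 1.0])
    const = rep[(rep["x"] == "intensity")]
    assert not const["defined"].any()
    assert const["pearson_r"].isna().all()


# ---------------------------------------------------------------------------
# fit table I/O


def test_fits_csv_round_trip(tmp_path):
    fits = _fits_from([200.0, 450.0], [1700.0, 2400.0], [5.0, 1.2])
    path = tmp_path / "fits.csv"
    write_fits_csv(path, fits, cell_ids=["a", "b"])
    back = read_fits_csv(path)
    assert list(back["cell_id"]) == ["a", "b"]
    assert np.allclose(back["tau1_ps"], [200.0, 450.0])
    ref = fits_to_frame(fits, ["a", "b"])
    for col in ("a1", "a2", "tau2_ps", "chi2_reduced"):
        assert np.allclose(back[col], ref[col])
    with pytest.raises(ValueError, match="missing columns"):
        bad = tmp_path / "bad.csv"
        bad.write_text("cell_id,a1\nx,0.5\n")
        read_fits_csv(bad)
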