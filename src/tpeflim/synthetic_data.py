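"""Synthetic dermal-cell TPE-FLIM data with the reference class structure.

The bundled reference table encodes the per-class bi-exponential decay
parameter distributions (mean +/- SD of tau1, tau2, taum, a1/a2 and
autofluorescence intensity) of M1 and M2 macrophages measured in vitro,
ex vivo and in vivo, together with the other dermal cell classes used as
classifier background (mast cells, dendritic cells, fibroblasts,
neutrophils), and the per-class cell counts that assemble the 399-cell
classification dataset.

From those distributions this module draws per-cell ground-truth decay
parameters, synthesises TCSPC photon histograms (periodic bi-exponential
decay convolved with a Gaussian IRF, Poisson counting noise), and builds
small FLIM image cubes of elliptical cells on an ECM-like background for
binning and segmentation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import decay_fitting
from .flim_features import compute_tau_m, features_from_parameters, _TABLE_COLUMNS
from .histograms import DecayHistogram, PhotonCube
from .instrument import InstrumentModel

#: Total number of cells in the assembled reference dataset.
TOTAL_REFERENCE_CELLS = 399

#: Group labels.
M1, M2, OTHER = 0, 1, 2

_ENVIRONMENTS = ("in_vitro", "ex_vivo", "in_vivo")


@dataclass(frozen=True)
class ReferenceClassRow:
    """One cell class: decay-parameter distributions and dataset count."""

    class_name: str
    group_label: int
    environment: str
    n_cells: int
    tau1_mean: float
    tau1_sd: float
    tau2_mean: float
    tau2_sd: float
    taum_mean: float
    taum_sd: float
    amp_ratio_mean: float
    amp_ratio_sd: float
    intensity_mean: float
    intensity_sd: float

    def __post_init__(self) -> None:
        if self.group_label not in (M1, M2, OTHER):
            raise ValueError(f"bad group_label {self.group_label}")
        if self.environment not in _ENVIRONMENTS:
            raise ValueError(f"bad environment {self.environment!r}")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not self.tau1_mean < self.tau2_mean:
            raise ValueError("tau1_mean must be below tau2_mean")
        for f in ("tau1_mean", "tau1_sd", "tau2_mean", "tau2_sd",
                  "taum_mean", "taum_sd", "amp_ratio_mean", "amp_ratio_sd",
                  "intensity_mean", "intensity_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class ReferenceClassTable:
    """The full reference distribution set (immutable row collection)."""

    rows: Tuple[ReferenceClassRow, ...]

    @property
    def total_cells(self) -> int:
        return sum(r.n_cells for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def get(self, class_name: str, environment: Optional[str] = None
            ) -> ReferenceClassRow:
        hits = [r for r in self.rows if r.class_name == class_name
                and (environment is None or r.environment == environment)]
        if not hits:
            raise KeyError(f"no class {class_name!r} (environment={environment})")
        if len(hits) > 1:
            raise KeyError(f"class {class_name!r} ambiguous; give environment")
        return hits[0]

    def subset(self, group_labels: Optional[Sequence[int]] = None,
               environments: Optional[Sequence[str]] = None
               ) -> "ReferenceClassTable":
        rows = tuple(
            r for r in self.rows
            if (group_labels is None or r.group_label in group_labels)
            and (environments is None or r.environment in environments)
        )
        return ReferenceClassTable(rows)


def load_reference_table(path=None) -> ReferenceClassTable:
    """Load the bundled (or a user-supplied) reference class table."""
    if path is None:
        path = resources.files("tpeflim.data") / "reference_classes.csv"
    try:
        df = pd.read_csv(path, comment="#")
        rows = tuple(
            ReferenceClassRow(
                class_name=str(r.class_name),
                group_label=int(r.group_label),
                environment=str(r.environment),
                n_cells=int(r.n_cells),
                tau1_mean=float(r.tau1_mean), tau1_sd=float(r.tau1_sd),
                tau2_mean=float(r.tau2_mean), tau2_sd=float(r.tau2_sd),
                taum_mean=float(r.taum_mean), taum_sd=float(r.taum_sd),
                amp_ratio_mean=float(r.amp_ratio_mean),
                amp_ratio_sd=float(r.amp_ratio_sd),
                intensity_mean=float(r.intensity_mean),
                intensity_sd=float(r.intensity_sd),
            )
            for r in df.itertuples()
        )
    except (OSError, ValueError, AttributeError, KeyError) as exc:
        raise RuntimeError(
            f"reference class table at {path} is missing or corrupted: {exc}"
        ) from exc
    return ReferenceClassTable(rows)


# ---------------------------------------------------------------------------
# Per-cell sampling


@dataclass(frozen=True)
class CellSample:
    """Ground-truth decay parameters of one synthetic cell."""

    true_tau1: float
    true_tau2: float
    true_a1: float
    true_a2: float
    group_label: int
    class_name: str
    intensity: float

    def __post_init__(self) -> None:
        if not 0 < self.true_tau1 < self.true_tau2:
            raise ValueError("need 0 < tau1 < tau2")
        if not (0 < self.true_a1 < 1 and 0 < self.true_a2 < 1):
            raise ValueError("amplitudes must lie in (0, 1)")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed))


def _truncated_normal(rng, mean, sd, size, low=0.0):
    """Normal draws resampled until strictly above ``low``."""
    out = rng.normal(mean, sd, size)
    bad = out <= low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= low
    return out


def sample_cells(row: ReferenceClassRow, n: int, seed) -> List[CellSample]:
    """Draw ``n`` cells from a class's truncated-Gaussian distributions.

    tau1 and tau2 are drawn jointly and redrawn until tau1 < tau2; the
    amplitude ratio r = a1/a2 maps onto the unit simplex as
    a1 = r/(1+r), a2 = 1/(1+r).  taum is never drawn: it is implied by the
    sampled parameters so the feature vector stays internally consistent.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    tau1 = _truncated_normal(rng, row.tau1_mean, row.tau1_sd, n)
    tau2 = _truncated_normal(rng, row.tau2_mean, row.tau2_sd, n)
    bad = tau1 >= tau2
    while np.any(bad):
        k = int(bad.sum())
        tau1[bad] = _truncated_normal(rng, row.tau1_mean, row.tau1_sd, k)
        tau2[bad] = _truncated_normal(rng, row.tau2_mean, row.tau2_sd, k)
        bad = tau1 >= tau2
    ratio = _truncated_normal(rng, row.amp_ratio_mean, row.amp_ratio_sd, n)
    intensity = _truncated_normal(rng, row.intensity_mean, row.intensity_sd, n)
    a1 = ratio / (1.0 + ratio)
    return [
        CellSample(
            true_tau1=float(tau1[i]), true_tau2=float(tau2[i]),
            true_a1=float(a1[i]), true_a2=float(1.0 - a1[i]),
            group_label=row.group_label, class_name=row.class_name,
            intensity=float(intensity[i]),
        )
        for i in range(n)
    ]


def sample_reference_dataset(table: Optional[ReferenceClassTable] = None,
                             seed=0) -> pd.DataFrame:
    """Assemble the synthetic classification dataset (399 cells by default).

    Draws each class's listed number of cells and returns the standard
    feature table (8 FLIM features, intensity, label, environment,
    class name), one row per cell, deterministically under ``seed``.
    """
    if table is None:
        table = load_reference_table()
    rng = _rng(seed)
    frames = []
    cell_id = 0
    for row in table.rows:
        cells = sample_cells(row, row.n_cells, rng)
        feats = features_from_parameters(
            np.array([c.true_tau1 for c in cells]),
            np.array([c.true_tau2 for c in cells]),
            np.array([c.true_a1 for c in cells]),
            np.array([c.true_a2 for c in cells]))
        df = pd.DataFrame(feats)
        df.insert(0, "cell_id", np.arange(cell_id, cell_id + row.n_cells))
        df["intensity_photons_per_mW"] = [c.intensity for c in cells]
        df["shape"] = np.nan
        df["label"] = row.group_label
        df["environment"] = row.environment
        df["class_name"] = row.class_name
        frames.append(df)
        cell_id += row.n_cells
    return pd.concat(frames, ignore_index=True)[_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# Decay-histogram simulation


def simulate_decay(cell: CellSample, instrument: InstrumentModel,
                   total_photons: int, seed) -> DecayHistogram:
    """Simulate one TCSPC histogram for a cell.

    Expected counts are ``total_photons`` times the normalised periodic
    bi-exponential decay convolved with the Gaussian IRF, plus the
    instrument's uniform background; observed counts are Poisson draws.
    Histograms below the 5000-photon analysis floor carry a warning flag.
    """
    if total_photons <= 0:
        raise ValueError("total_photons must be positive")
    rng = _rng(seed)
    mu = decay_fitting.expected_counts(
        instrument, cell.true_tau1, cell.true_tau2, cell.true_a1,
        total_photons, a2=cell.true_a2, offset=instrument.background_rate)
    hist = DecayHistogram(rng.poisson(mu).astype(np.float64), instrument,
                          truth=cell)
    return hist


# ---------------------------------------------------------------------------
# FLIM image cubes


@dataclass(frozen=True)
class EllipseRegion:
    """Elliptical cell footprint on the pixel grid (0-based, row-major)."""

    cy: float
    cx: float
    ry: float
    rx: float
    cell: CellSample
    photons_per_pixel: float = 500.0

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (((yy - self.cy) / self.ry) ** 2
                + ((xx - self.cx) / self.rx) ** 2) <= 1.0


#: ECM-like background: long-lifetime, low-intensity matrix fluorescence.
DEFAULT_BACKGROUND = dict(tau1=300.0, tau2=2200.0, a1=0.6,
                          photons_per_pixel=50.0)


@dataclass
class SceneSpec:
    """Cells-on-background layout for :func:`simulate_flim_cube`."""

    shape: Tuple[int, int] = (32, 32)
    cells: Sequence[EllipseRegion] = field(default_factory=tuple)
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))


def simulate_flim_cube(scene: SceneSpec, instrument: InstrumentModel,
                       seed) -> PhotonCube:
    """Render a scene into a photon cube with per-pixel Poisson noise.

    The ``labels`` plane stores each cell's group label and -1 for
    background; overlapping cell regions are rejected (ambiguous truth).
    """
    rng = _rng(seed)
    ny, nx = scene.shape
    labels = np.full((ny, nx), -1, dtype=np.int16)
    coverage = np.zeros((ny, nx), dtype=np.int16)
    bg = scene.background
    mu_bg = decay_fitting.expected_counts(
        instrument, bg["tau1"], bg["tau2"], bg["a1"],
        bg["photons_per_pixel"], offset=instrument.background_rate)
    mu = np.broadcast_to(mu_bg[:, None, None], (instrument.n_channels, ny, nx)).copy()
    for region in scene.cells:
        m = region.mask((ny, nx))
        coverage += m
        if np.any(coverage > 1):
            raise ValueError("overlapping cell regions give ambiguous ground truth")
        labels[m] = region.cell.group_label
        mu_cell = decay_fitting.expected_counts(
            instrument, region.cell.true_tau1, region.cell.true_tau2,
            region.cell.true_a1, region.photons_per_pixel,
            offset=instrument.background_rate)
        mu[:, m] = mu_cell[:, None]
    counts = rng.poisson(mu).astype(np.uint32)
    return PhotonCube(counts=counts, instrument=instrument, labels=labels)
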