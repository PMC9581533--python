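"""FLIM parameter set, classifier feature vectors, and 2D segmentation.

The classifier input is the 8-value FLIM parameter vector: the independent
fit parameters tau1, tau2, a1, a2 and the derived variables
taum = (a1*tau1 + a2*tau2)/(a1 + a2), tau2/tau1, a1/a2 and the amplitude
contrast (a1 - a2)/(a1 + a2).  Autofluorescence intensity (photons/mW) and
a circular/noncircular shape flag can be appended as optional features;
cell size is deliberately never included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decay_fitting import BiExpFit

#: Feature order of the default 8-value classifier input.
FEATURE_NAMES = ["tau1_ps", "tau2_ps", "a1", "a2", "taum_ps",
                 "tau_ratio", "amp_ratio", "amp_contrast"]

#: Sentinel labels for per-pixel segmentation maps.
UNCLASSIFIED = -1
AMBIGUOUS = -2


def compute_tau_m(a1, a2, tau1, tau2):
    """Amplitude-weighted mean lifetime ``(a1*tau1 + a2*tau2)/(a1 + a2)``."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    total = a1 + a2
    if np.any(total <= 0):
        raise ValueError("a1 + a2 must be positive")
    if np.any(np.asarray(tau1, dtype=float) <= 0) or np.any(
            np.asarray(tau2, dtype=float) <= 0):
        raise ValueError("lifetimes must be positive")
    out = (a1 * np.asarray(tau1, float) + a2 * np.asarray(tau2, float)) / total
    return float(out) if out.ndim == 0 else out


def features_from_parameters(tau1, tau2, a1, a2) -> dict:
    """The 8 FLIM features from decay parameters (vectorised).

    Inputs follow the tau1 <= tau2 label convention so that
    ``tau_ratio = tau2/tau1 >= 1``.
    """
    tau1 = np.asarray(tau1, dtype=float)
    tau2 = np.asarray(tau2, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    return {
        "tau1_ps": tau1,
        "tau2_ps": tau2,
        "a1": a1,
        "a2": a2,
        "taum_ps": compute_tau_m(a1, a2, tau1, tau2),
        "tau_ratio": tau2 / tau1,
        "amp_ratio": a1 / a2,
        "amp_contrast": (a1 - a2) / (a1 + a2),
    }


@dataclass
class FeatureVector:
    """One cell's classifier input plus optional metadata."""

    tau1_ps: float
    tau2_ps: float
    a1: float
    a2: float
    taum_ps: float
    tau_ratio: float
    amp_ratio: float
    amp_contrast: float
    intensity: Optional[float] = None  # photons/mW
    shape: Optional[int] = None  # 1 circular, 0 noncircular
    label: Optional[int] = None  # 0=M1, 1=M2, 2=other

    def values(self, include_intensity: bool = False,
               include_shape: bool = False) -> np.ndarray:
        v = [getattr(self, n) for n in FEATURE_NAMES]
        if include_intensity:
            if self.intensity is None:
                raise ValueError("intensity requested but not set")
            v.append(self.intensity)
        if include_shape:
            if self.shape is None:
                raise ValueError("shape requested but not set")
            v.append(float(self.shape))
        return np.asarray(v, dtype=float)


def build_feature_vector(fit: BiExpFit, intensity: Optional[float] = None,
                         shape: Optional[int] = None,
                         label: Optional[int] = None) -> FeatureVector:
    """Derive the FLIM feature vector from a bi-exponential fit."""
    feats = features_from_parameters(fit.tau1, fit.tau2, fit.a1, fit.a2)
    return FeatureVector(
        **{k: float(v) for k, v in feats.items()},
        intensity=intensity, shape=shape, label=label,
    )


def normalize_intensity(total_counts: float, laser_power_mW: float,
                        window_pixels: int = 49) -> float:
    """Autofluorescence intensity in photons/mW.

    Counts are averaged over the analysis window (the pixel of interest and
    its 48 square neighbours by default) and divided by excitation power.
    """
    if laser_power_mW <= 0:
        raise ValueError("laser power must be positive")
    if window_pixels <= 0:
        raise ValueError("window_pixels must be positive")
    return total_counts / window_pixels / laser_power_mW


# ---------------------------------------------------------------------------
# Feature tables

_TABLE_COLUMNS = ["cell_id", "tau1_ps", "tau2_ps", "a1", "a2", "taum_ps",
                  "tau_ratio", "amp_ratio", "amp_contrast",
                  "intensity_photons_per_mW", "shape", "label",
                  "environment", "class_name"]


def feature_frame(vectors: Sequence[FeatureVector],
                  cell_ids: Optional[Sequence] = None,
                  environments: Optional[Sequence[str]] = None,
                  class_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    n = len(vectors)
    cell_ids = list(cell_ids) if cell_ids is not None else list(range(n))
    environments = list(environments) if environments is not None else [""] * n
    class_names = list(class_names) if class_names is not None else [""] * n
    rows = []
    for cid, v, env, cname in zip(cell_ids, vectors, environments, class_names):
        rows.append({
            "cell_id": cid, "tau1_ps": v.tau1_ps, "tau2_ps": v.tau2_ps,
            "a1": v.a1, "a2": v.a2, "taum_ps": v.taum_ps,
            "tau_ratio": v.tau_ratio, "amp_ratio": v.amp_ratio,
            "amp_contrast": v.amp_contrast,
            "intensity_photons_per_mW": v.intensity, "shape": v.shape,
            "label": v.label, "environment": env, "class_name": cname,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_feature_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df


def frame_from_fits(fits_frame: pd.DataFrame) -> pd.DataFrame:
    """Feature table from a fit-result table (see decay_fitting CSV schema)."""
    feats = features_from_parameters(
        fits_frame["tau1_ps"].to_numpy(), fits_frame["tau2_ps"].to_numpy(),
        fits_frame["a1"].to_numpy(), fits_frame["a2"].to_numpy())
    out = pd.DataFrame({"cell_id": fits_frame["cell_id"], **feats})
    out["intensity_photons_per_mW"] = np.nan
    out["shape"] = np.nan
    out["label"] = fits_frame["label"] if "label" in fits_frame else np.nan
    out["environment"] = ""
    out["class_name"] = ""
    return out[_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# 2D segmentation


def class_boxes_from_table(table, params: Tuple[str, str] = ("tau1_ps", "amp_ratio"),
                           k: float = 2.0) -> dict:
    """Per-class rectangular gates mean +/- k*SD over a parameter pair.

    ``table`` is a ReferenceClassTable; one box per group label is built by
    pooling that label's rows (union of the per-row intervals).
    """
    mean_cols = {"tau1_ps": ("tau1_mean", "tau1_sd"),
                 "tau2_ps": ("tau2_mean", "tau2_sd"),
                 "taum_ps": ("taum_mean", "taum_sd"),
                 "amp_ratio": ("amp_ratio_mean", "amp_ratio_sd")}
    boxes: dict = {}
    for row in table.rows:
        box = boxes.setdefault(row.group_label, {p: [np.inf, -np.inf] for p in params})
        for p in params:
            m_col, s_col = mean_cols[p]
            m = getattr(row, m_col)
            s = getattr(row, s_col)
            box[p][0] = min(box[p][0], m - k * s)
            box[p][1] = max(box[p][1], m + k * s)
    return {lbl: {p: tuple(iv) for p, iv in box.items()}
            for lbl, box in boxes.items()}


def segment_pixels(param_maps: Mapping[str, np.ndarray], class_boxes: Mapping,
                   mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-pixel class map from rectangular gates on FLIM parameters.

    Each masked pixel is labelled with the unique class whose box contains
    its parameter values, ``AMBIGUOUS`` (-2) when several boxes match and
    ``UNCLASSIFIED`` (-1) when none does or the pixel is masked out.
    """
    if not class_boxes:
        raise ValueError("class_boxes must not be empty")
    shapes = {m.shape for m in param_maps.values()}
    if len(shapes) != 1:
        raise ValueError("parameter maps must share one shape")
    shape = shapes.pop()
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    out = np.full(shape, UNCLASSIFIED, dtype=np.int16)
    n_match = np.zeros(shape, dtype=np.int16)
    for lbl, box in class_boxes.items():
        inside = mask.copy()
        for p, (lo, hi) in box.items():
            if p not in param_maps:
                raise ValueError(f"missing parameter map '{p}'")
            inside &= (param_maps[p] >= lo) & (param_maps[p] <= hi)
        out[inside & (n_match == 0)] = lbl
        n_match += inside
    out[n_match > 1] = AMBIGUOUS
    return out
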