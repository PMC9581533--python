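"""Pipeline configuration: TOML loading, validation, and hashing."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field

from .instrument import InstrumentModel
from .tree_classifier import TreeHyperparams


@dataclass
class PipelineConfig:
    """End-to-end settings; one seed reproduces every downstream artifact."""

    seed: int = 0
    photons_per_cell: int = 100_000
    binning: int = 3
    include_intensity: bool = False
    include_shape: bool = False
    n_repeats: int = 10_000
    k_folds: int = 5
    phasor_threshold: float = 0.7
    laser_power_mW: float = 50.0
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    tree: TreeHyperparams = field(default_factory=TreeHyperparams)

    def __post_init__(self) -> None:
        if self.photons_per_cell <= 0:
            raise ValueError("photons_per_cell must be positive")
        if self.binning < 0:
            raise ValueError("binning must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 <= self.phasor_threshold <= 1.0:
            raise ValueError("phasor_threshold must lie in [0, 1]")
        if self.laser_power_mW <= 0:
            raise ValueError("laser_power_mW must be positive")

    def digest(self) -> str:
        """Stable short hash of the full configuration."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional TOML file plus keyword overrides.

    TOML layout: top-level scalar fields, with optional ``[instrument]``
    and ``[tree]`` tables.  Overrides (e.g. CLI flags) win over the file.
    Field names are validated; unknown keys raise.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as f:
            data = tomllib.load(f)
    inst = data.pop("instrument", {})
    tree = data.pop("tree", {})
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    try:
        kwargs = dict(data)
        if inst or "instrument" not in kwargs:
            kwargs["instrument"] = InstrumentModel(**inst)
        if tree or "tree" not in kwargs:
            kwargs["tree"] = TreeHyperparams(**tree)
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc
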