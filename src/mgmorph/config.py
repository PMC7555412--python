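"""Pipeline configuration.

``PipelineConfig`` gathers every constant the analysis pipeline uses: the
intensity-scaling factor ``scale_numerator * m / scale_reference_mean`` applied
to the blue channel (``m`` being the image's mean blue intensity), the 0.72
negative-image threshold, the strict (50, 3000)-pixel area gate, the random
forest hyperparameters (1,500 trees, 3 candidate features per split), the
three-cluster complete-linkage setting, and the bootstrap design (2,000 cells
per draw, 500 replicates, 800x800 density bins).  Overrides come from a YAML
key-value file in which every key is optional.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError

log = logging.getLogger("mgmorph.config")

_VALID_LINKAGE = ("complete",)
_VALID_CONNECTIVITY = (4, 8)
_VALID_RANK_TIES = ("average",)
_STATES = ("activated", "activating", "homeostatic")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, immutable bundle of all pipeline parameters."""

    # Intensity normalization (dimensionless / [0,1] intensities)
    scale_numerator: float = 1.55
    scale_reference_mean: float = 0.43137
    negative_threshold: float = 0.72
    # Object size gate in pixels; both bounds strict
    min_area_px: int = 50
    max_area_px: int = 3000
    # Random-forest cell filter
    n_trees: int = 1500
    features_per_split: int = 3
    train_per_class: int = 277
    # Morphological state clustering
    n_clusters: int = 3
    linkage: str = "complete"
    connectivity: int = 8
    rank_ties: str = "average"
    # Cluster -> state manual override, e.g. {1: "activated"}; empty = automatic
    state_override: dict[int, str] = field(default_factory=dict)
    # Genotype-stratified bootstrap
    boot_n: int = 2000
    boot_reps: int = 500
    density_bins: int = 800
    # Master seed; every stage derives its own namespaced stream from it
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.negative_threshold < 1):
            raise ConfigurationError(
                f"negative_threshold must lie in (0, 1), got {self.negative_threshold}"
            )
        if self.min_area_px >= self.max_area_px:
            raise ConfigurationError(
                f"min_area_px ({self.min_area_px}) must be < max_area_px ({self.max_area_px})"
            )
        if self.scale_numerator <= 0:
            raise ConfigurationError("scale_numerator must be positive")
        if self.scale_reference_mean <= 0:
            raise ConfigurationError("scale_reference_mean must be positive")
        if self.n_clusters < 2:
            raise ConfigurationError(f"n_clusters must be >= 2, got {self.n_clusters}")
        for name in ("boot_n", "boot_reps", "density_bins", "n_trees",
                     "features_per_split", "train_per_class"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.linkage not in _VALID_LINKAGE:
            raise ConfigurationError(f"linkage must be one of {_VALID_LINKAGE}")
        if self.connectivity not in _VALID_CONNECTIVITY:
            raise ConfigurationError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.rank_ties not in _VALID_RANK_TIES:
            raise ConfigurationError(f"rank_ties must be one of {_VALID_RANK_TIES}")
        for cluster, state in self.state_override.items():
            if state not in _STATES:
                raise ConfigurationError(
                    f"state_override[{cluster}] must be one of {_STATES}, got {state!r}"
                )

    def replace(self, **changes) -> "PipelineConfig":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["state_override"] = dict(self.state_override)
        return d


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Build a PipelineConfig, overriding defaults from a YAML file if given.

    Missing keys keep their defaults; unknown keys raise ``ConfigurationError``
    so typos never pass silently.
    """
    overrides: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must be a key-value mapping")
        overrides = loaded
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "state_override" in overrides and overrides["state_override"] is not None:
        overrides["state_override"] = {
            int(k): str(v) for k, v in overrides["state_override"].items()
        }
    cfg = PipelineConfig(**overrides)
    log.info("effective config: %s", cfg.to_dict())
    return cfg
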