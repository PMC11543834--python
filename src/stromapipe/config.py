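"""Pipeline configuration.

All tunable parameters of the pipeline live in a single dataclass so that a
run is fully described by (config, seed).  Defaults are the published
operating points of the workflow: spots are called stroma above 55% stroma
area, the four exclusion rules use strict 50/50/80/50 percent thresholds,
genes need 10 reads in 10 spots, spots need 40 detected genes and 100
normalized counts, the fold-change threshold test uses tau = 0.5 log2 units
at adjusted alpha 0.01, and trichrome images are deconvolved with the
Masson blue/pink stain vectors at 0.55 um/pixel with a pink-concentration
threshold of 0.20 (validated range 0.15-0.30).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

#: Blue (collagen) and pink (muscle) Masson trichrome stain OD vectors.
DEFAULT_BLUE = (0.891, 0.454, 0.001)
DEFAULT_PINK = (0.245, 0.931, 0.271)

#: Annotation classes used by the histology rule engine.
CANCER_CLASSES = ("GG1", "GG2", "GG3", "GG4", "GG5")
LG_CLASSES = ("GG1", "GG2")
HG_CLASSES = ("GG3", "GG4", "GG5")
EPITHELIUM_CLASS = "non-cancer gland"
SPECIAL_CLASSES = ("outside", "fold", "lumen", "uncertain")


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(a))
    if n == 0:
        raise ConfigError("stain vector must be nonzero")
    return tuple((a / n).tolist())


@dataclass
class PipelineConfig:
    seed: int = 0

    # histology rules
    stroma_threshold: float = 0.55
    exclusion_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "outside": 0.50,
            "fold": 0.50,
            "lumen": 0.80,
            "uncertain": 0.50,
        }
    )

    # gene / spot filtering and normalization
    min_gene_reads: int = 10
    min_gene_spots: int = 10
    min_spot_genes: int = 40
    min_spot_total: int = 100
    median_cell_count: int | None = None  # None -> computed from data

    # differential expression
    de_lfc_threshold: float = 0.5
    de_alpha: float = 0.01
    dispersion_prior_weight: float = 20.0
    ql_prior_df: float = 10.0
    use_library_offset: bool = True

    # stain quantification
    stain_vectors: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        DEFAULT_BLUE,
        DEFAULT_PINK,
    )
    stain_threshold: float = 0.20
    stain_threshold_range: tuple[float, float] = (0.15, 0.30)
    stain_resolution: float = 0.55  # um / pixel at quantification time
    stain_sigma: float = 1.0  # Gaussian prefilter, pixels

    # mixed models / survival
    lmm_alpha: float = 0.05
    spot_diameter: float = 55.0  # um
    spot_spacing: float = 200.0  # um

    def __post_init__(self) -> None:
        self.stain_vectors = (_unit(self.stain_vectors[0]), _unit(self.stain_vectors[1]))
        v1, v2 = (np.asarray(v) for v in self.stain_vectors)
        if np.linalg.norm(np.cross(v1, v2)) < 1e-8:
            raise ConfigError("stain vectors must be linearly independent")
        if not 0.0 <= self.stroma_threshold <= 1.0:
            raise ConfigError("stroma_threshold must be a fraction in [0, 1]")
        for cls, thr in self.exclusion_thresholds.items():
            if not 0.0 <= thr <= 1.0:
                raise ConfigError(f"exclusion threshold for {cls!r} outside [0, 1]")
        for name in (
            "min_gene_reads",
            "min_gene_spots",
            "min_spot_genes",
            "min_spot_total",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("de_lfc_threshold", "stain_threshold", "stain_resolution",
                     "stain_sigma", "spot_diameter", "spot_spacing"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("de_alpha", "lmm_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must be a probability in (0, 1)")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: Mapping[str, Any] | None = None) -> "PipelineConfig":
        """Load config from YAML; `overrides` (e.g. CLI flags) win over file values."""
        path = Path(path)
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"malformed YAML in {path}: expected a mapping")
        if overrides:
            data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys in {path}: {sorted(unknown)}")
        if "exclusion_thresholds" in data:
            base = dict(cls().exclusion_thresholds)
            base.update(data["exclusion_thresholds"])
            data["exclusion_thresholds"] = base
        return cls(**data)
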