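"""Pipeline-wide parameters.

Every numeric constant used by the analysis stages lives in
:class:`PipelineParams`, so a single config file (flat YAML key/value)
controls the whole run.  Defaults follow the published analysis protocol
this package implements: log-normalization scale factor 10,000, QC bounds
of 200-6,000 detected genes and <5% mitochondrial reads, 2,000 highly
variable genes for clustering and 4,500 for prototype training, 30
principal components, Louvain resolution 0.5, kNN k = 15, a similarity
threshold of 0.70 for subtype assignment, and the standard DEG / volcano
cutoffs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class PipelineParams:
    scale_factor: float = 10_000.0
    min_genes: int = 200
    max_genes: int = 6_000
    max_mito: float = 0.05
    n_hvg_cluster: int = 2_000
    n_hvg_ml: int = 4_500
    n_pcs: int = 30
    louvain_resolution: float = 0.5
    knn_k: int = 15
    similarity_tau: float = 0.70
    deg_padj: float = 0.05
    deg_lfc: float = 0.5
    volcano_lfc: float = 0.585
    volcano_neglogp: float = 1.5
    n_perm: int = 1_000
    min_expr_frac: float = 0.10
    score_bins: int = 25
    score_ctrl: int = 100
    min_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.max_mito < 1.0):
            raise ConfigError(f"max_mito must lie in (0, 1), got {self.max_mito}")
        if not (self.min_genes < self.max_genes):
            raise ConfigError(
                f"min_genes ({self.min_genes}) must be < max_genes ({self.max_genes})"
            )
        # tau > 0.5 guarantees at most one class can reach the threshold,
        # so assignment is unique.
        if not (0.5 < self.similarity_tau <= 1.0):
            raise ConfigError(
                f"similarity_tau must lie in (0.5, 1], got {self.similarity_tau}"
            )
        if self.n_perm < 100:
            raise ConfigError(f"n_perm must be >= 100, got {self.n_perm}")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be positive")
        if self.min_expr_frac < 0 or self.min_expr_frac > 1:
            raise ConfigError("min_expr_frac must lie in [0, 1]")
        if self.min_replicates < 1:
            raise ConfigError("min_replicates must be >= 1")


def load_params(config_path: str | Path | None = None) -> PipelineParams:
    """Load run parameters, applying defaults for absent keys.

    Parameters
    ----------
    config_path
        Path to a flat YAML mapping, or ``None`` for all defaults.

    Raises
    ------
    ConfigError
        On unknown keys or invariant violations (named in the message).
    """
    if config_path is None:
        return PipelineParams()
    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {config_path} must be a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(PipelineParams)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    return PipelineParams(**raw)
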