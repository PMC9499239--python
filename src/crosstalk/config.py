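"""Pipeline configuration: one flat record, YAML round-trippable.

Defaults follow the published protocol where it states a value (100 bootstrap
iterations over 80% cell subsamples, differential threshold 20, five CV
folds, min_cells 100, test level 0.05); the rest are this package's own
defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

_PATH_FIELDS = ("matrix", "genes", "cells", "ligand_matrix", "rename_map", "outdir")


@dataclass
class PipelineConfig:
    # paths
    matrix: str | None = None
    genes: str | None = None
    cells: str | None = None
    ligand_matrix: str | None = None
    rename_map: str | None = None
    outdir: str = "crosstalk_out"
    # parameters
    min_cells: int = 100
    n_iter: int = 100
    cell_frac: float = 0.8
    threshold: int = 20
    n_folds: int = 5
    alpha: float = 0.05
    n_perm: int = 100
    dropout: float = 0.0
    seed: int = 0
    # strategy flags
    discretization: str = "gmm"
    lfc_mode: str = "lfc"
    permutation_axis: str = "within_sample"
    direction_sensitive: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def override(self, **kw) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kw.items() if v is not None})
        return PipelineConfig(**data)

    def digest(self) -> str:
        """Hash of the analysis parameters; file locations are excluded so
        the same analysis run from different directories hashes identically."""
        data = {k: v for k, v in asdict(self).items() if k not in _PATH_FIELDS}
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"config={self.digest()} seed={self.seed}"
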