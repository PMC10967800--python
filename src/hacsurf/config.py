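"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the extract -> preprocess -> train pipeline.

    Thresholds default to the study values: surface-residue relative
    accessibility 0.30, mean pLDDT cut 50, length window 100-700,
    significance alpha 0.05, collinearity cut 0.8, Cook's rule 4/n with
    |studentized residual| > 2; SASA probe 1.4 A; SES sweep 1.0-3.6 A step
    0.2; five 80/20 splits with five-fold grid-search CV.
    """

    structure_dir: str = "structures"
    manifest: str = "manifest.csv"
    output_dir: str = "output"

    surface_threshold: float = 0.30
    min_mean_plddt: float = 50.0
    min_length: int = 100
    max_length: int = 700
    alpha: float = 0.05
    collinearity_threshold: float = 0.8
    resid_threshold: float = 2.0

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    fd_radius_min: float = 1.0
    fd_radius_max: float = 3.6
    fd_radius_step: float = 0.2
    voxel: float = 0.5
    pH: float = 7.0

    n_repeats: int = 5
    cv_folds: int = 5
    split_seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    algorithms: list[str] = field(default_factory=lambda: ["KNN", "RF", "SVM", "LR"])

    def fd_radii(self):
        import numpy as np

        return np.round(
            np.arange(self.fd_radius_min, self.fd_radius_max + 1e-9, self.fd_radius_step), 10
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
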