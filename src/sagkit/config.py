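"""Declarative pipeline configuration.

One YAML file carries the master seed, gate polygons and every analysis
threshold.  All randomness in a run flows from the single seed through
per-stage derived streams, so a full report bundle reproduces bit-identically
from its config.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cytometry import Gate

__all__ = ["PipelineConfig", "DEFAULT_GATES"]

#: Default rectangular gates on the (log10 SSC, log10 FL1) dot plot: the
#: labeled-cell gate sits in the prokaryote scatter range above the
#: fluorescence background; the bead gate brackets the bright calibration
#: microspheres.
DEFAULT_GATES: dict[str, list[list[float]]] = {
    "labeled_cells": [[1.2, 2.2], [2.9, 2.2], [2.9, 4.5], [1.2, 4.5]],
    "beads": [[3.05, 3.2], [4.2, 3.2], [4.2, 4.6], [3.05, 4.6]],
}


@dataclass
class PipelineConfig:
    seed: int = 0
    gates: dict[str, list[list[float]]] = field(
        default_factory=lambda: {k: [list(v) for v in vs] for k, vs in DEFAULT_GATES.items()}
    )
    phylotype_identity: float = 99.0
    rank_sum_alpha: float = 0.05
    ani_fragment_length: int = 1020
    ani_identity_floor: float = 30.0
    ani_coverage_floor: float = 0.7
    pca_n_pcs: int = 8
    pca_z_cutoff: float = 3.0
    amplitude_floor_fraction: float = 0.1
    unifrac_normalized: bool = True
    output_dir: str = "sagkit_run"

    def __post_init__(self) -> None:
        if not 0 < self.phylotype_identity <= 100:
            raise ValueError("phylotype_identity must lie in (0, 100]")
        if not 0 < self.rank_sum_alpha < 1:
            raise ValueError("rank_sum_alpha must lie in (0, 1)")
        if self.ani_fragment_length < 100:
            raise ValueError("ani_fragment_length too small")
        if not 0 <= self.ani_identity_floor <= 100:
            raise ValueError("ani_identity_floor must lie in [0, 100]")
        if not 0 < self.ani_coverage_floor <= 1:
            raise ValueError("ani_coverage_floor must lie in (0, 1]")
        if self.pca_n_pcs < 1 or self.pca_z_cutoff <= 0:
            raise ValueError("pca_n_pcs must be >= 1 and pca_z_cutoff > 0")
        if not 0 <= self.amplitude_floor_fraction < 1:
            raise ValueError("amplitude_floor_fraction must lie in [0, 1)")
        for name, vertices in self.gates.items():
            Gate(name, vertices)  # validates polygon

    def gate(self, name: str) -> Gate:
        return Gate(name, self.gates[name])

    def stage_seed(self, stage: str) -> int:
        """Derived per-stage seed (< 2**31), stable for a given master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.stage_seed(stage))

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
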