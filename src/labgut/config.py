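"""Pipeline configuration: every numeric threshold in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their field defaults.

    Units: completeness/contamination and detection_threshold are percent;
    sgb_threshold is a genome distance in [0, 1]; prevalence_gate and
    gene_band_* are proportions in [0, 1].
    """

    k: int = 21
    sketch_size: int = 10000
    hash_seed: int = 42
    sgb_threshold: float = 0.05
    detection_threshold: float = 0.01
    prevalence_gate: float = 0.001
    completeness_min_cluster: float = 50.0
    contamination_max: float = 5.0
    completeness_min_enrichment: float = 80.0
    gene_band_lower: float = 0.05
    gene_band_upper: float = 0.95
    fdr_method: str = "BH"
    ksgb_requires_reference: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be >= 1")
        for name in ("sgb_threshold", "prevalence_gate",
                     "gene_band_lower", "gene_band_upper"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gene_band_lower > self.gene_band_upper:
            raise ValueError("gene_band_lower must not exceed gene_band_upper")
        for name in ("detection_threshold", "completeness_min_cluster",
                     "contamination_max", "completeness_min_enrichment"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.fdr_method != "BH":
            raise ValueError(f"unsupported fdr_method {self.fdr_method!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
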