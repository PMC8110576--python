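"""Declarative pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inversion import InversionSettings
from .phantom import PhantomSpec
from .roi import STAGE_CUTOFFS_MPS, VOI_SWS_THRESHOLD_MPS

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything an end-to-end run needs, serializable to a single file."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    inversion: InversionSettings = field(default_factory=InversionSettings)
    stage_cutoffs_mps: dict[int, float] = field(
        default_factory=lambda: dict(STAGE_CUTOFFS_MPS)
    )
    voi_threshold_mps: float = VOI_SWS_THRESHOLD_MPS
    ttest_variant: str = "welch"  # or "student"
    ci_method: str = "delong"
    n_psc: int = 5
    n_viral: int = 5
    n_sources: int = 12
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_cutoffs_mps"] = {int(k): float(v) for k, v in self.stage_cutoffs_mps.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("grid_shape", "voxel_size_mm", "frequencies_hz"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomSpec(**ph)
        if "inversion" in d and isinstance(d["inversion"], dict):
            d["inversion"] = InversionSettings(**d["inversion"])
        if "stage_cutoffs_mps" in d:
            d["stage_cutoffs_mps"] = {
                int(k): float(v) for k, v in d["stage_cutoffs_mps"].items()
            }
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
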