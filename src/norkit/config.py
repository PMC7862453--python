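"""Run configuration: validated, loss-lessly serializable, unknown keys rejected."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    pj_length: int = 40_000
    dj_length: int = 40_000
    n_units: int = 2
    region_lengths: dict[str, int] | None = None  # None = full-scale defaults
    variant_rate: dict[str, float] = Field(
        default_factory=lambda: {
            "5'ETS": 1.5, "18S": 1.5, "ITS1": 1.5, "5.8S": 0.0,
            "ITS2": 1.5, "28S": 1.5, "3'ETS": 1.5, "IGS": 3.0,
        }
    )
    indel_fraction: float = 0.1
    gc_content: float = 0.5
    planted_sites: dict[str, list[int]] = Field(
        default_factory=lambda: {"EcoRV": [20_000, -16_000], "ApaLI": [25_000, -20_000]}
    )
    enzyme_motifs: dict[str, str] = Field(
        default_factory=lambda: {"EcoRV": "GATATC", "ApaLI": "GTGCAC"}
    )


class DesignConfig(_Strict):
    hook_length_min: int = 170
    hook_length_max: int = 200
    search_window: int = 1000


class CloneConfig(_Strict):
    vector_length: int = 10_000
    circular_overlap: int = 500
    rotation: int | None = None  # None = random


class FinishConfig(_Strict):
    min_overlap: int = 100
    max_divergence: float = 0.01
    min_identity: float = 0.95
    min_coverage: float = 0.90


class MergeConfig(_Strict):
    min_overlap: int = 100
    max_mismatch_rate: float = 0.01
    designed_overlap: int = 8000  # PJ-clone / array-clone overlap cut from the NOR


class VariantConfig(_Strict):
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1
    band: int = 200


class StructureConfig(_Strict):
    model: str = "stack"
    windows: tuple[int, ...] = (100, 350)
    n_rand: int = 100
    alpha: float = 0.05
    min_loop: int = 3


class CopiesConfig(_Strict):
    true_copies: float | None = None  # None = n_units
    calibrator_copies: float = 1.0
    n_amplicons: int = 4
    n_replicates: int = 3
    ct_sd: float = 0.2
    efficiency: float = 1.0


class RunConfig(_Strict):
    """Full pipeline configuration; identical (config, seed) => identical report."""

    seed: int = 0
    outdir: str = "norkit_run"
    log_level: str = "INFO"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    clone: CloneConfig = Field(default_factory=CloneConfig)
    finish: FinishConfig = Field(default_factory=FinishConfig)
    merge: MergeConfig = Field(default_factory=MergeConfig)
    variants: VariantConfig = Field(default_factory=VariantConfig)
    structure: StructureConfig = Field(default_factory=StructureConfig)
    copies: CopiesConfig = Field(default_factory=CopiesConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = self.model_dump(exclude={"outdir", "log_level"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:12]
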