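"""Pipeline configuration: one JSON-serializable document for a whole run."""

from __future__ import annotations

import json

from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["BarcodeConfig", "PipelineConfig"]


class BarcodeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    barcode: str
    expected_offset: int = 0


class PipelineConfig(BaseModel):
    """Full parameterization of a pipeline run.

    Unknown keys are rejected so that a typo in a config file fails loudly
    instead of silently running with defaults.
    """

    model_config = ConfigDict(extra="forbid")

    barcodes: list[BarcodeConfig]
    rescue: bool = False
    left_flank: str
    right_flank: str
    min_len: int = 9
    max_len: int = 45
    q_threshold: int = 18
    max_below: int = 3
    amber_as_gln: bool = True
    correct: bool = True
    max_mismatch: int = 2
    min_ratio: float = 10.0
    top_n: int = 200
    cut_height: float = 0.55
    min_size: int = 3
    motifs: list[str] = Field(default_factory=list)
    rarefaction: bool = True
    n_points: int = 50
    repeats: int = 10
    compare: list[list[str]] = Field(default_factory=list)
    seed: int = 0

    @field_validator("barcodes")
    @classmethod
    def _at_least_one_barcode(cls, v):
        if not v:
            raise ValueError("at least one barcode is required")
        return v

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as handle:
            return cls.model_validate(json.load(handle))

    def to_json(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write(self.model_dump_json(indent=2))
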