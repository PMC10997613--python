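"""Run configuration: scale defaults, filename dialect, detector levels.

A single YAML file configures a run; every field has a sensible default so
an empty config is valid.  Example::

    dpi: 8500
    side_codes: {D: abaxial, G: adaxial}
    filename_template: [side, ecotype_label, ecotype_index, "literal:I",
                        replicate, batch, leaf_count]
    egg_level: 0.90
    feces_level: 0.75
    n_females: 10
"""

from __future__ import annotations

from pydantic import BaseModel, Field, field_validator

import yaml

from .detect import ClassicalParams, SignificanceLevels
from .scan_io import DEFAULT_SIDE_CODES, FilenameTemplate

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Validated configuration for a pipeline run."""

    dpi: float | None = Field(default=None, gt=0,
                              description="fallback scan resolution when TIFFs carry no tag")
    side_codes: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_SIDE_CODES))
    filename_template: list[str] = Field(
        default_factory=lambda: list(FilenameTemplate().fields))
    egg_level: float = 0.90
    feces_level: float = 0.75
    n_females: int = Field(default=10, gt=0)
    infestation_hours: float = Field(default=72.0, gt=0)
    min_leaf_length_mm: float = Field(default=4.0, gt=0)
    backend: str = "classical"

    @field_validator("side_codes")
    @classmethod
    def _sides_valid(cls, v: dict) -> dict:
        bad = set(v.values()) - {"abaxial", "adaxial"}
        if bad:
            raise ValueError(f"side codes must map to abaxial/adaxial, got {bad}")
        return v

    @field_validator("backend")
    @classmethod
    def _backend_valid(cls, v: str) -> str:
        if v not in ("classical", "trained"):
            raise ValueError("backend must be 'classical' or 'trained'")
        return v

    @property
    def levels(self) -> SignificanceLevels:
        return SignificanceLevels(eggs=self.egg_level, black_feces=self.feces_level)

    @property
    def template(self) -> FilenameTemplate:
        return FilenameTemplate(fields=tuple(self.filename_template),
                                side_codes=dict(self.side_codes))

    @property
    def params(self) -> ClassicalParams:
        return ClassicalParams()


def load_config(path: str | None) -> RunConfig:
    """Load a YAML config file; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
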