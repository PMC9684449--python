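"""Study configuration: schema, defaults, (de)serialisation.

Defaults reproduce the study conditions: 2 mA total current, 10 mm ROI under
C3, the printed tissue conductivities, all fifteen montages, 2 mm study
grids.  A validated copy of the configuration is written next to every
results directory for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigurationError
from .montage import MONTAGE_NAMES
from .phantom import CSF, DEFAULT_VARIABILITY, GM, SKIN, SKULL, WM, ConductivityMap

_TISSUE_BY_NAME = {"skin": SKIN, "skull": SKULL, "csf": CSF, "gm": GM, "wm": WM}


class StudyConfig(BaseModel):
    """Validated, fully-defaulted study recipe."""

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(default=20, ge=0)
    seed: int = Field(default=0, ge=0)
    voxel_size_mm: float = Field(default=2.0, gt=0)
    current_mA: float = Field(default=2.0, gt=0)
    conductivities: dict = Field(
        default_factory=lambda: {
            "skin": 0.465, "skull": 0.01, "csf": 1.654, "gm": 0.275, "wm": 0.126
        }
    )
    montages: list = Field(default_factory=lambda: list(MONTAGE_NAMES))
    roi_label: str = "C3"
    roi_radius_mm: float = Field(default=10.0, gt=0)
    level_fraction: float = Field(default=0.5, gt=0, le=1)
    peak_percentile: float = Field(default=99.9, gt=0, le=100)
    p99_mask: str = "brain"  # "brain" (gm+wm) or "gm"
    variability: dict = Field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_VARIABILITY.items()
    })
    solver_tol: float = Field(default=1e-8, gt=0)
    output_dir: Optional[str] = None

    @field_validator("conductivities")
    @classmethod
    def _check_sigmas(cls, v):
        unknown = set(v) - set(_TISSUE_BY_NAME)
        if unknown:
            raise ValueError(f"unknown tissues {sorted(unknown)}")
        for name, s in v.items():
            if not s > 0:
                raise ValueError(f"conductivity {name} must be > 0")
        return v

    @field_validator("montages")
    @classmethod
    def _check_montages(cls, v):
        unknown = [m for m in v if m not in MONTAGE_NAMES]
        if unknown:
            raise ValueError(f"unknown montages {unknown}")
        return v

    @field_validator("p99_mask")
    @classmethod
    def _check_mask(cls, v):
        if v not in ("brain", "gm"):
            raise ValueError("p99_mask must be 'brain' or 'gm'")
        return v

    def conductivity_map(self) -> ConductivityMap:
        return ConductivityMap(
            {_TISSUE_BY_NAME[k]: float(v) for k, v in self.conductivities.items()}
        )

    def p99_labels(self) -> tuple:
        return (GM, WM) if self.p99_mask == "brain" else (GM,)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def load_config(path=None) -> StudyConfig:
    """Load a YAML study configuration; empty/missing fields take defaults."""
    data = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        with open(p) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config root must be a mapping")
    try:
        return StudyConfig(**data)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(x) for x in first["loc"]) or "<root>"
        raise ConfigurationError(f"invalid config field {loc}: {first['msg']}") from err
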