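"""Study configuration: schema-validated YAML/JSON with documented defaults.

Units at the interface are fixed: mm (lengths), ms (times), mV (transmembrane
voltage), uV (surface signals), m/s (conduction velocity).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .anatomy import SubjectSpec, default_subjects
from .ap import APParams, IschemiaEndpoints, LAYERS
from .ischemia import DEFAULT_BZ_RADII, DEFAULT_RADII


class SubjectSpecModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    lv_long_axis: float = 75.0
    lv_short_axis: float = 32.0
    wall_thickness_base: float = 10.0
    wall_thickness_apex: float = 7.0
    rv_wall_thickness: float = 4.0
    torso_radius: float = 165.0
    torso_height: float = 640.0
    heart_center_offset: tuple[float, float, float] = (25.0, 40.0, 90.0)
    heart_orientation: tuple[float, float] = (35.0, 20.0)
    rng_seed: int = 0

    def to_spec(self, voxel_size: float) -> SubjectSpec:
        return SubjectSpec(voxel_size=voxel_size, **self.model_dump())


class APParamsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rmv: float
    amplitude: float
    apd90: float
    cv: float


def _default_layers(rmv, amp, apds, cv):
    return {layer: APParamsModel(rmv=rmv, amplitude=amp, apd90=apd, cv=cv)
            for layer, apd in zip(LAYERS, apds)}


class EndpointsModel(BaseModel):
    """AP parameter endpoints: healthy and fully ischemic, per wall layer."""

    model_config = ConfigDict(extra="forbid")

    healthy: dict[str, APParamsModel] = Field(
        default_factory=lambda: _default_layers(-85.0, 125.0, (320.0, 340.0, 300.0), 0.6))
    ciz: dict[str, APParamsModel] = Field(
        default_factory=lambda: _default_layers(-70.0, 95.0, (240.0, 255.0, 225.0), 0.36))

    def to_endpoints(self) -> IschemiaEndpoints:
        return IschemiaEndpoints(
            healthy={k: APParams(**v.model_dump()) for k, v in self.healthy.items()},
            ciz={k: APParams(**v.model_dump()) for k, v in self.ciz.items()})


class StudyConfig(BaseModel):
    """Full study configuration; an empty file yields the default study."""

    model_config = ConfigDict(extra="forbid")

    subjects: list[str] = Field(default_factory=lambda: ["VM-like", "K-like", "D-like"])
    subject_overrides: list[SubjectSpecModel] = Field(default_factory=list)
    voxel_size: float = 1.0
    n_bspm: int = 600
    segments: list[int] = Field(default_factory=lambda: list(range(1, 18)))
    radii_per_subject: dict[str, list[float]] | None = None
    bz_radii: list[float] = Field(default_factory=lambda: list(DEFAULT_BZ_RADII))
    endpoints: EndpointsModel = Field(default_factory=EndpointsModel)
    rng_seed: int = 0
    output_dir: str = "results"

    @field_validator("bz_radii")
    @classmethod
    def _positive_bz(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("bz_radii must be positive")
        return v

    @field_validator("radii_per_subject")
    @classmethod
    def _positive_radii(cls, v):
        if v is not None and any(x <= 0 for subj in v.values() for x in subj):
            raise ValueError("radii_per_subject must be positive")
        return v

    @field_validator("voxel_size")
    @classmethod
    def _voxel(cls, v):
        if not 0 < v <= 2.0:
            raise ValueError("voxel_size must be in (0, 2] mm")
        return v

    @field_validator("segments")
    @classmethod
    def _segments(cls, v):
        if any(not 1 <= s <= 17 for s in v):
            raise ValueError("segments must lie in 1..17")
        return v

    # -- derived objects ---------------------------------------------------

    def subject_specs(self) -> list[SubjectSpec]:
        overrides = {m.name: m for m in self.subject_overrides}
        defaults = {s.name: s for s in default_subjects()}
        specs = []
        for name in self.subjects:
            if name in overrides:
                specs.append(overrides[name].to_spec(self.voxel_size))
            elif name in defaults:
                s = defaults[name]
                s.voxel_size = self.voxel_size
                specs.append(s)
            else:
                raise ValueError(f"unknown subject {name!r} (no override given)")
        return specs

    def radii_map(self) -> dict[str, tuple[float, ...]]:
        if self.radii_per_subject is not None:
            return {k: tuple(v) for k, v in self.radii_per_subject.items()}
        return {s: DEFAULT_RADII.get(s, DEFAULT_RADII["K-like"]) for s in self.subjects}

    def ap_endpoints(self) -> IschemiaEndpoints:
        return self.endpoints.to_endpoints()


def fast_config(seed: int = 0) -> StudyConfig:
    """Desk-scale study: one thin-walled subject, 2 mm voxels, 17 segments x
    2 radii x 1 border zone (34 ischemic setups)."""
    return StudyConfig(subjects=["D-like"], voxel_size=2.0,
                       radii_per_subject={"D-like": [5.0, 25.0]},
                       bz_radii=[4.8], rng_seed=seed)


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML or JSON study configuration.

    An empty file produces the full default study. Unknown keys are rejected
    with an error naming the key.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return StudyConfig(**data)


def save_config(config: StudyConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
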