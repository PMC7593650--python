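"""Run configuration: schema-validated stage parameters.

All physical quantities carry their unit in the field name (um, mm, N, MPa).
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "ConfigError", "VARIANTS"]

VARIANTS = ("individual_meniscus", "individual",
            "generic_two_thickness", "generic_one_thickness")


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown keys {sorted(unknown)} in {cls.__name__}; "
            f"allowed: {sorted(known)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if isinstance(value, dict) and ftype in _SECTION_TYPES:
            value = _from_dict(_SECTION_TYPES[ftype], value)
        kwargs[name] = value
    return cls(**kwargs)


@dataclass
class PhantomConfig:
    voxel_spacing_um: float = 17.4
    noise_sd: float = 5.0
    condyle_radius_lateral_mm: float = 0.55
    condyle_radius_medial_mm: float = 0.50
    cartilage_thickness_femur_mm: float = 0.10
    cartilage_thickness_tibia_mm: float = 0.10
    clearance_lateral_um: float = 18.0
    clearance_medial_um: float = 20.0
    extra_bone_gap_medial_um: float = 60.0


@dataclass
class SegmentationConfig:
    smoothing_sigma_voxels: float = 1.0
    bone_threshold: float | None = None      # None: histogram-suggested
    cartilage_threshold: float = 55.0
    mask_smooth_radius_voxels: float = 2.0
    min_component_voxels: int = 40


@dataclass
class MeniscusConfig:
    max_gap_um: float = 150.0
    superior_clearance_voxels: int = 2


@dataclass
class MeshingConfig:
    target_edge_bone_um: float = 104.4
    target_edge_soft_um: float = 52.2
    distal_layers: int = 2
    top_layers: int = 1
    surface_smooth_iterations: int = 4
    surface_smooth_lambda: float = 0.5
    surface_normal_tol: float = 0.05


@dataclass
class SolverConfig:
    gap_translation_um: float = 87.0
    loading_displacement_um: float = 30.0
    n_steps: int = 4
    n_init_substeps: int = 1
    penalty_stiffness: float | None = None   # None: 50 E_slave / h
    max_iterations: int = 30
    force_rtol: float = 1e-3


@dataclass
class AnalysisConfig:
    target_force_n: float = 0.3
    isolation_neighbors: int = 3
    isolation_radius_factor: float = 3.0
    histogram_bin_mpa: float = 0.2
    histogram_start_mpa: float = 0.2
    baseline_lateral: str = "generic_one_thickness"
    baseline_medial: str = "generic_two_thickness"
    report_surface: str = "cartilage"  # mean/peak from the cartilage pair


_SECTION_TYPES = {
    "PhantomConfig": PhantomConfig,
    "SegmentationConfig": SegmentationConfig,
    "MeniscusConfig": MeniscusConfig,
    "MeshingConfig": MeshingConfig,
    "SolverConfig": SolverConfig,
    "AnalysisConfig": AnalysisConfig,
}


@dataclass
class RunConfig:
    seed: int = 0
    variants: tuple[str, ...] = VARIANTS
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    meniscus: MeniscusConfig = field(default_factory=MeniscusConfig)
    meshing: MeshingConfig = field(default_factory=MeshingConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        self.variants = tuple(self.variants)
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigError(f"unknown variant {v!r}; one of {VARIANTS}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
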