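"""Pipeline configuration: thresholds, radii and seeds, with YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Parameters that drive every stage of the pipeline.

    voxel_p_threshold : uncorrected two-sided voxel-wise p for cluster forming.
    cluster_alpha     : cluster-level familywise alpha.
    n_null_fields     : Monte-Carlo sample size for cluster-size thresholds.
    fdr_q             : Benjamini-Hochberg level for the region-pair matrices.
    seed_radius_mm    : radius of post hoc seed spheres around cluster peaks.
    wm_sphere_radius_mm : radius of the localized white-matter average.
    polynomial_order  : order of the baseline drift model.
    coverage_fraction : minimum share of subjects with data at a voxel.
    z_before_average  : if True, Fisher-z each correlation before averaging in
        connectedness maps; default transforms the per-voxel mean r instead.
    rotation_radius_mm : head radius converting rotations to arc length in the
        motion summary.
    """

    voxel_p_threshold: float = 0.005
    cluster_alpha: float = 0.05
    n_null_fields: int = 1000
    fdr_q: float = 0.05
    seed_radius_mm: float = 6.0
    wm_sphere_radius_mm: float = 15.0
    polynomial_order: int = 4
    coverage_fraction: float = 0.85
    z_before_average: bool = False
    rotation_radius_mm: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_p_threshold", "cluster_alpha", "fdr_q",
                     "coverage_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1 and not (name == "coverage_fraction" and v == 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("seed_radius_mm", "wm_sphere_radius_mm", "rotation_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.polynomial_order < 0:
            raise ValueError("polynomial_order must be >= 0")
        if self.n_null_fields < 100:
            raise ValueError("n_null_fields must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
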