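"""Pipeline configuration: schema-validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Section):
    n_td: int = 22
    n_dl: int = 14
    n_dc: int = 8
    n_dldc: int = 8
    effect_size_delta: float = 8.0
    rho_shared: float = 0.5
    sigma_subject: float = 0.1
    sigma_noise: float = 1.0
    comorbid_rule: str = "additive"
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    motion_severity: float = 0.05
    p_bad_run: float = 0.1
    ar1_coef: float = 0.3
    motion_coupling: float = 0.0
    hrf: str | None = "glover"
    write_bold: bool = True


class QCConfig(_Section):
    voxel_size_mm: float = 2.2
    n_consecutive: int = 2
    min_run_fraction: float = 0.5
    rotation_radius_mm: float = 50.0
    include_rotations: bool = True


class FirstLevelConfig(_Section):
    fwhm_mm: float = 10.0
    voxel_size_mm: float = 2.2
    hrf: str | None = "glover"
    combine: str = "concat"


class GroupConfig(_Section):
    q_fdr: float = 0.05
    alpha_uncorrected: float = 0.001
    ss_type: int = 3


class MVPAConfig(_Section):
    n_repetitions: int = 1000
    n_permutations: int = 1000
    classifier: str = "linear_svm"
    pairing: str = "bijection"
    rois: list[str] = Field(default_factory=lambda: ["whole_brain"])
    save_null_distributions: bool = True


class BehaviorConfig(_Section):
    rt_trials: str = "correct"


class StagesConfig(_Section):
    simulate: bool = True
    qc: bool = True
    first_level: bool = True
    group: bool = True
    mvpa: bool = True
    behavior: bool = True


class PipelineConfig(_Section):
    seed: int = 0
    out_dir: str = "ldpatterns_out"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    first_level: FirstLevelConfig = Field(default_factory=FirstLevelConfig)
    group: GroupConfig = Field(default_factory=GroupConfig)
    mvpa: MVPAConfig = Field(default_factory=MVPAConfig)
    behavior: BehaviorConfig = Field(default_factory=BehaviorConfig)
    stages: StagesConfig = Field(default_factory=StagesConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
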