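"""Run configuration: YAML-backed settings shared by the CLI subcommands."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs besides the input files."""

    # paths
    lesion_dir: str = "lesions"
    cohort_csv: str = "cohort.csv"
    hemisphere: str = "hemisphere.nii.gz"
    out_dir: str = "out"
    # grid expectations
    grid_shape: tuple = (40, 48, 40)
    voxel_mm: float = 4.0
    # pipeline
    k_folds: int = 5
    n_perm_fwe: int = 1000
    n_monte_carlo: int = 10000
    voxel_p: float = 0.005
    cluster_fwe_p: float = 0.05
    min_coverage: int | None = None
    connectivity: int = 26
    tail: str = "deficit"
    models: tuple = ()  # empty = all ten standard variants
    # simulation
    n_patients: int = 70
    n_factors: int = 3
    n_tests: int = 21
    effect_size: float = 1.0
    noise_sd: float = 8.0
    age_coef: float = 0.35
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        for name in ("voxel_p", "cluster_fwe_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a master seed must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["models"] = list(self.models)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path
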