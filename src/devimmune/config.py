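"""Pipeline configuration: schema-validated stage parameters and seeds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

_STAGES = (
    "syndata",
    "preprocess",
    "neighborhoods",
    "datest",
    "markers",
    "pseudode",
    "repertoire",
    "microenv",
    "transfer",
)


@dataclass
class PipelineConfig:
    """End-to-end driver settings; every random stage has an explicit seed."""

    seed: int = 0
    outdir: str = "devimmune_out"
    k: int = 30
    prop: float = 0.05
    bin_width: float = 2.0
    da_fdr: float = 0.1
    organ_fdr: float = 0.01
    marker_min_logfc: float = 1.0
    marker_max_fdr: float = 1e-3
    marker_max_expr_fraction: float = 0.7
    pseudobulk_min_cells: int = 20
    control_lfc_threshold: float = 0.5
    nmf_d: int = 10
    detection_threshold: float = 0.15
    detection_quantile: float = 0.99
    membership_fraction: float = 0.2
    group_sum_threshold: float = 0.8
    spot_quantile: float = 0.90
    transfer_k: int = 30
    skip: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [s for s in self.skip if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) in skip: {bad}; valid: {list(_STAGES)}")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if not 0 < self.prop <= 1:
            raise ValueError("prop must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
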