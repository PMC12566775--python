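"""Pipeline configuration: one structured block per stage, strict keys."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "SimBlock", "SegmentsBlock", "ScanBlock", "BsrBlock", "IntegrateBlock"]


def _from_dict(cls, data: dict, context: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimBlock:
    """Mirrors the simulation configuration (see ``simdata.SimConfig``)."""

    chromosome_lengths_cm: list[float] = field(
        default_factory=lambda: [180.0, 170.0, 160.0, 150.0, 140.0, 130.0, 120.0, 110.0, 105.0, 100.0]
    )
    bp_per_cm: float = 1_000_000.0
    qtls: list[dict] | None = None  # None -> five-QTL default architecture
    mu: float = 0.0
    n_embryos: int = 2194
    n_select_per_class: int = 100
    snp_density: float = 5.0
    missing_rate: float = 0.2
    genotype_error_rate: float = 0.02
    het_undercall_rate: float = 0.05
    bulk_size: int = 50
    bulk_depth_mean: float = 200.0
    n_bulk_reps: int = 2
    n_genes: int = 500


@dataclass
class SegmentsBlock:
    smooth_window: int = 5
    min_snps_per_segment: int = 3
    qc_smooth_window: int = 1
    qc_min_snps_per_segment: int = 2
    qc_multiplier: float = 2.0


@dataclass
class ScanBlock:
    n_perm: int = 1000
    alpha: float = 0.05
    fdr_q: float = 0.01
    lod_drop: float = 1.5
    step_cm: float = 1.0
    lod_threshold: float = 3.0  # fallback/companion LOD cutoff
    min_separation_cm: float = 30.0


@dataclass
class BsrBlock:
    alpha: float = 0.05
    pooling: str = "pool_replicates"


@dataclass
class IntegrateBlock:
    require_concordance: bool = True
    full_containment: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimBlock = field(default_factory=SimBlock)
    segments: SegmentsBlock = field(default_factory=SegmentsBlock)
    scan: ScanBlock = field(default_factory=ScanBlock)
    bsr: BsrBlock = field(default_factory=BsrBlock)
    integrate: IntegrateBlock = field(default_factory=IntegrateBlock)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        blocks = {}
        for name, sub_cls in (
            ("sim", SimBlock),
            ("segments", SegmentsBlock),
            ("scan", ScanBlock),
            ("bsr", BsrBlock),
            ("integrate", IntegrateBlock),
        ):
            if name in data:
                blocks[name] = _from_dict(sub_cls, data.pop(name) or {}, name)
        return cls(**data, **blocks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)
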