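"""Pipeline configuration: schema, validation, and YAML round-trip.

One config drives a multi-sample run: a sample manifest (id, modality
paths, sort gate, patient group), per-stage parameter blocks, and named
seeds. Unknown keys are rejected at load and every referenced path must
exist, so misconfigurations surface before any stage runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .embed import GraphParams
from .qc import QCThresholds


def _build(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ValueError(f"{where}: expected a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class SampleEntry:
    id: str
    path: str
    sort_gate: str = "CD34+"
    group: str | None = None
    n_hvgs: int | None = None       # per-sample dialect overrides
    min_cells: int | None = None


@dataclass
class ProjectionConfig:
    neighbors: int = 5
    threshold: float = 0.5


@dataclass
class ClassifyConfig:
    enabled: bool = False
    signature: str | None = None
    primitive_label: str = "Primitive"
    alpha: float = 0.05


@dataclass
class DemuxConfig:
    doublet_overlap: float = 0.7
    fixed_thresholds: dict = field(default_factory=dict)


@dataclass
class GatesConfig:
    cd26: str = "CD26"
    cd35: str = "CD35"
    cd26_threshold: float | None = None   # None: automatic Otsu placement
    cd35_threshold: float | None = None


@dataclass
class DeconvolutionConfig:
    enabled: bool = False
    bulk: str | None = None
    groups: str | None = None
    n_markers_per_cluster: int = 50


@dataclass
class ReferenceConfig:
    path: str | None = None
    labels: str | None = None     # optional cell_id -> cluster TSV
    leiden_resolution: float = 0.76
    max_mito_fraction: float = 0.06


@dataclass
class PipelineConfig:
    seed: int = 0
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    samples: list[SampleEntry] = field(default_factory=list)
    qc: QCThresholds = field(default_factory=QCThresholds)
    graph: GraphParams = field(default_factory=GraphParams)
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    gates: GatesConfig = field(default_factory=GatesConfig)
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "reference": ReferenceConfig,
    "qc": QCThresholds,
    "graph": GraphParams,
    "demux": DemuxConfig,
    "projection": ProjectionConfig,
    "classify": ClassifyConfig,
    "gates": GatesConfig,
    "deconvolution": DeconvolutionConfig,
}


def parse_config(data: dict, base_dir: Path | None = None) -> PipelineConfig:
    """Build and validate a PipelineConfig from a plain mapping."""
    data = dict(data or {})
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in data:
        if not isinstance(data["seed"], int):
            raise ValueError("config: seed must be an integer")
        kwargs["seed"] = data["seed"]
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], f"config.{name}")
    kwargs["samples"] = [
        _build(SampleEntry, s, f"config.samples[{i}]")
        for i, s in enumerate(data.get("samples", []))
    ]
    config = PipelineConfig(**kwargs)
    _validate_paths(config, base_dir or Path("."))
    if config.classify.enabled and not config.classify.signature:
        raise ValueError("config.classify: enabled but no signature path given")
    if config.deconvolution.enabled and not config.deconvolution.bulk:
        raise ValueError("config.deconvolution: enabled but no bulk table given")
    return config


def _validate_paths(config: PipelineConfig, base_dir: Path) -> None:
    def check(label: str, value: str | None):
        if value is None:
            return
        path = Path(value)
        if not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise ValueError(f"{label}: path does not exist: {value}")

    check("config.reference.path", config.reference.path)
    check("config.reference.labels", config.reference.labels)
    check("config.classify.signature", config.classify.signature)
    check("config.deconvolution.bulk", config.deconvolution.bulk)
    check("config.deconvolution.groups", config.deconvolution.groups)
    for s in config.samples:
        check(f"config.samples[{s.id}].path", s.path)


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    return parse_config(data, base_dir=path.parent)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
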