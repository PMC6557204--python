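"""Pipeline configuration: one flat, validated structure over all stages.

The YAML layout mirrors the module names::

    seed: 0
    source: fixture            # or "simulate"
    sample_order: [primary, recurrent, xeno1, xeno2]
    xenofilter: {mq_high: 30}
    filter: {strandedness_min: 0.1, mmqs_max: 100, dist3p_min: 0.1,
             deep_min_cov: 1000, deep_min_count: 2, deep_min_freq: 0.01,
             somatic_alpha: 0.05}
    timeline: {clonal_af: 0.5, alpha: 0.05, stable_af_tolerance: 0.05}
    allelic_state: {allele_hom: -0.2, allele_het: -0.8, cov_change: 0.32,
                    min_snps: 10}
    simulate: {depth: {primary: 1000, recurrent: 1000, xeno1: 1000, xeno2: 1000}}

Every threshold is validated against its module's ranges before any stage
runs; defaults are embedded and printable via ``oligoclone config --dump``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .allelic_state import SegmentThresholds
from .samples import TUMOR_SAMPLES
from .timeline import TimelineConfig
from .variant_filter import FilterConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    source: str = "fixture"
    sample_order: tuple[str, ...] = TUMOR_SAMPLES
    mq_high: int = 30
    filter: FilterConfig = field(default_factory=FilterConfig)
    clonal_af: float = 0.5
    alpha: float = 0.05
    stable_af_tolerance: float = 0.05
    allelic: SegmentThresholds = field(default_factory=SegmentThresholds)
    depth_per_sample: dict[str, float] = field(
        default_factory=lambda: {s: 1000.0 for s in TUMOR_SAMPLES}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.source not in ("fixture", "simulate"):
            raise ValueError(f"unknown source {self.source!r}")
        if not 0 <= self.mq_high <= 60:
            raise ValueError("mq_high must be in [0, 60]")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        # module configs re-validate their own ranges on construction
        self.timeline_config()

    def timeline_config(self) -> TimelineConfig:
        return TimelineConfig(
            sample_order=tuple(self.sample_order),
            clonal_af=self.clonal_af,
            alpha=self.alpha,
            stable_af_tolerance=self.stable_af_tolerance,
            presence=self.filter,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "source": self.source,
            "sample_order": list(self.sample_order),
            "xenofilter": {"mq_high": self.mq_high},
            "filter": dataclasses.asdict(self.filter),
            "timeline": {
                "clonal_af": self.clonal_af,
                "alpha": self.alpha,
                "stable_af_tolerance": self.stable_af_tolerance,
            },
            "allelic_state": dataclasses.asdict(self.allelic),
            "simulate": {"depth": dict(self.depth_per_sample)},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = data or {}
        return cls(
            seed=int(data.get("seed", 0)),
            source=data.get("source", "fixture"),
            sample_order=tuple(data.get("sample_order", TUMOR_SAMPLES)),
            mq_high=int(data.get("xenofilter", {}).get("mq_high", 30)),
            filter=FilterConfig(**data.get("filter", {})),
            clonal_af=float(data.get("timeline", {}).get("clonal_af", 0.5)),
            alpha=float(data.get("timeline", {}).get("alpha", 0.05)),
            stable_af_tolerance=float(
                data.get("timeline", {}).get("stable_af_tolerance", 0.05)
            ),
            allelic=SegmentThresholds(**data.get("allelic_state", {})),
            depth_per_sample={
                str(k): float(v)
                for k, v in data.get("simulate", {})
                .get("depth", {s: 1000.0 for s in TUMOR_SAMPLES})
                .items()
            },
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
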