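"""Somatic variant selection: support testing, false-positive filtering,
effect-class selection, and deep-sequencing presence calling.

The false-positive filter follows the read-evidence conventions of pileup-
based somatic callers: an alt allele must be seen on both strands (minor-
strand fraction >= 0.1), with a bounded mean mismatch-quality sum on its
reads (<= 100), and not be confined to read ends (mean relative distance to
the effective 3' end >= 0.1).  Presence in deep targeted sequencing requires
coverage >= 1000x, alt count >= 2 and alt fraction >= 1%.  All thresholds
are inclusive on the passing side and configurable.

The somatic-status test is a one-sided Fisher exact test of alt proportions
(tumor vs matched normal); it stands in for a caller-internal somatic
statistic and is flagged as such in reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats


class EffectClass(str, enum.Enum):
    """Predicted coding consequence of a variant (annotation taken as given)."""

    NONSYNONYMOUS = "nonsynonymous_substitution"
    START_CODON_CHANGE = "start_codon_change"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


#: Classes with potential effect at the protein level; everything else is dropped.
PROTEIN_AFFECTING = frozenset(EffectClass) - {EffectClass.OTHER}


@dataclass(frozen=True)
class ReadEvidence:
    """Stranded read counts plus alt-read quality metrics for one locus in
    one sample."""

    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    mismatch_quality_sum: float = 0.0
    avg_dist_3prime: float = 0.5

    def __post_init__(self) -> None:
        if min(self.alt_fwd, self.alt_rev, self.ref_fwd, self.ref_rev) < 0:
            raise ValueError("read counts must be nonnegative")
        if not 0 <= self.avg_dist_3prime <= 1:
            raise ValueError("avg_dist_3prime must be in [0, 1]")

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_fwd + self.ref_rev

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class FilterConfig:
    """All variant-selection thresholds (inclusive on the passing side)."""

    strandedness_min: float = 0.1
    mmqs_max: float = 100.0
    dist3p_min: float = 0.1
    deep_min_cov: int = 1000
    deep_min_count: int = 2
    deep_min_freq: float = 0.01
    somatic_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.strandedness_min <= 0.5:
            raise ValueError("strandedness_min must be in [0, 0.5]")
        if self.mmqs_max < 0 or not 0 <= self.dist3p_min <= 1:
            raise ValueError("invalid read-evidence thresholds")
        if self.deep_min_cov < 1 or self.deep_min_count < 0 or not 0 <= self.deep_min_freq <= 1:
            raise ValueError("invalid deep-sequencing thresholds")
        if not 0 < self.somatic_alpha < 1:
            raise ValueError("somatic_alpha must be in (0, 1)")


SOMATIC = "somatic"
GERMLINE_SUSPECT = "germline_suspect"
UNCALLED = "uncalled"


@dataclass
class SomaticCall:
    status: str
    p_value: float
    note: str = "one-sided Fisher exact stand-in for caller-internal somatic statistic"


def somatic_test(
    tumor: ReadEvidence,
    normal: ReadEvidence,
    alpha: float = 0.05,
    cfg: FilterConfig | None = None,
) -> SomaticCall:
    """Classify a tumor/normal pair as somatic, germline-suspect or uncalled.

    One-sided Fisher exact test of the alt proportion (tumor > normal);
    somatic requires significance at ``alpha`` *and* a normal alt fraction
    below the deep-sequencing detection limit.  Any normal alt fraction at
    or above that limit raises the germline-suspect flag, however small the
    p-value.
    """
    cfg = cfg or FilterConfig()
    if tumor.depth == 0 or normal.depth == 0:
        raise ValueError("somatic_test requires nonzero depth in both samples")
    table = [
        [tumor.alt_count, tumor.depth - tumor.alt_count],
        [normal.alt_count, normal.depth - normal.alt_count],
    ]
    p_value = float(stats.fisher_exact(table, alternative="greater").pvalue)
    if normal.alt_fraction >= cfg.deep_min_freq:
        status = GERMLINE_SUSPECT
    elif p_value <= alpha:
        status = SOMATIC
    else:
        status = UNCALLED
    return SomaticCall(status=status, p_value=p_value)


@dataclass
class FilterResult:
    passed: bool
    reasons: list[str]


def strandedness(ev: ReadEvidence) -> float:
    """Minor-strand fraction of alt reads, in [0, 0.5]."""
    if ev.alt_count == 0:
        raise ValueError("strandedness undefined without alt reads")
    return min(ev.alt_fwd, ev.alt_rev) / ev.alt_count


def fp_filter(ev: ReadEvidence, cfg: FilterConfig | None = None) -> FilterResult:
    """Read-evidence false-positive filter; reasons list every violation.

    Fails on strand bias (minor-strand alt fraction < strandedness_min),
    excessive mean mismatch-quality sum (> mmqs_max), or alt positions
    crowded at read ends (avg_dist_3prime < dist3p_min).
    """
    cfg = cfg or FilterConfig()
    if ev.alt_count == 0:
        raise ValueError("fp_filter requires at least one alt read")
    reasons = []
    if strandedness(ev) < cfg.strandedness_min:
        reasons.append("strandedness")
    if ev.mismatch_quality_sum > cfg.mmqs_max:
        reasons.append("mmqs")
    if ev.avg_dist_3prime < cfg.dist3p_min:
        reasons.append("dist3p")
    return FilterResult(passed=not reasons, reasons=reasons)


def effect_filter(
    variants: Sequence, effects: Iterable[EffectClass | str] | None = None
) -> list:
    """Retain variants whose effect class can alter the protein.

    ``variants`` may be objects with an ``effect`` attribute/key, or
    ``effects`` may be given in parallel.  Retained classes: nonsynonymous
    substitution, start-codon change, stop gain/loss, frameshift.
    """
    if effects is None:
        effects = [
            v.effect if hasattr(v, "effect") else v["effect"] for v in variants
        ]
    kept = []
    for variant, effect in zip(variants, effects, strict=True):
        if EffectClass(effect) in PROTEIN_AFFECTING:
            kept.append(variant)
    return kept


def deep_presence(ev: ReadEvidence, cfg: FilterConfig | None = None) -> bool:
    """Deep-sequencing presence call for one locus in one sample."""
    cfg = cfg or FilterConfig()
    return presence_from_counts(ev.depth, ev.alt_count, cfg)


def presence_from_counts(depth: int, alt_count: int, cfg: FilterConfig | None = None) -> bool:
    """Present iff depth >= min coverage, alt count >= min count, and alt
    fraction >= min frequency (all inclusive).  Pure and threshold-monotone:
    raising alt support at fixed depth never flips present to absent."""
    cfg = cfg or FilterConfig()
    if depth < cfg.deep_min_cov or alt_count < cfg.deep_min_count:
        return False
    return alt_count / depth >= cfg.deep_min_freq
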