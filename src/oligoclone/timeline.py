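"""Temporal ordering of somatic variants across a multi-sample series.

Each variant's deep-sequencing read counts across the ordered tumor samples
are turned into a presence vector (deep-sequencing thresholds), a first
sample of appearance, a clonality call at first appearance (allele
frequency >= 50% places the variant in the majority of cells at the diploid
heterozygous expectation), a rising/stable/falling trend between the first
and following sample (one-sided Fisher exact test of alt proportions), and
a timeline category.  Series summaries reproduce per-sample presence counts
and per-transition new/lost bookkeeping; copy-number events and variants
are interleaved into an ordered event list by first sample of detection.

The blood sample never enters timeline ordering -- it is a germline control
only.  Clonality is classified on raw allele frequencies without
copy-number correction; the copy-aware expected-AF model (``synthetic``)
is available for interpretation but does not reassign categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .samples import BLOOD, TUMOR_SAMPLES
from .variant_filter import FilterConfig, presence_from_counts

RISING = "rising"
STABLE = "stable"
FALLING = "falling"

CATEGORIES = (
    "primary_clonal",
    "primary_subclonal",
    "recurrent_new_clonal",
    "recurrent_new_subclonal",
    "recurrent_only",
    "xeno_new_clonal",
    "xeno_new_subclonal",
)

CLONAL_MAJORITY = "clonal_majority"
SUBCLONAL = "subclonal"


@dataclass(frozen=True)
class TimelineConfig:
    """Thresholds for presence, clonality and trend calling."""

    sample_order: tuple[str, ...] = TUMOR_SAMPLES
    clonal_af: float = 0.5
    alpha: float = 0.05            # one-sided trend test level (stand-in)
    stable_af_tolerance: float = 0.05
    presence: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if not 0 < self.clonal_af <= 1:
            raise ValueError("clonal_af must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if BLOOD in self.sample_order:
            raise ValueError("blood is a germline control; exclude it from timeline order")


@dataclass
class TimelineAssignment:
    locus: str
    gene: str
    presence: dict[str, bool]
    af: dict[str, float]
    first_sample: str
    clonality_at_first: str
    rising: bool
    rising_p: float | None
    trend: str
    category: str
    stable_early: bool = False


@dataclass
class TrendCall:
    trend: str
    p_rising: float
    p_falling: float


def detect_increase(
    alt_first: int,
    depth_first: int,
    alt_next: int,
    depth_next: int,
    alpha: float = 0.05,
) -> TrendCall:
    """Trend of the alt-read proportion between two consecutive samples.

    One-sided Fisher exact tests at level ``alpha``: rising if the later
    proportion significantly exceeds the earlier one, falling for the
    reverse, otherwise stable.
    """
    if depth_first <= 0 or depth_next <= 0:
        raise ValueError("detect_increase requires positive depths")
    if not 0 <= alt_first <= depth_first or not 0 <= alt_next <= depth_next:
        raise ValueError("alt counts must lie within depths")
    table = [[alt_next, depth_next - alt_next], [alt_first, depth_first - alt_first]]
    p_rising = float(stats.fisher_exact(table, alternative="greater").pvalue)
    p_falling = float(stats.fisher_exact(table, alternative="less").pvalue)
    if p_rising <= alpha:
        trend = RISING
    elif p_falling <= alpha:
        trend = FALLING
    else:
        trend = STABLE
    return TrendCall(trend, p_rising, p_falling)


def _categorize(
    first: str, clonal: bool, presence: dict[str, bool], order: tuple[str, ...]
) -> str:
    idx = order.index(first)
    if idx == 0:
        return "primary_clonal" if clonal else "primary_subclonal"
    later = [s for s in order[idx + 1:]]
    if first == order[1] and later and not any(presence.get(s, False) for s in later):
        return "recurrent_only"
    if first == order[1]:
        return "recurrent_new_clonal" if clonal else "recurrent_new_subclonal"
    return "xeno_new_clonal" if clonal else "xeno_new_subclonal"


def call_timeline(
    observations: pd.DataFrame,
    cfg: TimelineConfig | None = None,
) -> tuple[list[TimelineAssignment], list[str]]:
    """Assign a timeline category to every locus in an observation table.

    ``observations`` is a long table with columns locus, gene (optional),
    sample, depth and alt counts (``alt_count_fwd``/``alt_count_rev`` or
    ``alt_count``).  Returns ``(assignments, never_present)`` where the
    second list holds loci absent in every ordered sample (reported
    separately, never silently dropped).
    """
    cfg = cfg or TimelineConfig()
    df = observations.copy()
    if "alt_count" not in df.columns:
        df["alt_count"] = df["alt_count_fwd"] + df["alt_count_rev"]
    assignments: list[TimelineAssignment] = []
    never_present: list[str] = []
    for locus, grp in df.groupby("locus", sort=False):
        by_sample = {r["sample"]: r for _, r in grp.iterrows()}
        gene = str(grp["gene"].iloc[0]) if "gene" in grp.columns else str(locus)
        presence: dict[str, bool] = {}
        af: dict[str, float] = {}
        for sample in cfg.sample_order:
            row = by_sample.get(sample)
            if row is None:
                continue
            depth, alt = int(row["depth"]), int(row["alt_count"])
            presence[sample] = presence_from_counts(depth, alt, cfg.presence)
            af[sample] = alt / depth if depth else 0.0
        present_samples = [s for s in cfg.sample_order if presence.get(s, False)]
        if not present_samples:
            never_present.append(str(locus))
            continue
        first = present_samples[0]
        clonal = af[first] >= cfg.clonal_af
        # trend between first appearance and the next measured sample
        rising, trend, p_rising = False, STABLE, None
        idx = cfg.sample_order.index(first)
        following = [s for s in cfg.sample_order[idx + 1:] if s in by_sample]
        if following:
            nxt = following[0]
            call = detect_increase(
                int(by_sample[first]["alt_count"]),
                int(by_sample[first]["depth"]),
                int(by_sample[nxt]["alt_count"]),
                int(by_sample[nxt]["depth"]),
                cfg.alpha,
            )
            trend, p_rising = call.trend, call.p_rising
            rising = trend == RISING
        measured = [af[s] for s in cfg.sample_order if s in af and presence.get(s, False)]
        stable_early = (
            first == cfg.sample_order[0]
            and len(measured) == len(cfg.sample_order)
            and max(measured) - min(measured) <= cfg.stable_af_tolerance
        )
        assignments.append(
            TimelineAssignment(
                locus=str(locus),
                gene=gene,
                presence=presence,
                af=af,
                first_sample=first,
                clonality_at_first=CLONAL_MAJORITY if clonal else SUBCLONAL,
                rising=rising,
                rising_p=p_rising,
                trend=trend,
                category=_categorize(first, clonal, presence, cfg.sample_order),
                stable_early=stable_early,
            )
        )
    return assignments, never_present


@dataclass
class SeriesSummary:
    """Presence bookkeeping over the ordered series.

    ``clonal_at_first_strict`` counts first-sample variants at AF >= the
    clonality threshold in the first sample; ``clonal_at_first_with_stable``
    additionally counts variants whose AF stayed stable across the whole
    series (the series-stability argument admits sub-threshold variants as
    early heterozygous events) -- both readings are surfaced, neither is
    preferred.
    """

    sample_order: tuple[str, ...]
    present_counts: dict[str, int]
    new_counts: dict[str, int]
    lost_counts: dict[str, int]
    category_counts: dict[str, int]
    n_rising: int
    clonal_at_first_strict: int
    clonal_at_first_with_stable: int
    n_assigned: int

    def validate(self) -> None:
        order = self.sample_order
        for prev, curr in zip(order, order[1:]):
            lhs = self.present_counts[curr] - self.present_counts[prev]
            if lhs != self.new_counts[curr] - self.lost_counts[curr]:
                raise AssertionError(f"conservation violated at transition {prev}->{curr}")


def summarize_series(
    assignments: list[TimelineAssignment],
    sample_order: tuple[str, ...] = TUMOR_SAMPLES,
) -> SeriesSummary:
    """Per-sample presence counts, per-transition new/lost bookkeeping and
    category counts; enforces count(k+1) = count(k) + new - lost."""
    present_counts = {
        s: sum(a.presence.get(s, False) for a in assignments) for s in sample_order
    }
    new_counts: dict[str, int] = {}
    lost_counts: dict[str, int] = {}
    for prev, curr in zip(sample_order, sample_order[1:]):
        new_counts[curr] = sum(
            not a.presence.get(prev, False) and a.presence.get(curr, False)
            for a in assignments
        )
        lost_counts[curr] = sum(
            a.presence.get(prev, False) and not a.presence.get(curr, False)
            for a in assignments
        )
    category_counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        category_counts[a.category] += 1
    first = sample_order[0] if sample_order else None
    strict = sum(
        a.first_sample == first and a.clonality_at_first == CLONAL_MAJORITY
        for a in assignments
    )
    with_stable = sum(
        a.first_sample == first
        and (a.clonality_at_first == CLONAL_MAJORITY or a.stable_early)
        for a in assignments
    )
    summary = SeriesSummary(
        sample_order=sample_order,
        present_counts=present_counts,
        new_counts=new_counts,
        lost_counts=lost_counts,
        category_counts=category_counts,
        n_rising=sum(a.rising for a in assignments),
        clonal_at_first_strict=strict,
        clonal_at_first_with_stable=with_stable,
        n_assigned=len(assignments),
    )
    summary.validate()
    return summary


@dataclass(frozen=True)
class OrderedEvent:
    label: str
    kind: str            # "variant" or "copy_number"
    first_sample: str
    clonal: bool


def order_events(
    assignments: list[TimelineAssignment],
    cn_events: pd.DataFrame | None = None,
    sample_order: tuple[str, ...] = TUMOR_SAMPLES,
) -> list[OrderedEvent]:
    """Interleave variants and copy-number events into acquisition order.

    Events are bucketed by the sample of first detection; within a bucket
    clonal events precede subclonal ones and remaining ties keep a stable
    sort by label.  ``cn_events`` needs columns event, first_sample and
    (optionally) clonal.
    """
    events = [
        OrderedEvent(
            label=a.gene or a.locus,
            kind="variant",
            first_sample=a.first_sample,
            clonal=a.clonality_at_first == CLONAL_MAJORITY,
        )
        for a in assignments
    ]
    if cn_events is not None:
        for _, row in cn_events.iterrows():
            events.append(
                OrderedEvent(
                    label=str(row["event"]),
                    kind="copy_number",
                    first_sample=str(row["first_sample"]),
                    clonal=bool(row.get("clonal", True)),
                )
            )
    for e in events:
        if e.first_sample not in sample_order:
            raise ValueError(f"event {e.label}: unknown sample {e.first_sample}")
    return sorted(
        events, key=lambda e: (sample_order.index(e.first_sample), not e.clonal, e.label)
    )
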