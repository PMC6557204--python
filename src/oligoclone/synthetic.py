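"""Synthetic data generation for the clonal-evolution pipeline.

Everything the pipeline consumes can be generated here: a clone tree with
per-sample cancer-cell fractions drives binomial read-count sampling at
configurable depth (exome-like ~100x, deep targeted sequencing 1000-36000x);
host/graft read mixtures carry per-origin mapping-quality distributions; exon
coverage/allele tracks realize the four allelic states at a given purity.

The bridge between the clone tree and read counts is the standard purity /
copy-number mixture model for the expected variant allele frequency: for a
variant on ``m`` of ``cn_t`` tumor copies, carried by a fraction ``ccf`` of
tumor cells, in a sample of tumor purity ``p``,

    AF = p*ccf*m / (p*(ccf*cn_t + (1-ccf)*2) + (1-p)*2)

with non-carrier tumor cells and normal cells assumed diploid at the locus.
A clonal heterozygous diploid variant in a pure sample thus sits at AF 0.5;
a clonal variant on the single remaining copy of a hemizygous locus in a
pure xenograft sits at AF 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allelic_state import SegmentState, expected_profile
from .samples import BLOOD, PRIMARY, RECURRENT, TUMOR_SAMPLES, XENO1, XENO2
from .xenofilter import HUMAN, MAX_MQ, MOUSE, ReadAlignmentPair


def expected_af(m: int, cn_t: int, ccf: float, p: float) -> float:
    """Expected variant allele frequency under the purity/copy-number model.

    Parameters
    ----------
    m : mutant copies per carrier tumor cell, ``0 <= m <= cn_t``.
    cn_t : total copies at the locus in carrier tumor cells.
    ccf : cancer-cell fraction -- fraction of tumor cells carrying the
        variant, in [0, 1].
    p : tumor purity of the sample, in [0, 1].

    Monotone nondecreasing in each of ``m``, ``ccf`` and ``p``.
    """
    if not 0 <= ccf <= 1:
        raise ValueError(f"ccf={ccf} outside [0, 1]")
    if not 0 <= p <= 1:
        raise ValueError(f"purity={p} outside [0, 1]")
    if cn_t < 0:
        raise ValueError(f"cn_t={cn_t} negative")
    if not 0 <= m <= cn_t:
        raise ValueError(f"mutant copies m={m} outside [0, cn_t={cn_t}]")
    denom = p * (ccf * cn_t + (1 - ccf) * 2) + (1 - p) * 2
    if denom == 0:  # no sequenceable copies at all (pure tumor, total loss)
        return 0.0
    return p * ccf * m / denom


@dataclass
class Clone:
    """One subclone: its parent, per-sample fraction of tumor cells, and the
    variants / copy-number events it acquired (inherited by descendants)."""

    id: str
    parent: str | None
    fraction_per_sample: dict[str, float]
    variants_acquired: frozenset[str] = frozenset()
    cn_events_acquired: frozenset[tuple[str, str]] = frozenset()


@dataclass
class ClonalModel:
    """Clone tree plus per-sample purity and per-locus copy states.

    ``copy_state`` maps ``(locus, sample)`` to ``(cn_t, m)`` -- total and
    mutant copies in carrier tumor cells; loci absent from the map are
    diploid heterozygous ``(2, 1)``.  Blood is constrained to purity 0 and
    xenografts to purity 1 (any stromal contamination in a xenograft is
    mouse, so every human cell is tumor).
    """

    clones: list[Clone]
    purity_per_sample: dict[str, float]
    copy_state: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    samples: tuple[str, ...] = TUMOR_SAMPLES

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone ids")
        known = set(ids)
        for clone in self.clones:
            if clone.parent is not None and clone.parent not in known:
                raise ValueError(f"clone {clone.id}: unknown parent {clone.parent}")
            for frac in clone.fraction_per_sample.values():
                if not 0 <= frac <= 1:
                    raise ValueError(f"clone {clone.id}: fraction outside [0, 1]")
        for sample in self.samples:
            total = sum(c.fraction_per_sample.get(sample, 0.0) for c in self.clones)
            if total > 1 + 1e-9:
                raise ValueError(f"clone fractions in {sample} sum to {total} > 1")
        for sample, p in self.purity_per_sample.items():
            if not 0 <= p <= 1:
                raise ValueError(f"purity of {sample} outside [0, 1]")
        if self.purity_per_sample.get(BLOOD, 0.0) != 0.0:
            raise ValueError("blood purity must be 0")
        for xeno in (XENO1, XENO2):
            if xeno in self.purity_per_sample and self.purity_per_sample[xeno] != 1.0:
                raise ValueError(f"{xeno} purity must be 1 (pure graft)")

    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for clone in self.clones:
            for locus in sorted(clone.variants_acquired):
                seen.setdefault(locus, None)
        return list(seen)

    def ccf(self, locus: str, sample: str) -> float:
        """Fraction of tumor cells carrying ``locus``: the summed fraction of
        every clone descending from (or equal to) an acquiring clone."""
        by_id = {c.id: c for c in self.clones}
        total = 0.0
        for clone in self.clones:
            node: Clone | None = clone
            while node is not None:
                if locus in node.variants_acquired:
                    total += clone.fraction_per_sample.get(sample, 0.0)
                    break
                node = by_id.get(node.parent) if node.parent else None
        return min(total, 1.0)

    def expected_af(self, locus: str, sample: str) -> float:
        cn_t, m = self.copy_state.get((locus, sample), (2, 1))
        return expected_af(m, cn_t, self.ccf(locus, sample), self.purity_per_sample[sample])


@dataclass
class SimulationConfig:
    """Depths, seed and dispersion for read-count simulation.

    ``overdispersion`` is the beta-binomial concentration inverse: 0 means
    pure binomial sampling; larger values spread allele fractions with
    Beta(af/od, (1-af)/od) noise.
    """

    depth_per_sample: dict[str, float]
    seed: int = 0
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.depth_per_sample.values()):
            raise ValueError("depths must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")


def _draw_alt(rng: np.random.Generator, depth: int, af: float, overdispersion: float) -> int:
    if depth == 0 or af <= 0:
        return 0
    if overdispersion > 0 and 0 < af < 1:
        af = rng.beta(af / overdispersion, (1 - af) / overdispersion)
    return int(rng.binomial(depth, min(af, 1.0)))


def simulate_clonal_series(model: ClonalModel, cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate per-(locus, sample) read counts from a clone tree.

    Depth is Poisson around the configured per-sample mean; alt reads are
    binomial (beta-binomial when overdispersed) at the model's expected AF,
    split uniformly over strands.  Seeded and bit-reproducible.
    """
    if not model.clones:
        raise ValueError("model has no clones")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for locus in model.loci():
        for sample in model.samples:
            if sample not in cfg.depth_per_sample:
                continue
            depth = int(rng.poisson(cfg.depth_per_sample[sample]))
            af = model.expected_af(locus, sample)
            alt = _draw_alt(rng, depth, af, cfg.overdispersion)
            alt_fwd = int(rng.binomial(alt, 0.5)) if alt else 0
            ref = depth - alt
            ref_fwd = int(rng.binomial(ref, 0.5)) if ref else 0
            rows.append(
                {
                    "locus": locus,
                    "gene": locus,
                    "sample": sample,
                    "ref_count_fwd": ref_fwd,
                    "ref_count_rev": ref - ref_fwd,
                    "alt_count_fwd": alt_fwd,
                    "alt_count_rev": alt - alt_fwd,
                    "depth": depth,
                    "af": alt / depth if depth else 0.0,
                    "true_af": af,
                    "provenance": "simulated",
                }
            )
    columns = [
        "locus", "gene", "sample", "ref_count_fwd", "ref_count_rev",
        "alt_count_fwd", "alt_count_rev", "depth", "af", "true_af", "provenance",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class OriginMQ:
    """Mapping-quality distribution of reads from one true origin: normal
    means/sds against each reference, sampled, rounded and clipped to
    [0, 60]."""

    mean_human: float
    sd_human: float
    mean_mouse: float
    sd_mouse: float

    def __post_init__(self) -> None:
        for name in ("mean_human", "mean_mouse"):
            if not 0 <= getattr(self, name) <= MAX_MQ:
                raise ValueError(f"{name} outside [0, {MAX_MQ}]")
        if self.sd_human <= 0 or self.sd_mouse <= 0:
            raise ValueError("degenerate (zero/negative sd) MQ distribution")


def default_mq_params(separation: float = 40.0) -> dict[str, OriginMQ]:
    """Well-behaved origin MQ distributions separated by ``separation``
    quality points: each origin maps near MQ 55 on its own genome and
    ``separation`` lower on the other."""
    high, sd = 55.0, 4.0
    low = max(high - separation, 0.0)
    return {
        HUMAN: OriginMQ(high, sd, low, sd + 2),
        MOUSE: OriginMQ(low, sd + 2, high, sd),
    }


def simulate_xenograft_reads(
    n_graft: int,
    n_host: int,
    mq_params: dict[str, OriginMQ] | None = None,
    seed: int = 0,
) -> list[ReadAlignmentPair]:
    """Simulate a graft/host read mixture with true-origin labels.

    Each read carries mapping qualities against both references drawn from
    its true origin's distribution; the labels are for scoring only and are
    never used by the cleaning procedure.
    """
    if n_graft < 0 or n_host < 0:
        raise ValueError("read counts must be nonnegative")
    mq_params = mq_params or default_mq_params()
    rng = np.random.default_rng(seed)
    reads = []
    for origin, n in ((HUMAN, n_graft), (MOUSE, n_host)):
        dist = mq_params[origin]
        mq_h = np.clip(np.rint(rng.normal(dist.mean_human, dist.sd_human, n)), 0, MAX_MQ)
        mq_m = np.clip(np.rint(rng.normal(dist.mean_mouse, dist.sd_mouse, n)), 0, MAX_MQ)
        for i in range(n):
            reads.append(
                ReadAlignmentPair(
                    read_id=f"{origin}_{i}",
                    mq_human=int(mq_h[i]),
                    mq_mouse=int(mq_m[i]),
                    true_origin=origin,
                )
            )
    return reads


def simulate_exon_track(
    segments: list[tuple[str, SegmentState]],
    cfg: SimulationConfig,
    *,
    purity: float = 1.0,
    n_exons: int = 25,
    snp_depth: float = 80.0,
    exon_span: int = 200,
) -> pd.DataFrame:
    """Simulate a BED-like exon coverage + SNP allele-count track.

    Each segment realizes its true state's expected coverage ratio and
    major-allele fraction at the given purity (Poisson coverage, binomial
    allele counts; the major allele is randomly oriented per SNP).  Mean
    exon coverage comes from ``cfg.depth_per_sample['tumor']`` and
    ``['control']`` (default 100x each).
    """
    rng = np.random.default_rng(cfg.seed)
    mean_tumor = cfg.depth_per_sample.get("tumor", 100.0)
    mean_control = cfg.depth_per_sample.get("control", 100.0)
    rows = []
    for seg, state in segments:
        state = SegmentState(state)
        major_frac, cov_ratio = expected_profile(state, purity)
        for i in range(n_exons):
            cov_c = int(rng.poisson(mean_control))
            cov_t = int(rng.poisson(mean_tumor * cov_ratio))
            total = int(rng.poisson(snp_depth))
            a_major = int(rng.binomial(total, major_frac)) if total else 0
            a1, a2 = (a_major, total - a_major) if rng.random() < 0.5 else (total - a_major, a_major)
            start = i * exon_span
            rows.append(
                {
                    "chrom": seg,
                    "start": start,
                    "end": start + exon_span,
                    "exon_id": f"{seg}_exon{i}",
                    "segment": seg,
                    "cov_tumor": cov_t,
                    "cov_control": cov_c,
                    "allele1_count": a1,
                    "allele2_count": a2,
                    "true_state": state.value,
                }
            )
    columns = [
        "chrom", "start", "end", "exon_id", "segment",
        "cov_tumor", "cov_control", "allele1_count", "allele2_count", "true_state",
    ]
    return pd.DataFrame(rows, columns=columns)


def demo_model(
    purity: dict[str, float] | None = None,
    ndst4_like: bool = True,
) -> ClonalModel:
    """A small worked clonal model of the study design.

    A founding clone carries an early heterozygous variant in every sample;
    a subclone carries a late variant on a hemizygous locus whose
    cancer-cell fraction sweeps from ~0.4 in the primary tumor to clonal in
    the recurrence and xenografts -- the trajectory of a variant under
    selection with loss of the wild-type allele.
    """
    purity = purity or {BLOOD: 0.0, PRIMARY: 0.9, RECURRENT: 0.9, XENO1: 1.0, XENO2: 1.0}
    founder = Clone(
        id="founder",
        parent=None,
        fraction_per_sample={PRIMARY: 0.6, RECURRENT: 0.0, XENO1: 0.0, XENO2: 0.0},
        variants_acquired=frozenset({"early_snv"}),
    )
    swept = Clone(
        id="swept",
        parent="founder",
        fraction_per_sample={PRIMARY: 0.4, RECURRENT: 1.0, XENO1: 1.0, XENO2: 1.0},
        variants_acquired=frozenset({"late_snv"} if ndst4_like else frozenset()),
        cn_events_acquired=frozenset({("4q", "copy_loss_LOH")}),
    )
    copy_state = {}
    if ndst4_like:
        # hemizygous in recurrence, duplicated mutant (cnLOH) would be (2, 2)
        copy_state = {
            ("late_snv", PRIMARY): (2, 1),
            ("late_snv", RECURRENT): (1, 1),
            ("late_snv", XENO1): (1, 1),
            ("late_snv", XENO2): (1, 1),
        }
    return ClonalModel(
        clones=[founder, swept],
        purity_per_sample=purity,
        copy_state=copy_state,
    )
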