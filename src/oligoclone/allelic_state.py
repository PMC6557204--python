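"""Exon-level LOH / copy-number state classification.

Tumor/control exome coverage and allele counts at control-heterozygous SNPs
are combined into two per-segment summary statistics:

- the allele log2 ratio, ``log2(MaxCovAllele / (CovAllele1 + CovAllele2))``,
  which is 0 for complete homozygosity and -1 for a balanced heterozygote;
- the coverage log2 ratio, ``log2(cov_tumor / cov_control / f)`` with ``f``
  the genome-wide median tumor/control ratio, which is 0 at copy-neutral
  loci and -1 after loss of one of two copies.

A decision table over the two statistics assigns each segment one of four
states: copy loss with LOH, copy-neutral LOH (one haplotype lost and the
remaining one duplicated), allelic imbalance / copy gain, or conserved
heterozygosity.  The default thresholds bisect the pure-tumor expectations
and are configurable; for impure samples a purity-aware mode classifies by
nearest expected profile instead (see :func:`classify_segment`).

Segmentation is by predefined segment labels (chromosome arms by default);
change-point detection is out of scope.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class SegmentState(str, enum.Enum):
    """Allelic/copy states distinguishable from coverage + allele ratios."""

    COPY_LOSS_LOH = "copy_loss_LOH"
    COPY_NEUTRAL_LOH = "copy_neutral_LOH"
    ALLELIC_IMBALANCE_GAIN = "allelic_imbalance_gain"
    CONSERVED_HET = "conserved_heterozygosity"
    UNINFORMATIVE = "copy_neutral_uninformative"


#: States with a defined ground-truth profile (everything but UNINFORMATIVE).
TRUE_STATES = (
    SegmentState.COPY_LOSS_LOH,
    SegmentState.COPY_NEUTRAL_LOH,
    SegmentState.ALLELIC_IMBALANCE_GAIN,
    SegmentState.CONSERVED_HET,
)


@dataclass(frozen=True)
class ExonObservation:
    """Per-exon coverage and SNP allele counts (0-based half-open coords).

    Allele counts refer to reads over each of the two alleles at SNPs that
    are heterozygous in the control; exons without an informative SNP carry
    ``allele1_count = allele2_count = 0``.
    """

    chrom: str
    start: int
    end: int
    cov_tumor: float
    cov_control: float
    allele1_count: int = 0
    allele2_count: int = 0

    def __post_init__(self) -> None:
        if min(self.cov_tumor, self.cov_control, self.allele1_count, self.allele2_count) < 0:
            raise ValueError("coverage and allele counts must be nonnegative")


@dataclass(frozen=True)
class SegmentThresholds:
    """Decision-table boundaries on the two log2 statistics.

    Defaults bisect the pure-tumor expectations: heterozygous allele log2 is
    -1 and homozygous 0 (boundaries -0.8 and -0.2); one-copy loss gives
    coverage log2 -1, with the half-attenuated boundary at 0.32 ~ log2(1.25).
    """

    allele_hom: float = -0.2   # allele log2 above this => (near-)homozygous
    allele_het: float = -0.8   # allele log2 below this => balanced het
    cov_change: float = 0.32   # |coverage log2| above this => copy change
    min_snps: int = 10         # informative SNPs required for any call


@dataclass
class SegmentCall:
    segment: str
    state: SegmentState
    support: int               # number of informative SNPs
    mean_allele_log2: float
    mean_cov_log2: float


def allele_ratio(a1: int, a2: int) -> float:
    """Major-allele read fraction, ``max(a1, a2) / (a1 + a2)``.

    Symmetric in its arguments and always in [0.5, 1]; 0.5 for a balanced
    heterozygote, 1.0 for complete homozygosity.
    """
    total = a1 + a2
    if total <= 0:
        raise ValueError("allele_ratio undefined for zero total allele count")
    if min(a1, a2) < 0:
        raise ValueError("allele counts must be nonnegative")
    return max(a1, a2) / total


def allele_log2(a1: int, a2: int) -> float:
    """log2 of the major-allele ratio; ranges in [-1, 0]."""
    return math.log2(allele_ratio(a1, a2))


def coverage_log2(cov_tumor: float, cov_control: float, normalization_factor: float = 1.0) -> float:
    """Normalized tumor/control coverage log2 ratio.

    ``normalization_factor`` is the genome-wide median tumor/control ratio,
    so copy-neutral loci sit at 0 regardless of library size.
    """
    if cov_control <= 0:
        raise ValueError("coverage_log2 undefined for zero control coverage")
    if normalization_factor <= 0:
        raise ValueError("normalization factor must be positive")
    return math.log2((cov_tumor / cov_control) / normalization_factor)


def expected_profile(state: SegmentState, purity: float = 1.0) -> tuple[float, float]:
    """Expected (major-allele fraction, tumor/control coverage ratio).

    Mixes the tumor state with a diploid-heterozygous normal component at
    tumor fraction ``purity``.  Copy configurations per state (major/minor
    haplotype copies in tumor cells): conserved het 1/1, copy loss 1/0,
    copy-neutral LOH 2/0, gain 2/1.
    """
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    major_minor = {
        SegmentState.CONSERVED_HET: (1, 1),
        SegmentState.COPY_LOSS_LOH: (1, 0),
        SegmentState.COPY_NEUTRAL_LOH: (2, 0),
        SegmentState.ALLELIC_IMBALANCE_GAIN: (2, 1),
    }
    try:
        major, minor = major_minor[state]
    except KeyError:
        raise ValueError(f"no expected profile for state {state!r}") from None
    q = purity
    a = q * major + (1 - q)       # major-haplotype copies per average cell
    b = q * minor + (1 - q)
    total = a + b
    return max(a, b) / total, total / 2.0


def _expected_log2(state: SegmentState, purity: float) -> tuple[float, float]:
    frac, ratio = expected_profile(state, purity)
    return math.log2(frac), math.log2(ratio)


def classify_segment(
    exons: list[ExonObservation] | pd.DataFrame,
    thresholds: SegmentThresholds | None = None,
    *,
    purity: float | None = None,
    normalization_factor: float = 1.0,
    segment: str = "",
) -> SegmentCall:
    """Call the allelic/copy state of one segment from its exons.

    With ``purity=None`` (default) the decision table over
    (mean allele log2, mean coverage log2) is applied:

    ======================  =====================  ========================
    allele log2             coverage log2          state
    ======================  =====================  ========================
    >= allele_hom (-0.2)    <= -cov_change         copy_loss_LOH
    >= allele_hom           |.| < cov_change       copy_neutral_LOH
    (allele_het, allele_hom) >= cov_change         allelic_imbalance_gain
    <= allele_het (-0.8)    |.| < cov_change       conserved_heterozygosity
    otherwise                                      copy_neutral_uninformative
    ======================  =====================  ========================

    With a ``purity`` the segment is instead assigned the state whose
    expected (allele log2, coverage log2) profile at that purity is nearest
    in Euclidean distance -- the table's boundaries are pure-tumor
    expectations and compress toward uninformative as normal contamination
    rises.  Fewer informative SNPs than ``thresholds.min_snps`` always
    yields ``copy_neutral_uninformative`` (never an exception).

    Invariant to exon ordering within the segment.
    """
    thresholds = thresholds or SegmentThresholds()
    if isinstance(exons, pd.DataFrame):
        exons = [
            ExonObservation(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                cov_tumor=float(r.cov_tumor),
                cov_control=float(r.cov_control),
                allele1_count=int(r.allele1_count),
                allele2_count=int(r.allele2_count),
            )
            for r in exons.itertuples()
        ]
    informative = [e for e in exons if e.allele1_count + e.allele2_count > 0]
    covered = [e for e in exons if e.cov_control > 0]
    support = len(informative)
    if support == 0 or not covered:
        return SegmentCall(segment, SegmentState.UNINFORMATIVE, support, math.nan, math.nan)

    a_log2 = float(np.mean([allele_log2(e.allele1_count, e.allele2_count) for e in informative]))
    c_log2 = float(
        np.mean(
            [coverage_log2(e.cov_tumor, e.cov_control, normalization_factor) for e in covered]
        )
    )
    if support < thresholds.min_snps:
        return SegmentCall(segment, SegmentState.UNINFORMATIVE, support, a_log2, c_log2)

    if purity is not None:
        state = min(
            TRUE_STATES,
            key=lambda s: math.dist((a_log2, c_log2), _expected_log2(s, purity)),
        )
        return SegmentCall(segment, state, support, a_log2, c_log2)

    t = thresholds
    if a_log2 >= t.allele_hom and c_log2 <= -t.cov_change:
        state = SegmentState.COPY_LOSS_LOH
    elif a_log2 >= t.allele_hom and abs(c_log2) < t.cov_change:
        state = SegmentState.COPY_NEUTRAL_LOH
    elif t.allele_het < a_log2 < t.allele_hom and c_log2 >= t.cov_change:
        state = SegmentState.ALLELIC_IMBALANCE_GAIN
    elif a_log2 <= t.allele_het and abs(c_log2) < t.cov_change:
        state = SegmentState.CONSERVED_HET
    else:
        state = SegmentState.UNINFORMATIVE
    return SegmentCall(segment, state, support, a_log2, c_log2)


def classify_track(
    exons: pd.DataFrame,
    thresholds: SegmentThresholds | None = None,
    *,
    purity: float | None = None,
    segment_col: str = "segment",
    normalize: bool = True,
) -> pd.DataFrame:
    """Classify every segment in a BED-like exon table.

    The normalization factor is the genome-wide median tumor/control
    coverage ratio over all exons (1.0 when ``normalize=False``).  Returns
    one row per segment: segment, state, support, mean_allele_log2,
    mean_cov_log2.
    """
    factor = 1.0
    if normalize and len(exons):
        with_cov = exons[exons["cov_control"] > 0]
        if len(with_cov):
            factor = float((with_cov["cov_tumor"] / with_cov["cov_control"]).median())
    rows = []
    for seg, grp in exons.groupby(segment_col, sort=False):
        call = classify_segment(
            grp, thresholds, purity=purity, normalization_factor=factor, segment=str(seg)
        )
        rows.append(
            {
                "segment": call.segment,
                "state": call.state.value,
                "support": call.support,
                "mean_allele_log2": call.mean_allele_log2,
                "mean_cov_log2": call.mean_cov_log2,
            }
        )
    return pd.DataFrame(
        rows, columns=["segment", "state", "support", "mean_allele_log2", "mean_cov_log2"]
    )
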