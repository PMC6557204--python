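"""Disambiguation of graft (human) from host (mouse) reads in xenograft data.

Sequencing a patient-derived xenograft yields a mixture of human tumor reads
and contaminating mouse stromal reads.  The cleaning procedure works on
abstract alignment records -- each read is summarized by its best mapping
quality (MQ) against the human and against the mouse reference -- and runs in
two steps:

1. reads that map strictly better to the mouse genome are deleted;
2. the survivors compete on a chimeric (concatenated human+mouse) genome,
   modeled here as an argmax over the two per-genome MQs, and human-assigned
   reads that nevertheless carry a high mouse MQ are cross-referenced and
   eliminated.

Ties (equal MQ in both genomes) are retained as human: only reads *better* in
mouse are deleted.  An unmapped read is treated as MQ -1, so mapping anywhere
beats mapping nowhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MAX_MQ = 60
UNMAPPED_MQ = -1

HUMAN = "human"
MOUSE = "mouse"


@dataclass
class ReadAlignmentPair:
    """One read's mapping qualities against the graft and host references.

    ``mq_human`` / ``mq_mouse`` are integers in [0, 60] or ``None`` for
    unmapped.  ``true_origin`` is carried by simulated reads for scoring only
    and is never consulted by the cleaning procedure.
    """

    read_id: str
    mq_human: int | None
    mq_mouse: int | None
    assignment: str | None = None
    true_origin: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.mq_human is None and self.mq_mouse is None:
            raise ValueError(f"read {self.read_id!r}: both MQs unmapped")
        for name in ("mq_human", "mq_mouse"):
            mq = getattr(self, name)
            if mq is not None and not 0 <= mq <= MAX_MQ:
                raise ValueError(f"read {self.read_id!r}: {name}={mq} outside [0, {MAX_MQ}]")

    @property
    def _mqh(self) -> int:
        return UNMAPPED_MQ if self.mq_human is None else self.mq_human

    @property
    def _mqm(self) -> int:
        return UNMAPPED_MQ if self.mq_mouse is None else self.mq_mouse


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning run; counts always reconcile:
    ``n_input == n_removed_step1 + n_removed_crossref + n_retained``.

    Sensitivity (fraction of graft reads retained) and specificity (fraction
    of host reads removed) are filled in only when true-origin labels are
    available on every input read.
    """

    n_input: int
    n_removed_step1: int
    n_removed_crossref: int
    n_retained: int
    sensitivity: float | None = None
    specificity: float | None = None

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_step1 + self.n_removed_crossref + self.n_retained:
            raise ValueError("cleaning report counts do not reconcile")


def step1_filter(
    reads: list[ReadAlignmentPair],
) -> tuple[list[ReadAlignmentPair], list[ReadAlignmentPair]]:
    """Delete reads mapping strictly better to the mouse genome.

    Returns ``(survivors, removed)``; the partition is exhaustive and
    disjoint, and ties are kept (the rule requires *higher* mouse MQ).
    """
    survivors, removed = [], []
    for read in reads:
        (removed if read._mqm > read._mqh else survivors).append(read)
    return survivors, removed


def step2_chimeric_assign(survivors: list[ReadAlignmentPair]) -> list[ReadAlignmentPair]:
    """Assign each surviving read to the winning genome of the chimeric
    competition (argmax of the two MQs; ties go to human, as in step 1)."""
    for read in survivors:
        read.assignment = MOUSE if read._mqm > read._mqh else HUMAN
    return survivors


def cross_reference_clean(
    assigned: list[ReadAlignmentPair],
    mq_high_threshold: int = 30,
    *,
    n_removed_step1: int = 0,
) -> tuple[list[ReadAlignmentPair], CleaningReport]:
    """Eliminate human-assigned reads that still map confidently to mouse.

    A read assigned to human but with ``mq_mouse >= mq_high_threshold`` is
    cross-referenced against the mouse set and removed; mouse-assigned reads
    are removed outright.  ``n_removed_step1`` lets the report account for
    reads already deleted upstream.
    """
    if not 0 <= mq_high_threshold <= MAX_MQ:
        raise ValueError(f"mq_high_threshold={mq_high_threshold} outside [0, {MAX_MQ}]")
    retained, crossref_removed = [], []
    for read in assigned:
        if read.assignment == HUMAN and read._mqm < mq_high_threshold:
            retained.append(read)
        else:
            crossref_removed.append(read)
    report = CleaningReport(
        n_input=n_removed_step1 + len(assigned),
        n_removed_step1=n_removed_step1,
        n_removed_crossref=len(crossref_removed),
        n_retained=len(retained),
    )
    _score(report, retained, crossref_removed)
    return retained, report


def clean_reads(
    reads: list[ReadAlignmentPair], mq_high_threshold: int = 30
) -> tuple[list[ReadAlignmentPair], CleaningReport]:
    """Run the full two-step cleaning and return retained human reads.

    Deterministic and order-independent: permuting the input permutes the
    output identically.
    """
    survivors, removed1 = step1_filter(reads)
    assigned = step2_chimeric_assign(survivors)
    retained, report = cross_reference_clean(
        assigned, mq_high_threshold, n_removed_step1=len(removed1)
    )
    # re-score against the full input, including step-1 removals
    kept = {id(r) for r in retained}
    removed = removed1 + [r for r in assigned if id(r) not in kept]
    _score(report, retained, removed)
    return retained, report


def _score(
    report: CleaningReport,
    retained: list[ReadAlignmentPair],
    removed: list[ReadAlignmentPair],
) -> None:
    labeled = all(r.true_origin is not None for r in retained + removed)
    if not labeled or not retained + removed:
        return
    n_graft = sum(r.true_origin == HUMAN for r in retained + removed)
    n_host = len(retained) + len(removed) - n_graft
    if n_graft:
        report.sensitivity = sum(r.true_origin == HUMAN for r in retained) / n_graft
    if n_host:
        report.specificity = sum(r.true_origin == MOUSE for r in removed) / n_host
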