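"""Packaged worked example: an oligodendroglioma / xenograft variant series.

The fixture encodes the deep-sequencing allele-frequency trajectories of an
87-locus somatic variant panel across an ordered sample series (blood,
primary tumor, recurrent tumor, two xenograft passages), as published for a
recurrent 1p/19q-codeleted oligodendroglioma and its derived xenografts:

- 11 loci already detectable in the primary tumor (among them the IDH1
  R132H hotspot, PSKH1 and SNX12 at clonal frequency, and NDST4 on 4q whose
  AF rises from 17.5% to 80% to 100% as the wild-type allele is lost and
  the mutant duplicated);
- 70 loci first detected in the recurrent tumor (63 at clonal frequency,
  including CIC and FUBP1; ZAK and KPNA1 at 20% rising to predominance in
  the xenografts; ARHGAP6 found in the recurrence only, at 12%);
- 6 loci exclusive to the xenografts.

Every allele-frequency cell carries a provenance tag: ``printed`` where the
value is taken from the published per-sample tables or text, ``assumed``
where the series narrative fixes only the qualitative behavior (stable /
clonal / predominant) and a representative value is filled in.  Loci whose
genomic position is unpublished use their gene symbol as locus id; the
anonymous remainder of the inventory is synthetic placeholder rows
(``NOVEL_*``) that reproduce the published per-category counts.

A separate single-locus ``sanger`` panel carries the TERT promoter C250T
variant (detected by targeted Sanger sequencing in all tumors, outside the
87-locus deep-sequencing panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .samples import BLOOD, PRIMARY, RECURRENT, SAMPLES, TUMOR_SAMPLES, XENO1, XENO2
from .variant_filter import EffectClass

PRINTED = "printed"
ASSUMED = "assumed"

DEEP_PANEL = "deep"
SANGER_PANEL = "sanger"

#: Default deep-sequencing depth at which fixture read counts are realized.
DEFAULT_DEPTH = 1000


@dataclass(frozen=True)
class VariantRecord:
    locus: str
    gene: str
    coding_change: str | None
    protein_change: str | None
    effect: EffectClass
    panel: str = DEEP_PANEL


@dataclass
class TrajectoryFixture:
    """Per-(locus, sample) allele-frequency trajectories with provenance.

    ``af_matrix`` maps (locus, sample) to an allele fraction, or ``None``
    for a locus called absent in that sample; missing keys mean no
    measurement.  ``depth_matrix`` gives the deep-sequencing depth for each
    cell and ``provenance`` tags each cell ``printed`` or ``assumed``.
    """

    variants: list[VariantRecord]
    af_matrix: dict[tuple[str, str], float | None]
    depth_matrix: dict[tuple[str, str], int]
    provenance: dict[tuple[str, str], str]
    sample_order: tuple[str, ...] = SAMPLES

    def __post_init__(self) -> None:
        ids = [v.locus for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in fixture")

    @property
    def deep_loci(self) -> list[str]:
        return [v.locus for v in self.variants if v.panel == DEEP_PANEL]

    def record(self, locus: str) -> VariantRecord:
        return next(v for v in self.variants if v.locus == locus)

    def assumed_cells(self, locus: str | None = None) -> list[tuple[str, str]]:
        cells = [k for k, tag in self.provenance.items() if tag == ASSUMED]
        if locus is not None:
            cells = [c for c in cells if c[0] == locus]
        return sorted(cells)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per measured (locus, sample) cell."""
        rows = []
        for v in self.variants:
            for sample in self.sample_order:
                key = (v.locus, sample)
                if key not in self.af_matrix:
                    continue
                af = self.af_matrix[key]
                rows.append(
                    {
                        "locus": v.locus,
                        "gene": v.gene,
                        "sample": sample,
                        "af": np.nan if af is None else af,
                        "absent": af is None,
                        "depth": self.depth_matrix[key],
                        "provenance": self.provenance[key],
                        "effect": v.effect.value,
                        "panel": v.panel,
                    }
                )
        return pd.DataFrame(rows)

    def observations(
        self,
        panel: str = DEEP_PANEL,
        exclude_cells: set[tuple[str, str]] | None = None,
    ) -> pd.DataFrame:
        """Realize the trajectories as a variant-observation read-count table.

        Alt counts are the rounded product of AF and depth (absent cells
        get zero alt reads), split evenly over strands.  ``exclude_cells``
        drops specific (locus, sample) cells, e.g. assumed ones, treating
        them as unmeasured.
        """
        exclude_cells = exclude_cells or set()
        rows = []
        for v in self.variants:
            if v.panel != panel:
                continue
            for sample in self.sample_order:
                key = (v.locus, sample)
                if key not in self.af_matrix or key in exclude_cells:
                    continue
                af = self.af_matrix[key]
                depth = self.depth_matrix[key]
                alt = 0 if af is None else int(round(af * depth))
                ref = depth - alt
                rows.append(
                    {
                        "locus": v.locus,
                        "gene": v.gene,
                        "sample": sample,
                        "ref_count_fwd": ref // 2,
                        "ref_count_rev": ref - ref // 2,
                        "alt_count_fwd": alt // 2,
                        "alt_count_rev": alt - alt // 2,
                        "depth": depth,
                        "af": alt / depth if depth else 0.0,
                        "provenance": self.provenance[key],
                    }
                )
        return pd.DataFrame(rows)

    def arm_events(self) -> pd.DataFrame:
        """Chromosome-arm copy-number events of the series, with the sample
        of first detection: 1p/19q codeletion from the primary tumor;
        chromosome 4, 6q and 14q losses and the 9p/12 copy-neutral LOH from
        the recurrence; the 4q copy-neutral LOH (loss then duplication of
        the mutant-bearing arm) from the first xenograft."""
        rows = [
            ("1p_loss", PRIMARY, True),
            ("19q_loss", PRIMARY, True),
            ("chr4_loss", RECURRENT, True),
            ("6q_loss", RECURRENT, True),
            ("14q_loss", RECURRENT, True),
            ("9p_cnLOH", RECURRENT, True),
            ("chr12_cnLOH", RECURRENT, True),
            ("4q_cnLOH", XENO1, True),
        ]
        return pd.DataFrame(rows, columns=["event", "first_sample", "clonal"])


_MISSENSE = EffectClass.NONSYNONYMOUS

# Loci found in the primary tumor, with their printed primary-tumor AFs.
# trajectory: (primary, recurrent, xeno1, xeno2); None = absent.
_PRIMARY_TABLE = [
    # locus, gene, coding change, protein change, effect, primary AF
    ("chr1:110019535", "SYPL2", "NM_001040709:c.392C>G", "p.Ala131Gly", _MISSENSE, 0.198),
    ("chr13:52539048", "ATP7B", "NM_000053:c.1829C>T", "p.Pro610Leu", _MISSENSE, 0.03),
    ("chr16:67943302", "PSKH1", "NM_006742:c.650G>A", "p.Arg217Gln", _MISSENSE, 0.63),
    ("chr2:209113112", "IDH1", "NM_005896:c.395G>A", "p.Arg132His", _MISSENSE, 0.37),
    ("chr2:73996452", "DUSP11", "NM_003584:c.575A>G", "p.Asp192Gly", _MISSENSE, 0.20),
    ("chr3:119462961", "C3orf15", "NM_033364:c.1820G>A", "p.Arg607Gln", _MISSENSE, 0.11),
    ("chr4:115754766", "NDST4", "NM_022569:c.2392C>G", "p.Leu798Val", _MISSENSE, 0.175),
    ("chr7:143095768", "EPHA1", "NM_005232:c.1262C>A", "p.Ala421Asp", _MISSENSE, 0.10),
    ("chrX:70280873", "SNX12", "NM_001256188:c.470G>A", "p.Arg157His", _MISSENSE, 0.56),
    ("chr1:154067525", "NUP210L", "NM_207308:c.2072delT", "p.Leu691fs", EffectClass.FRAMESHIFT, 0.012),
    ("chr18:46447974", "SMAD7", "NM_001190823:c.484_485insT", "p.Pro162fs", EffectClass.FRAMESHIFT, 0.083),
]

# Primary loci whose AF stayed stable across the whole series (early,
# uniformly distributed heterozygous variants).
_STABLE_PRIMARY = {"PSKH1", "IDH1", "SNX12"}

# Printed later-sample AFs for primary loci (gene -> {sample: af}).
_PRIMARY_LATER_PRINTED = {"NDST4": {RECURRENT: 0.80, XENO1: 1.00}}

# AF a subclonal variant rises to once its clone sweeps (unprinted; the
# published trajectories state the rise, not the endpoint).
_CLONAL_AF = 0.50

# Loci exclusive to the xenografts, with printed xenograft AFs.
_XENO_TABLE = [
    ("chr10:69748523", "HERC4", "NM_015601:c.1703T>C", "p.Val568Ala", _MISSENSE, 0.47, 0.48),
    ("chr1:179497498", "AXDND1", "NM_144696.4:c.2647C>T", "p.Arg883*", EffectClass.STOP_GAIN, 0.28, 0.31),
    ("chr13:52440005", "CCDC70", "NM_031290.2:c.491G>A", "p.Trp164*", EffectClass.STOP_GAIN, 0.31, 0.34),
    ("chr1:52838968", "ORC1", "NM_001190819.1:c.2456C>G", "p.Ser819Cys", _MISSENSE, 1.00, 0.99),
    ("chr6:161501997", "MAP3K4", "NM_005922.2:c.2182G>A", "p.Glu728Lys", _MISSENSE, 0.26, 0.27),
    ("chr4:26426323", "RBPJ", "NM_015874:c.706_707delAA", "p.Lys236fs", EffectClass.FRAMESHIFT, 0.95, 0.95),
]

# Named loci first detected in the recurrent tumor.  ZAK and KPNA1 (20%)
# rose to predominance in the xenografts; ARHGAP6 (12%) was lost again.
# CIC, FUBP1 and ARID1A sit on arms reduced to one haplotype and were
# maintained homozygous through xenograft passage.
_RECURRENT_NAMED = [
    # locus, gene, coding, protein, effect, (recurrent, xeno1, xeno2) AFs, printed-mask
    ("ZAK", "ZAK", "NM_016653:c.1618C>T", "p.Gln540*", EffectClass.STOP_GAIN,
     (0.20, 0.95, 0.95), (True, False, False)),
    ("KPNA1", "KPNA1", "NM_002264:c.179_181delAAG", "p.Glu60del", EffectClass.OTHER,
     (0.20, 0.95, 0.95), (True, False, False)),
    ("ARHGAP6", "ARHGAP6", "NM_013423:c.455G>C", "p.Arg152Pro", _MISSENSE,
     (0.12, None, None), (True, True, True)),
    ("CIC", "CIC", "NM_015125:c.4421T>G", "p.Val1474Gly", _MISSENSE,
     (0.80, 0.80, 0.80), (False, False, False)),
    ("FUBP1", "FUBP1", "NM_003902:c.1307_1310delTAGA", "p.Ile436fs", EffectClass.FRAMESHIFT,
     (0.80, 0.80, 0.80), (False, False, False)),
    ("ARID1A", "ARID1A", "NM_006015:c.2290_2291insC", "p.Gln766fs", EffectClass.FRAMESHIFT,
     (0.80, 0.80, 0.80), (False, False, False)),
    ("TET1", "TET1", "NM_030625:c.4399G>A", "p.Glu1467Lys", _MISSENSE,
     (0.50, 0.50, 0.50), (False, False, False)),
    ("TGFBR2", "TGFBR2", "NM_003242:c.426G>C", "p.Glu142Asp", _MISSENSE,
     (0.50, 0.50, 0.50), (False, False, False)),
]

# Published per-category inventory counts for loci first seen in the
# recurrence: 70 in total, 63 at clonal frequency, 6 subclonal (ZAK, KPNA1
# and four others), 1 recurrence-only (ARHGAP6).
N_RECURRENT_NEW = 70
N_RECURRENT_CLONAL = 63
_N_ANON_CLONAL = N_RECURRENT_CLONAL - 5   # named clonal: CIC, FUBP1, ARID1A, TET1, TGFBR2
_N_ANON_SUBCLONAL = 6 - 2                 # subclonal: ZAK, KPNA1 + anonymous
_SUBCLONAL_AF = 0.20

#: Blood-sample alt fraction of the NUP210L frameshift (probable sequencing
#: error; at the detection limit).
NUP210L_BLOOD_AF = 0.011

TOTAL_DEEP_LOCI = 87


def build_paper_fixture(depth: int = DEFAULT_DEPTH) -> TrajectoryFixture:
    """Construct the packaged worked-example fixture (deterministic).

    All printed table/text cells carry provenance ``printed``; every filled
    value the publication states only qualitatively is tagged ``assumed``.
    The anonymous remainder of the 87-locus inventory (synthetic
    ``NOVEL_*`` placeholder rows) reproduces the per-category counts.
    """
    variants: list[VariantRecord] = []
    af: dict[tuple[str, str], float | None] = {}
    dp: dict[tuple[str, str], int] = {}
    tag: dict[tuple[str, str], str] = {}

    def put(locus: str, sample: str, value: float | None, provenance: str) -> None:
        af[(locus, sample)] = value
        dp[(locus, sample)] = depth
        tag[(locus, sample)] = provenance

    # --- loci present from the primary tumor -----------------------------
    for locus, gene, coding, protein, effect, primary_af in _PRIMARY_TABLE:
        variants.append(VariantRecord(locus, gene, coding, protein, effect))
        put(locus, BLOOD, NUP210L_BLOOD_AF if gene == "NUP210L" else 0.0,
            PRINTED if gene == "NUP210L" else ASSUMED)
        put(locus, PRIMARY, primary_af, PRINTED)
        later_printed = _PRIMARY_LATER_PRINTED.get(gene, {})
        if gene in _STABLE_PRIMARY:
            later = {s: primary_af for s in (RECURRENT, XENO1, XENO2)}
        else:
            later = {s: later_printed.get(s, _CLONAL_AF) for s in (RECURRENT, XENO1, XENO2)}
            if gene == "NDST4":
                later[XENO2] = later[XENO1]  # cnLOH endpoint carried forward
        for sample in (RECURRENT, XENO1, XENO2):
            put(locus, sample, later[sample],
                PRINTED if sample in later_printed else ASSUMED)

    # --- named loci first detected in the recurrence ---------------------
    for locus, gene, coding, protein, effect, trajectory, printed in _RECURRENT_NAMED:
        variants.append(VariantRecord(locus, gene, coding, protein, effect))
        put(locus, BLOOD, 0.0, ASSUMED)
        put(locus, PRIMARY, None, PRINTED)
        for sample, value, is_printed in zip((RECURRENT, XENO1, XENO2), trajectory, printed):
            put(locus, sample, value, PRINTED if is_printed else ASSUMED)

    # --- anonymous recurrence inventory (synthetic placeholders) ---------
    for i in range(_N_ANON_CLONAL):
        locus = f"NOVEL_C{i + 1:02d}"
        variants.append(VariantRecord(locus, locus, None, None, _MISSENSE))
        put(locus, BLOOD, 0.0, ASSUMED)
        put(locus, PRIMARY, None, PRINTED)
        for sample in (RECURRENT, XENO1, XENO2):
            put(locus, sample, _CLONAL_AF, ASSUMED)
    for i in range(_N_ANON_SUBCLONAL):
        locus = f"NOVEL_S{i + 1:02d}"
        variants.append(VariantRecord(locus, locus, None, None, _MISSENSE))
        put(locus, BLOOD, 0.0, ASSUMED)
        put(locus, PRIMARY, None, PRINTED)
        for sample in (RECURRENT, XENO1, XENO2):
            put(locus, sample, _SUBCLONAL_AF, ASSUMED)

    # --- loci exclusive to the xenografts --------------------------------
    for locus, gene, coding, protein, effect, af1, af2 in _XENO_TABLE:
        variants.append(VariantRecord(locus, gene, coding, protein, effect))
        put(locus, BLOOD, 0.0, ASSUMED)
        put(locus, PRIMARY, None, PRINTED)
        put(locus, RECURRENT, None, PRINTED)
        put(locus, XENO1, af1, PRINTED)
        put(locus, XENO2, af2, PRINTED)

    # --- Sanger-only TERT promoter panel ---------------------------------
    tert = VariantRecord(
        "TERT_promoter", "TERT", "NM_198253.2:c.-146G>A", "C250T",
        EffectClass.OTHER, panel=SANGER_PANEL,
    )
    variants.append(tert)
    put(tert.locus, BLOOD, 0.0, ASSUMED)
    for sample in TUMOR_SAMPLES:  # heterozygous in every tumor sample
        put(tert.locus, sample, 0.50, ASSUMED)

    fixture = TrajectoryFixture(variants, af, dp, tag)
    n_deep = len(fixture.deep_loci)
    if n_deep != TOTAL_DEEP_LOCI:
        raise AssertionError(f"fixture inventory has {n_deep} deep loci, expected {TOTAL_DEEP_LOCI}")
    return fixture
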