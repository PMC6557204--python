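"""Readers and writers for the pipeline's tabular formats.

Three dialects are supported: a TSV variant-observation table (the native
interchange format), a minimal VCF dialect mirroring the same fields in
INFO keys, and a BED-like TSV for exon coverage/allele tracks (0-based
half-open coordinates).  TSV round-trips are lossless for all defined
fields; the VCF dialect stores the observation's sample and provenance in
INFO (``SAMPLE``, ``PROV``) so a per-sample table survives the round trip.

Locus ids of the form ``chr2:209113112`` map to VCF CHROM/POS (1-based);
any other label is kept verbatim as CHROM with POS 1, and the original
locus id always travels in the VCF ID column.  Alleles are not modeled:
REF/ALT are written as placeholder ``N``/``A``.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd

VARIANT_COLUMNS = [
    "locus",
    "gene",
    "sample",
    "ref_count_fwd",
    "ref_count_rev",
    "alt_count_fwd",
    "alt_count_rev",
    "depth",
    "af",
    "provenance",
]
_COUNT_COLUMNS = [
    "ref_count_fwd", "ref_count_rev", "alt_count_fwd", "alt_count_rev", "depth",
]

EXON_COLUMNS = [
    "chrom", "start", "end", "exon_id", "segment",
    "cov_tumor", "cov_control", "allele1_count", "allele2_count",
]

READS_COLUMNS = ["read_id", "mq_human", "mq_mouse", "assignment", "removed_stage"]


class FormatError(ValueError):
    """A file failed to parse; the message carries 1-based line numbers."""


def write_variant_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = df.reindex(columns=[c for c in df.columns if c in VARIANT_COLUMNS or c == "true_af"])
    out.to_csv(path, sep="\t", index=False)
    return path


def _validate_variant_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in VARIANT_COLUMNS and c != "true_af"]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=3)
    for col in _COUNT_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() | (values < 0)]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise FormatError(f"{path}: malformed {col!r} at line(s) {lines}")
        df[col] = values.astype(int)
    df["af"] = pd.to_numeric(df["af"], errors="coerce")
    return df[VARIANT_COLUMNS + (["true_af"] if "true_af" in df.columns else [])]


def read_variant_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a variant-observation table in the ``tsv`` or ``vcf-min`` dialect.

    Malformed rows are rejected with their line numbers; unknown columns
    produce a warning, not an error; an empty file yields an empty table
    with a warning.
    """
    path = Path(path)
    if dialect == "vcf-min":
        return read_vcf_min(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty file, returning empty table", stacklevel=2)
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"locus": str, "gene": str, "sample": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, returning empty table", stacklevel=2)
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    except pd.errors.ParserError as err:
        raise FormatError(f"{path}: {err}") from err
    return _validate_variant_frame(df, path)


_LOCUS_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<pos>\d+)$")


def _locus_to_site(locus: str) -> tuple[str, int]:
    match = _LOCUS_RE.match(locus)
    if match:
        return match.group("chrom"), int(match.group("pos"))
    return locus, 1


def write_vcf_min(df: pd.DataFrame, path: str | Path) -> Path:
    """Write observations as the minimal VCF dialect (one record per row)."""
    path = Path(path)
    chroms: list[str] = []
    records = []
    for _, r in df.iterrows():
        chrom, pos = _locus_to_site(str(r["locus"]))
        if chrom not in chroms:
            chroms.append(chrom)
        info = (
            f"SAMPLE={r['sample']};GENE={r['gene']};DP={int(r['depth'])};"
            f"ADF={int(r['ref_count_fwd'])},{int(r['alt_count_fwd'])};"
            f"ADR={int(r['ref_count_rev'])},{int(r['alt_count_rev'])};"
            f"AF={float(r['af']):.6g};PROV={r['provenance']}"
        )
        for key, col in (("MMQS", "mismatch_quality_sum"), ("DIST3P", "avg_dist_3prime"),
                         ("EFFECT", "effect")):
            if col in df.columns and pd.notna(r[col]):
                info += f";{key}={r[col]}"
        filt = str(r["filter"]) if "filter" in df.columns and pd.notna(r.get("filter")) else "PASS"
        records.append(f"{chrom}\t{pos}\t{r['locus']}\tN\tA\t.\t{filt}\t{info}")
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample name">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand ref,alt depths">',
        '##INFO=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand ref,alt depths">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction">',
        '##INFO=<ID=PROV,Number=1,Type=String,Description="Cell provenance tag">',
        '##INFO=<ID=MMQS,Number=1,Type=Float,Description="Mean mismatch quality sum">',
        '##INFO=<ID=DIST3P,Number=1,Type=Float,Description="Mean relative distance to 3-prime end">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class">',
        '##FILTER=<ID=strandedness,Description="Alt minor-strand fraction below threshold">',
        '##FILTER=<ID=mmqs,Description="Mismatch quality sum above threshold">',
        '##FILTER=<ID=dist3p,Description="Alt positions crowd read 3-prime ends">',
        *[f"##contig=<ID={c}>" for c in chroms],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    path.write_text("\n".join(header + records) + "\n")
    return path


def read_vcf_min(path: str | Path) -> pd.DataFrame:
    """Read the minimal VCF dialect back into an observation table."""
    from cyvcf2 import VCF

    path = Path(path)
    rows = []
    for record in VCF(str(path)):
        info = dict(record.INFO)
        adf = info.get("ADF", (0, 0))
        adr = info.get("ADR", (0, 0))
        rows.append(
            {
                "locus": record.ID or f"{record.CHROM}:{record.POS}",
                "gene": info.get("GENE", ""),
                "sample": info.get("SAMPLE", ""),
                "ref_count_fwd": int(adf[0]),
                "ref_count_rev": int(adr[0]),
                "alt_count_fwd": int(adf[1]),
                "alt_count_rev": int(adr[1]),
                "depth": int(info.get("DP", 0)),
                "af": float(info.get("AF", 0.0)),
                "provenance": info.get("PROV", ""),
            }
        )
    if not rows:
        warnings.warn(f"{path}: no records, returning empty table", stacklevel=2)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_exon_track(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in EXON_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", index=False)
    return path


def read_exon_track(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, returning empty table", stacklevel=2)
        return pd.DataFrame(columns=EXON_COLUMNS)
    required = [c for c in EXON_COLUMNS if c != "segment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if "segment" not in df.columns:
        df["segment"] = df["chrom"]
    return df


def write_reads_table(reads, path: str | Path, removed_stage: dict[int, str] | None = None) -> Path:
    """Write alignment pairs as TSV; unmapped MQs are written as ``.``."""
    path = Path(path)
    removed_stage = removed_stage or {}
    rows = []
    for r in reads:
        rows.append(
            {
                "read_id": r.read_id,
                "mq_human": "." if r.mq_human is None else r.mq_human,
                "mq_mouse": "." if r.mq_mouse is None else r.mq_mouse,
                "assignment": r.assignment or ".",
                "removed_stage": removed_stage.get(id(r), "."),
            }
        )
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_reads_table(path: str | Path):
    """Read alignment pairs from TSV (columns read_id, mq_human, mq_mouse)."""
    from .xenofilter import ReadAlignmentPair

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("read_id", "mq_human", "mq_mouse") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    reads = []
    for i, r in df.iterrows():
        try:
            mq_h = None if r["mq_human"] in (".", "", None) else int(r["mq_human"])
            mq_m = None if r["mq_mouse"] in (".", "", None) else int(r["mq_mouse"])
            reads.append(ReadAlignmentPair(read_id=str(r["read_id"]), mq_human=mq_h, mq_mouse=mq_m))
        except (TypeError, ValueError) as err:
            raise FormatError(f"{path}: malformed row at line {int(i) + 2}: {err}") from err
    return reads
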