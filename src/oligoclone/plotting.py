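"""Figure helpers: per-variant AF trajectories and per-segment log2 tracks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .samples import TUMOR_SAMPLES  # noqa: E402


def plot_af_trajectories(
    observations: pd.DataFrame,
    path: str | Path,
    loci: list[str] | None = None,
    sample_order: tuple[str, ...] = TUMOR_SAMPLES,
) -> Path:
    """Line plot of allele-frequency trajectories across the sample series."""
    path = Path(path)
    df = observations
    if loci is not None:
        df = df[df["locus"].isin(loci)]
    fig, ax = plt.subplots(figsize=(6, 4))
    for locus, grp in df.groupby("locus"):
        by_sample = grp.set_index("sample")["af"]
        ys = [by_sample.get(s) for s in sample_order]
        label = grp["gene"].iloc[0] if "gene" in grp.columns else locus
        ax.plot(range(len(sample_order)), ys, marker="o", label=str(label))
    ax.set_xticks(range(len(sample_order)), sample_order)
    ax.set_ylabel("allele frequency")
    ax.set_ylim(0, 1.05)
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    if loci is not None and len(loci) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_segment_track(
    exons: pd.DataFrame,
    calls: pd.DataFrame,
    path: str | Path,
) -> Path:
    """Coverage and allele log2 ratios per exon, annotated with segment calls."""
    import math

    from .allelic_state import allele_log2, coverage_log2

    path = Path(path)
    fig, (ax_cov, ax_all) = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    x = range(len(exons))
    cov = [
        coverage_log2(r.cov_tumor, r.cov_control) if r.cov_control > 0 else math.nan
        for r in exons.itertuples()
    ]
    allele = [
        allele_log2(r.allele1_count, r.allele2_count)
        if r.allele1_count + r.allele2_count > 0
        else math.nan
        for r in exons.itertuples()
    ]
    ax_cov.plot(x, cov, ".", ms=3, color="tab:green")
    ax_cov.set_ylabel("coverage log2")
    ax_all.plot(x, allele, ".", ms=3, color="tab:blue")
    ax_all.set_ylabel("allele log2")
    ax_all.set_xlabel("exon index")
    # annotate segment boundaries and calls
    boundaries = exons["segment"].ne(exons["segment"].shift()).to_numpy().nonzero()[0]
    states = calls.set_index("segment")["state"].to_dict() if len(calls) else {}
    for b in boundaries:
        seg = exons["segment"].iloc[b]
        ax_cov.axvline(b, color="grey", lw=0.5)
        ax_all.axvline(b, color="grey", lw=0.5)
        ax_cov.text(b, ax_cov.get_ylim()[1], f"{seg}\n{states.get(seg, '')}",
                    fontsize=6, va="top")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
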