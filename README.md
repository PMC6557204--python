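# oligoclone

Clonal-evolution analysis of a multi-sample tumor / xenograft sequencing
series.

When a tumor is sampled repeatedly over its clinical course — at first
diagnosis, at recurrence, and after engraftment into immunodeficient mice —
the allele frequency (AF) of each somatic variant in each sample records
which subpopulations of tumor cells carried it and how they expanded or
vanished. `oligoclone` implements the computational steps needed to turn
such a series into a variant-acquisition timeline:

- **Xenograft read disambiguation** (`oligoclone.xenofilter`): a two-step
  cleaning of graft (human) from host (mouse) reads by mapping-quality
  comparison against both genomes, with a cross-reference step that
  eliminates human-assigned reads still mapping confidently to mouse.
- **Allelic-state classification** (`oligoclone.allelic_state`): per-segment
  calls of copy loss with LOH, copy-neutral LOH, allelic imbalance/gain, or
  conserved heterozygosity from the coverage log2 ratio and the allele
  ratio `MaxCovAllele / (CovAllele1 + CovAllele2)` at control-heterozygous
  SNPs.
- **Variant filtering** (`oligoclone.variant_filter`): somatic support
  testing against the matched normal, a read-evidence false-positive filter
  (strandedness ≥ 0.1, mismatch-quality sum ≤ 100, distance to the
  effective 3′ end ≥ 0.1), protein-effect selection, and deep-sequencing
  presence calling (coverage ≥ 1000×, alt count ≥ 2, frequency ≥ 1%).
- **Timeline reconstruction** (`oligoclone.timeline`): per-variant presence
  vectors across the ordered samples, clonality at first appearance
  (AF ≥ 50%), detection of significant AF increases between consecutive
  samples (one-sided Fisher exact test), timeline categories, and series
  summaries with new/lost bookkeeping at every transition.
- **Synthetic data** (`oligoclone.synthetic`): a clone-tree simulator
  (binomial read counts at configurable depth), host/graft read-mixture
  simulation, and exon coverage/allele tracks — every input the pipeline
  consumes can be generated with a seed.
- **Worked example** (`oligoclone.fixture`): a packaged 87-locus variant
  panel from a recurrent 1p/19q-codeleted oligodendroglioma and its
  derived xenografts, with published per-sample allele frequencies and
  provenance tags on every cell.

## The expected-AF model

The bridge between clonal structure and read counts is the standard
purity / copy-number mixture model. For a variant on $m$ of $CN_t$ copies
in carrier tumor cells, carried by a cancer-cell fraction $f$ of tumor
cells, in a sample of tumor purity $p$ (non-carrier tumor cells and normal
cells diploid at the locus):

$$\mathrm{AF} \;=\; \frac{p\,f\,m}{\,p\,\bigl(f\,CN_t + (1-f)\cdot 2\bigr) + (1-p)\cdot 2\,}$$

A clonal heterozygous diploid variant in a pure sample sits at AF 0.5; a
clonal variant on the single remaining copy of a hemizygous locus in a
pure xenograft sits at AF 1.0 — the signature of selection followed by
loss of the wild-type allele, and, after duplication of the mutant arm
(copy-neutral LOH), of complete reduction to homozygosity.

## Worked example

```python
from oligoclone import build_paper_fixture, call_timeline, summarize_series, expected_af

fixture = build_paper_fixture()
assignments, _ = call_timeline(fixture.observations())
summary = summarize_series(assignments)

print("present:", summary.present_counts)
print("new:", summary.new_counts, " lost:", summary.lost_counts)
print("rising variants:", summary.n_rising)
print("clonal in primary (strict >=50%):", summary.clonal_at_first_strict)
print("clonal in primary (incl. stable-AF):", summary.clonal_at_first_with_stable)

ndst4 = next(a for a in assignments if a.gene == "NDST4")
print("NDST4:", {s: round(f, 3) for s, f in ndst4.af.items()},
      ndst4.category, "rising" if ndst4.rising else "stable")
```

prints

```
present: {'primary': 11, 'recurrent': 81, 'xeno1': 86, 'xeno2': 86}
new: {'recurrent': 70, 'xeno1': 6, 'xeno2': 0}  lost: {'recurrent': 0, 'xeno1': 1, 'xeno2': 0}
rising variants: 10
clonal in primary (strict >=50%): 2
clonal in primary (incl. stable-AF): 3
NDST4: {'primary': 0.175, 'recurrent': 0.8, 'xeno1': 1.0, 'xeno2': 1.0} primary_subclonal rising
```

Reading: of the 87 deep-sequenced loci, 11 were already detectable in the
primary tumor, 81 were confirmed in the recurrence (70 newly acquired),
and 86 persisted into the first xenograft (6 new, 1 lost). Ten variants
rose significantly in AF after their first appearance — the NDST4
missense change among them, climbing from a 17.5% subclonal signal in the
primary tumor to fixation in the pure xenograft as chromosome arm 4q went
through loss and copy-neutral LOH. Only two variants exceeded the strict
50% clonality threshold in the primary tumor; a third (the IDH1 R132H
hotspot at 37%) is admitted by its perfectly stable AF across the whole
series.

The same stages are scriptable from a shell:

```sh
oligoclone simulate --kind reads --out reads.tsv --seed 1
oligoclone clean-xeno --in reads.tsv --mq-high 30 --out kept.tsv --report report.json
oligoclone loh --in exons.tsv --out calls.tsv
oligoclone timeline --obs obs.tsv --out timeline.tsv --summary summary.json
oligoclone report --outdir run/
oligoclone config --dump
```

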