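# Methods

## Setting and scope

`oligoclone` analyzes a tumor series ordered in time — germline blood
control, primary tumor, recurrent tumor, first- and second-generation
xenograft — at the level of per-locus read counts. It does not align reads
or call variants from raw sequence: alignment, pileup and primary calling
are upstream concerns, and the package consumes their tabular output
(per-sample ref/alt read counts with strand split and read-evidence
metrics, per-read mapping-quality pairs, per-exon coverage and SNP allele
counts). Everything downstream of those tables — host-read disambiguation,
allelic-state classification, variant filtering, presence calling, and
timeline reconstruction — is implemented and tested here, on synthetic
data and on a packaged worked example.

## The expected-AF mixture model

For a variant on `m` of `CN_t` copies in carrier tumor cells, carried by a
cancer-cell fraction `f`, at sample purity `p`:

    AF = p·f·m / ( p·(f·CN_t + (1−f)·2) + (1−p)·2 )

Assumptions: the locus is diploid in non-carrier tumor cells and in normal
cells; purity and cancer-cell fraction act independently; sampling of
fragments is uniform across cells. The model is monotone nondecreasing in
`m`, `f` and `p`, which makes qualitative reasoning safe: an AF can only
rise through clone expansion, copy gain of the mutant allele, loss of the
wild-type allele, or rising purity. The package uses the model in two
places — as the ground truth of the clone-tree simulator, and as an
interpretive tool (e.g. the fixation of a hemizygous clonal variant at
AF 1.0 in a pure xenograft). It deliberately does **not** reassign
timeline categories: clonality is classified on raw allele frequencies,
because per-locus copy states are rarely known for every variant and a
raw-AF threshold keeps the classification reproducible from the printed
tables alone.

## Xenograft read cleaning

Reads are abstracted to a pair of mapping qualities (MQ, capped at 60;
unmapped treated as −1 so that mapping anywhere beats mapping nowhere).

1. **Competitive deletion** — reads with strictly higher MQ against the
   host (mouse) genome are deleted. Ties are retained: deletion requires
   being *better* in mouse, and at equal evidence the read may well be
   from a conserved region of the graft.
2. **Chimeric assignment and cross-reference** — survivors are assigned to
   the winning genome (argmax of the two MQs, ties to human — consistent
   with step 1), and human-assigned reads whose mouse MQ is still at or
   above `mq_high` (default 30, the conventional confident-mapping cutoff;
   configurable) are eliminated.

The chimeric-genome competition is modeled as the argmax over the two
per-genome MQs rather than a re-alignment; the procedure only consumes MQ
comparisons, so this abstraction preserves its decision behavior without
requiring reference genomes or an aligner. Single-read semantics are used
throughout; requiring mate agreement in paired-end data would be a strict
extension. When origin MQ distributions are well separated (≥ 30 quality
points, with the cross-reference threshold placed between the two
cross-genome means) the procedure retains ≥ 99% of graft reads and removes
≥ 99% of host reads on simulated mixtures; performance degrades smoothly
as the distributions overlap.

## Allelic-state classification

Two statistics summarize a segment (chromosome arms by default —
segmentation by change-point detection is out of scope):

- allele log2: `log2(max(a1,a2)/(a1+a2))` averaged over control-
  heterozygous SNPs; −1 for balanced heterozygosity, 0 for homozygosity;
- coverage log2: `log2((cov_tumor/cov_control)/factor)`, with `factor` the
  genome-wide median tumor/control ratio so library size cancels.

The default decision table encodes pure-tumor expectations: allele log2
≥ −0.2 together with coverage log2 ≤ −0.32 is copy loss with LOH; with
|coverage log2| < 0.32 it is copy-neutral LOH; allele log2 in (−0.8, −0.2)
with coverage log2 ≥ 0.32 is allelic imbalance/gain; allele log2 ≤ −0.8
with neutral coverage is conserved heterozygosity; anything else is
uninformative, as is any segment with fewer than 10 informative SNPs
(guarding against single-SNP artifacts). The boundaries −0.2/−0.8 bisect
the heterozygous (−1) and homozygous (0) expectations; ±0.32 ≈ log2(1.25)
is the half-attenuated coverage boundary. All are configurable.

These boundaries are pure-tumor quantities. At purity `q` the expected
profiles compress — e.g. copy-neutral LOH sits at allele log2
`log2((1+q)/2)`, which is −0.32 at q = 0.6 and would fall outside the
fixed near-homozygous band. For impure samples the classifier therefore
offers a purity-aware mode (`classify_segment(..., purity=q)`) that
assigns the state whose expected (allele log2, coverage log2) profile at
that purity is nearest in Euclidean distance. With ≥ 20 informative SNPs
per segment this recovers 100% of simulated states at purity 1 and ≥ 90%
at purity 0.6.

## Variant filtering

- **False-positive filter** on alt-read evidence, thresholds inclusive on
  the passing side: minor-strand fraction of alt reads ≥ 0.1 (the
  strandedness convention of pileup-based somatic callers), mean
  mismatch-quality sum ≤ 100, mean relative distance of the variant from
  the effective 3′ read end ≥ 0.1. Failure reasons are accumulated, not
  short-circuited, so a report lists every violated criterion.
- **Somatic status**: a one-sided Fisher exact test of alt proportions
  (tumor > normal) at α = 0.05, with a germline-suspect flag whenever the
  normal alt fraction reaches the deep-sequencing detection limit (1%) —
  however significant the tumor contrast. This test is a documented
  stand-in for a caller-internal somatic statistic and is labelled as such
  in its output.
- **Effect selection** retains the protein-affecting classes
  (nonsynonymous substitution, start-codon change, stop gain/loss,
  frameshift); annotations are taken as given input.
- **Deep-sequencing presence**: present iff coverage ≥ 1000×, alt count
  ≥ 2 and alt fraction ≥ 1% (all inclusive). This is the presence
  instrument of the timeline: no separate detection limit is introduced.

## Timeline reconstruction

Samples are ordered (primary, recurrent, xenograft 1, xenograft 2); blood
is excluded from ordering and used only for germline flagging, since a
sub-percent blood signal is more plausibly sequencing error than a
germline variant. Per locus: the first sample with a positive presence
call anchors the timeline; clonality at first appearance is AF ≥ 50%
(the diploid heterozygous expectation — see the model section for why no
copy-number correction is applied); the trend to the next measured sample
is a one-sided Fisher exact test at α = 0.05 (one-sided because the
question is specifically selection, i.e. increase; the α is a
conventional choice, not derived). Categories partition assigned loci:
primary clonal/subclonal, recurrence-new clonal/subclonal,
recurrence-only (present in the recurrence, absent from both xenografts),
xenograft-new clonal/subclonal.

A variant present in every sample whose AF range stays within 0.05 is
additionally flagged `stable_early`: a perfectly flat trajectory across
samples of differing purity and clonal composition argues for an early,
uniformly distributed heterozygous variant even when the raw AF sits below
50%. Series summaries therefore surface two clonal-in-primary counts — the
strict threshold count and the count including stable-AF variants — and
prefer neither; on the packaged fixture they are 2 and 3 (the IDH1 hotspot
at 37% being the stable addition).

Summaries enforce the conservation law `count(k+1) = count(k) + new −
lost` at every transition. Event ordering buckets variants and
copy-number events by the sample of first detection, clonal before
subclonal within a bucket, remaining ties stably sorted by label — no
phylogeny beyond first-appearance bucketing is attempted.

## The synthetic-data generator

The generator emulates the study conditions, not raw sequencing:

- **Clone trees**: clones carry acquired variant sets and per-sample
  fractions of tumor cells (disjoint; carrier fraction is the subtree
  sum); per-locus copy states; per-sample purity with blood fixed at 0 and
  xenografts at 1 (stromal contamination in a xenograft is mouse, so every
  human cell is tumor). Depth is
  Poisson around the configured mean — exome-like ~100×, deep targeted
  sequencing 1000–36000×; fixture realizations use 1000× — and alt counts
  are binomial at the model AF (beta-binomial if overdispersion > 0;
  default 0, as no dispersion information is available, which makes
  simulated AFs slightly cleaner than amplicon data). Strand split is
  symmetric binomial.
- **Read mixtures**: per-origin MQ distributions are rounded, clipped
  normals; defaults put a read near MQ 55 on its own genome and a
  configurable separation lower on the other. True-origin labels are
  carried for scoring only.
- **Exon tracks**: each exon draws Poisson coverages at the state's
  expected tumor/control ratio and one informative SNP with binomial
  allele counts at the state's expected major-allele fraction, with
  random major-allele orientation.

Not emulated: mappability and GC structure, correlated errors along
amplicons, FFPE artifacts, germline variation beyond the two-allele SNP
tracks, and read-level sequence. Passing tests therefore demonstrate the
correctness and calibration of the decision procedures under the stated
sampling models, not robustness to platform-specific artifacts.

The packaged fixture encodes the published per-sample AF tables of the
oligodendroglioma series field-for-field, with provenance tags: `printed`
cells come from the publication's tables or text; `assumed` cells fill
trajectories the publication fixes only qualitatively (the stable IDH1/
PSKH1/SNX12 series carried forward; subclonal risers set to 0.50 once
their clone sweeps; ZAK and KPNA1 xenograft endpoints at 0.95, chosen to
reflect their reported predominance while remaining excludable by tag —
the rising-variant count is computed both with and without them). Where
the publication's text and tables disagree on a primary-tumor AF (DUSP11,
C3orf15, SMAD7, SYPL2, NDST4 differ by rounding or a few points), the
table values are used. The anonymous remainder of the 87-locus inventory
is synthetic placeholder rows (`NOVEL_*`) reproducing the published
per-category counts.

## Numerical and design choices

- Fisher exact tests come from `scipy.stats`; an independent
  hypergeometric-tail enumeration oracle checks them in the tests.
- Tie-breaks: MQ ties retain/assign human; event-ordering ties are stable
  by label; all presence/filter thresholds are inclusive on the passing
  side (a "minimum" is met at equality).
- Degenerate inputs are contracts, not crashes where the domain demands
  it: a segment with no informative SNPs classifies as uninformative; a
  locus absent everywhere is reported separately, never dropped silently.
  Zero depths, zero-total allele counts, out-of-range thresholds and
  invalid clone trees are rejected with parameter-validation errors.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from the configuration; identical configuration + seed yields a
  byte-identical report bundle, and the run manifest records the seed and
  a configuration hash.
- Problem sizes: simulation-based tests use 200 segments × 20 SNPs for
  state recovery, 4000 + 4000 reads per mixture, depth 10⁵ for AF
  convergence (tolerance 0.01), and 100 replicates × 20 variants for
  first-appearance recovery — sizes at which the checked rates are stable
  to well under the asserted margins.

## Limitations

- Clonality from raw AF conflates copy number, purity and cancer-cell
  fraction; the mixture model is provided for interpretation but a full
  subclonal deconvolution (clustering AFs across samples) is out of
  scope.
- The somatic test and the rising-variant test are exact 2×2 tests at
  conventional α; no multiple-testing correction is applied across the
  87-locus panel, matching the worked example's per-variant reading.
- The read cleaner operates on abstract MQ pairs; aligner-specific MQ
  calibration differences are outside its model.
- Segment classification assumes known segment boundaries and a single
  dominant state per segment; subclonal copy-number mixtures classify to
  the nearest profile.
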