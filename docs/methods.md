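# Methods

This note records the models, conventions and open design choices behind
`cbescan`, in the order the pipeline runs.

## Substitution model and hard filtering

A substitution record is one called SNV with the GATK site annotations
QD (QualByDepth), QUAL, SOR (StrandOddsRatio), FS (FisherStrand, phred),
MQ (RMSMappingQuality), MQRankSum and ReadPosRankSum, plus per-sample
allele depths. Multi-allelic VCF rows are decomposed into one record per
alternate allele, since all downstream analysis is per-substitution.
Hard filtering fails a record iff at least one criterion is strictly
violated (QD < 2, QUAL < 30, SOR > 3, FS > 60, MQ < 40, MQRankSum < −12.5,
ReadPosRankSum < −8); a value exactly at its threshold passes, and a
missing annotation never triggers its criterion — GATK omits the rank-sum
annotations at sites without heterozygous read support, and treating
absence as failure would silently discard exactly the high-VAF sites a
base-editing analysis cares about. Filtering is monotone: loosening any
threshold can only convert failures into passes.

VAF is alt_depth / (ref_depth + alt_depth); zero total depth is an error,
not 0. The VAF partition at a cutoff sends the boundary value to the
high side (VAF ≥ c | VAF < c).

## Context windows and orientation

Windows are fixed-length strings with an explicit site offset:
upstream + 1 + downstream bases (40-base form: 20 + 1 + 19; 101-base
form: 50 + 1 + 50). Deamination evidence comes in two strand readings —
C>T (sense) and G>A (antisense) — so by default windows whose central
base is G are taken from the reverse-complement strand, giving every
window a central C and one shared motif convention; a flag disables this
for strand-as-called counting, which changes counts but not the W-
enrichment conclusions. Windows overhanging a contig edge are N-padded to
full length (droppable by option); an N neighbor never satisfies a motif,
so padding is conservative rather than inventive. All intake coordinates
are 1-based (VCF, GTF) and converted to 0-based half-open internally;
BED12 is already half-open.

## Motif classifiers and metrics

A motif rule constrains the two neighbors of the central C: ACW = 5′ ∈
{A}, 3′ ∈ {A,T}; WCW = 5′ ∈ {A,T}, 3′ ∈ {A,T}; NNN predicts every window
positive. ACW ⊆ WCW ⊆ NNN as predictors, which forces positive-class
recall (and per-transcript effective counts, and hence ESD) to be
monotone along that chain — a useful end-to-end invariant. External
models plug in as a sequence → score ∈ [0,1] function thresholded at 0.5.

Metrics are accuracy plus precision/recall/F1 macro-averaged over the
positive and negative classes, with zero-denominator per-class values
contributing 0. Macro averaging is the convention under which the
always-positive baseline has closed forms — accuracy = prevalence, macro
recall = 1/2, macro precision = prevalence/2, macro F1 =
prevalence/(1+prevalence) — and these closed forms are what the analytic
acceptance checks verify on the published corpus compositions.

The stratified benchmark splits a labeled window set into canonical
(ACW present) and non-canonical strata, draws a configured number of
class-balanced subsets (default 10 × 1000 + 1000) without replacement
within a subset from one seeded stream, scores every classifier on every
subset, and compares classifier pairs per metric and stratum with
two-tailed Welch tests across subsets.

## Dataset construction

Two corpus-building styles are implemented. The paired style keeps one
positive (editor-treated) and one negative (control) source sample per
split and removes positives whose exact window sequence also occurs among
the negatives — such sequences show substitution without the editor and
are background, not editing; negatives are untouched. "Overlap" is read
as exact full-window string identity; a genomic-locus mode exists behind
a flag but exact identity is the only reproducible reading and matches
the pooled style's explicit duplicate semantics. The pooled style merges
all samples per class, deduplicates within each class (first occurrence
kept, in input order, mirroring `seqkit rmdup`), removes cross-class
duplicates from the positives while retaining them in the negatives,
splits 7:1.5:1.5 and balances each split by seeded downsampling of the
larger class. Split sizes are floor(n × r/Σr) for eval and test with the
remainder to train — the rounding rule that maps 68,380 items to
47,866/10,257/10,257 exactly. Every stage writes input/retained/removed
counts to a bookkeeping report whose conservation is asserted in tests.
Split membership beyond the counts depends on the seed, which the source
data do not fix; only counts are reproducible.

## PRS scanning and ESD

Within a reading frame, a single C→T can create a stop codon only at the
first position of CAA (→TAA), CAG (→TAG) or CGA (→TGA): no stop codon
has T at its second or third position. `find_prs` is therefore a codon
scan over sense codons; `brute_force_prs` independently substitutes every
C, translates, and reports positions whose substitution introduces a stop
at a sense-codon position — the two are asserted equal on randomized
CDSs (property test and acceptance script).

CDS assembly concatenates exon intervals in transcript order
(reverse-complementing on −) and never fails on an invalid ORF; validity
travels as flags (starts-with-ATG, terminal stop, internal-stop-free,
frame). By Ensembl convention the CDS includes the terminal stop, so
aa_length = codons − 1 when a terminal stop is present and codons
otherwise (flagged). Non-multiple-of-3 CDSs are rejected by default; a
tolerate-frame option trims trailing bases and flags the transcript,
since API-derived CDSs are occasionally incomplete.

PRS contexts default to *genomic* mode — flanks read from the unspliced
genome in transcript orientation, matching how per-site flanking
sequences are retrieved from genomic coordinates — with a *spliced* mode
(flanks from the assembled CDS) available because the biological
substrate is mRNA; the two differ only within an intron's reach of a
junction.

ESD = n_effective / (n_PRS × L_aa) normalizes the effective-PRS count
multiplicatively to both substrate count and protein length, making ESD
a density bounded by 1/L_aa; an additive-denominator variant
n_eff/(n_PRS + L_aa) is selectable for sensitivity analysis, as the
multiplicative reading of "normalized to the total number of substrates
and to the protein length" is a choice, not a theorem. Transcripts with
zero PRSs get ESD 0 and stay in tissue averages (exclusion selectable):
dropping them would bias tissue means toward substrate-rich transcripts.

## Tissue aggregation and high-risk extraction

The tissue table holds {1, −1, 0} per transcript × tissue (tissue-specific
high / low / neither expression). A tissue's group is its 1-marked
transcripts; the "All" background is every transcript with any nonzero
mark anywhere (a transcript may sit in several groups, and each group is
a subset of "All"; the literal background includes the tested tissue's
own transcripts, with exclusion selectable). Each tissue is compared to
"All" by a two-tailed Welch test; identical constant groups are reported
as t = 0, p = 1 (no evidence) rather than NaN, with the degeneracy check
tolerance-based because sums of identical floats carry ~1e-18 noise.
BH-adjusted p-values are always reported alongside raw ones; direction
flags ("elevated"/"reduced") use raw p < α by default, with adjusted-p
flagging selectable, since the visual convention being mirrored marks raw
significance. 

High-risk transcripts are those with ESD strictly above
mean + t<sub>0.975, n−1</sub> × sd of the background — the upper bound of
the two-sided 95% t-interval for *individual* values. An interval of the
mean (SEM-scaled) would shrink with n and flag a growing constant
fraction of transcripts; the individual-value reading is the one
consistent with flagging hundreds rather than tens of thousands, and
SEM-scaled and one-sided variants remain selectable.

## Synthetic studies: what they do and do not show

The generator plants everything the pipeline is supposed to find:

* **Genome**: i.i.d. bases, 2 × 100 kb by default, GC 0.5 — large enough
  that 6 samples yield ~20,000 calls total while the whole suite stays in
  seconds.
* **Transcripts**: 60 models, 1–3 exons, half on −, valid ORFs written
  into the genome (so assembly validity holds by construction); ~120–200
  codons each. Four "high-risk" transcripts are shorter (60–80 codons)
  and receive (A-ending codon, CAA/CAG) pairs at per-codon rate 0.25, so
  their PRS contexts are ACW/WCW-satisfying by construction while
  background PRSs arise at the uniform-codon rate (~3/61 per codon with
  ~25% WCW-effective contexts). The length and context separation is what
  makes the planted transcripts individually exceed the t-interval
  cutoff; the manifest records every transcript's oracle-derived PRS
  offsets.
* **Variants**: editor samples edit each C (and antisense G) with
  probability 0.01 × 6^{5′W} × 2^{3′W} — a strong 5′ and weak 3′
  weak-base preference; both sample kinds add context-uniform background
  substitutions at 5×10⁻³. Each call's quality annotations are drawn
  nominal, except that each criterion independently is drawn violating
  with probability 0.02 (draws keep a margin from the thresholds so VCF
  float round-trips cannot flip a verdict); VAFs are Beta(8,3) for editor
  and Beta(2,2) for control samples. These rates are chosen for test
  power at desk scale, not biological realism — real RNA off-target rates
  are orders of magnitude lower per base.
* **Tissues**: six organ-style columns; the planted high-risk transcripts
  are marked 1 in one designated tissue ("colon"), other transcripts are
  marked 1 elsewhere with probability 0.6 and −1 with probability 0.2.

Everything is drawn from one `numpy` Generator seeded by the config, and
outputs are byte-identical under a fixed seed. What passing tests show:
the implementation recovers exactly what was planted — filter verdicts
per call, motif enrichment between sample groups, PRS positions, ESD
ordering, the elevated tissue, the high-risk set. What they do not show:
performance on real data, where edits cluster on expressed transcripts,
coverage and splicing structure the annotations, motif preferences are
weaker, and duplicate windows are abundant.

## Numerical choices

* Welch tests delegate to scipy (`equal_var=False`); the two degenerate
  constant-group cases are resolved to (0, 1) / (±inf, 0) before scipy
  sees them.
* Metric computation delegates to scikit-learn
  (`precision_recall_fscore_support`, `zero_division=0`); the brute-force
  confusion-matrix oracle in the tests is independent of it.
* The high-risk cutoff uses the sample sd (ddof = 1) and scipy's t
  quantile; sd = 0 collapses the cutoff to the mean.
* Balanced downsampling and splitting use `numpy.random.default_rng`;
  derived stream seeds stay below 2³¹.
* Window FASTA headers encode `chrom:pos:strand:label`; round-trips
  preserve sequence, geometry, origin and label.

## Known limitations

Only single-base C→U (and antisense G→A) substrates are modeled; no
missense or splice-site consequences; no multi-isoform handling beyond
whatever models are supplied; GO enrichment and expression retrieval are
out of scope (tissue tables are file inputs). The learned-model
comparisons that require trained weights are represented only by the
external-scorer contract.
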