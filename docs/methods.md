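# Methods

This note documents the models and procedures implemented in `tagseq3`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and strand conventions

All intervals are 0-based half-open internally; 1-based coordinates appear
only in formats that require them (SAM input). The "start" of a read is its
5'-most sequenced position in read orientation: the leftmost genomic base
for + strand alignments and the rightmost for − strand alignments. The
generator and the peak caller share this convention, which is what makes the
~275 bp offset geometry strand-symmetric.

## Ambiguity filter

Each candidate alignment of a read of length `L` with `m` mismatches gets
likelihood `ε^m (1−ε)^(L−m)` under a constant per-base substitution rate
`ε` (default 0.01). The binomial coefficient is omitted: it is identical for
all candidate alignments of the same read and cancels in the posterior
ratio, which is the only quantity the filter uses. Likelihoods are computed
in log space and normalised by the maximum before exponentiation, so
arbitrarily long reads cannot underflow. A read is kept, retaining its
minimum-mismatch alignment only, when the best-alignment posterior reaches
`posterior_min` (default 0.8).

At the default threshold no tie-breaking rule is ever exercised: two
candidates tied at the minimum mismatch count bound the posterior at 0.5.
For thresholds ≤ 0.5 the lexicographically smallest (chrom, start, strand)
candidate is retained, keeping output deterministic. The test suite proves,
by exhaustive enumeration of mismatch tuples (≤ 4 candidates, ≤ 2
mismatches, L = 25) against a direct-product oracle, that rejection happens
exactly on tied best candidates.

## Peak calling

Read starts pooled over all samples are chained per (chromosome, strand):
consecutive sorted positions at most `merge_gap` (20 bp) apart join one
cluster, and a cluster's interval spans its left-most to right-most read
start. "Within 20 bp" is interpreted as start-to-start distance, and the
peak covers read starts rather than whole alignments — consistent with peak
lengths of the same order as the RNA fragment spread.

Filters apply in a fixed order: clusters need strictly more than
`min_pooled_reads` (150) reads, then at least `min_unique_starts` (25)
distinct positions; peaks antisense (≥ 1 bp overlap, opposite strand) to a
called peak that itself overlaps a known-gene exon on the gene's strand are
removed as library-preparation artifacts; finally a strict
`strict_min_reads` (200) cut. The ≥ 1 bp overlap geometry of the antisense
rule is a design choice; the sense partner must be exonic in a known gene,
so mutually antisense peaks in open intergenic space survive.

Fold enrichment compares observed counts with a global uniform background,
`expected = total_reads × peak_length / mappable_size`, pooled and per
sample. `mappable_size` defaults to 2.7 Gb (a human-scale mappable genome)
and should be set to the toy genome size in simulations; the 150-read and
enrichment thresholds are treated as independent parameters.

## Annotation hierarchy

Categories are assigned by fixed priority — coding exon, lncRNA-catalog
exon, other exon, intron, 5 kb promoter flank, 5 kb downstream flank,
intergenic — with overlap meaning ≥ 1 shared bp, decided at the exon level
for exonic classes. Overlap detection is strand-agnostic by default
(sense/antisense relationships are recorded as auxiliary flags; a
configurable sense-requirement for the lncRNA class would be a one-line
change in the exon-hit filter) because the antisense-artifact filter has
already removed antisense exonic artifacts upstream. A peak lands in a
flank class only when it touches neither exons nor introns of any
transcript; when both flank types are in reach, promoter wins.

`distance_to_3prime` measures, in genomic coordinates, from the peak's
strand-aware 3' boundary to the nearest same-strand transcript 3' boundary
(upstream positive, half-open boundary-to-boundary, so an abutting peak
scores 0). This reference point reproduces the expected ~275 bp
fragment-offset geometry. The detection-saturation curve shuffles reads
once and takes prefixes per subsampling fraction, making the curve monotone
by construction.

## Expression

Counts tally read starts inside `[start, end)` on the peak strand; peaks
are disjoint per strand so a read counts at most once. Normalisation is
`y = sqrt(x / mean_j(x))`, where the sample mean runs over all peaks in the
matrix (the only defensible denominator once the matrix is the object in
scope); each normalised sample then satisfies `mean(y²) = 1` exactly. The
matrix carries a stage tag (raw → normalized → median_centered) and
re-normalisation is rejected. The variability filter uses the sample
standard deviation (n−1 denominator); the subset defaults to all samples
and the cohort pipeline passes the cancer samples. Clustering is average
linkage under centred-correlation distance (1 − Pearson), the classic
gene-expression workflow; constant rows are assigned correlation 0 to every
other row rather than NaN.

## Two-class SAM and one-vs-rest orchestration

The moderated statistic is `d_i = (mean₂ − mean₁) / (s_i + s0)` with `s_i`
the pooled standard error of the mean difference. The exchangeability
constant `s0` is the percentile of the `s` distribution minimising the
coefficient of variation of `d`'s median absolute deviation across 100
s-quantile windows (scanned at 5 % steps; all-equal `s` degenerates to
`s0 = 0`).

The permutation null relabels samples: all distinct label assignments when
their number is within the permutation budget (default 1,000), otherwise
distinct random draws from the budgeted seed. Expected order statistics are
per-rank means of the sorted permutation `d`. For a displacement threshold
Δ, the upper cutoff is the smallest positive sorted `d` exceeding its
expected value by Δ (mirrored below); all peaks beyond a cutoff are called.
The false-call count of each permutation is its number of statistics beyond
the cutoffs; the FDR estimate divides the **average** count across
permutations — the original convention of the method — by the number of
calls. The median (q50) and 90th-percentile (q90) summaries remain
available (`false_call_summary`), but the median variant combined with
automated threshold selection is markedly anti-conservative: under a pure
null the median count is zero whenever more than half the permutations show
no exceedance beyond the observed extreme, which licenses a spurious call
in roughly 40 % of null datasets. Δ is the smallest candidate displacement
whose estimate meets the target (default 0.05); if none qualifies the
called set is empty.

One-vs-rest runs one contrast per diagnostic class (class vs all others),
skipping classes with fewer than two samples, each contrast on a
deterministic child seed. Unbalanced contrasts use unbalanced label
permutations, not subsampling. The overall FDR for "called in ≥ 1 contrast"
is the sum over contrasts of expected false calls (per-contrast FDR ×
calls) divided by the size of the union of called sets, capped at 1 — a
stated estimator choice, since only the aggregation concept is given.

Null calibration: on exchangeable null matrices (Gaussian, and
overdispersed counts pushed through the normalisation), the automated
smallest-Δ selection makes a (false) call in roughly one null dataset in
ten at target 0.05 — about the theoretical expectation for this estimator
(≈ target per tail plus a small selection term) — and those calls are one
or two peaks out of hundreds, so the fraction of null peaks called stays
far below the nominal rate. The acceptance suite asserts both facts.

## Staining calls and marker association

Staining is called positive at ≥ 30 % of tumour cells and negative below
10 %; the undefined band [10, 30) maps to an explicit indeterminate state
excluded from contingency tables. Association tests apply the tie-corrected
Kruskal–Wallis rank-sum test to the binary calls (not the underlying
percentages): with two groups of binary observations, H equals
`((N−1)/N) ×` the Pearson chi-square of the 2×2 table, and this encoding
reproduces all three published marker p-values from the printed counts —
the strongest available evidence for the original encoding. The chi-square
approximation (df = k−1) is used throughout; at these group sizes an exact
permutation test is unnecessary. Tie correction is always applied (binary
data is maximally tied).

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical structure the pipeline consumes:
25 bp single-end tags; read starts drawn a truncated-normal distance
(mean 275 bp, SD 25 bp by default — the true spread of the fragment-offset
distribution is not identifiable from the cluster description, so it is a
parameter) upstream of locus 3' ends on the locus strand; uniform
background reads on random strands; a controllable multimapper fraction
with 1–3 decoy alignments and mismatch counts within the two-mismatch
allowance; per-sample multinomial allocation of the library across
expressed loci proportional to truth levels. One master seed drives a whole
cohort through deterministic child seeds, so identical designs give
byte-identical output files.

It does **not** simulate sequences, base qualities or an aligner; mismatch
counts are drawn, not derived. Toy annotations place features with ≥ 11 kb
spacing, so hidden novel loci are guaranteed > 5 kb from every transcript —
real genomes have no such guarantee, and flank/intron ambiguities are
exercised only by the dedicated annotation fixtures, not by cohort runs.
Expression truth is a fixed per-class mean without biological dispersion
between samples of a class, so differential-expression recovery on these
cohorts measures the machinery (normalisation, permutation null, threshold
selection), not robustness to biological variance. Passing tests therefore
demonstrate correctness of the implementations and calibration under the
stated models, not performance on real tumour data.

## Problem sizes

The cohort used by the acceptance measurements is 12 classes × 4 samples ×
3,000 reads on a 1.4 Mb two-chromosome genome with one injected
class-specific locus per class and three shared loci (expression weight 2:1
specific:shared), 300 permutations per contrast; null calibration uses 100
replicates of 200 peaks × 10 samples with exhaustive (252) permutations.
These sizes give stable sensitivity/calibration estimates while keeping a
full run in well under a minute.

## Known limitations

- The peak caller has no local background model; enrichment is always
  against the global uniform expectation, as in the original analysis.
- FDR estimates from few distinct permutations (small classes) are coarse;
  the result object carries a warning below 25 distinct permutations.
- `choose_s0` needs ≥ 10 peaks; below that the two-class fit falls back to
  the median `s`.
- The GTF reader takes exon/CDS features only; transcript assembly is out
  of scope.
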