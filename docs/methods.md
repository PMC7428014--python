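# Methods

This note documents the models and procedures implemented in `quantm`,
the defaults they use, and what the simulation-based tests do and do not
demonstrate.

## Reference construction

Mature tRNA sequences (gtRNAdb naming style) are upper-cased, U→T
normalised, and collapsed so that each reference entry carries a unique
sequence. Genes merged into one entry keep the name
`AA-anticodon-family-x` when they share amino acid, anticodon and family
index; a merge across family indices anchors the name at the smallest
(family, copy) pair, again with the `-x` suffix, and records every member
in the metadata TSV. Collapsing is per compartment: cytosolic and
mitochondrial sets never merge even on identical sequence. Identical
sequences with conflicting anticodon or amino-acid annotations are an
error, never silently resolved. The CCA tail is a read feature removed
during trimming and is never part of the reference.

Invariants (tested): collapsing is idempotent, partitions the input
genes, and `total_entries <= n_genes` with equality iff all sequences are
distinct.

## Trimming

Three steps, in order: a fixed 2-base cut (the engineered NN), removal of
the 5' adapter `TCCAACTGGATACTGGN` and everything 5' of it, removal of
the 3' adapter `CCAGTATCCAGTTGGAATT` and everything 3' of it. Because the
3' literal begins with CCA, the tRNA's CCA tail comes off in the same
match; a standalone terminal-CCA trimmer exists for externally trimmed
input but is off by default.

Adapter search is semi-global dynamic programming with unit-cost
substitutions and indels; `N` in an adapter matches anything free. The
accepted error count is `floor(error_rate x matched_adapter_length)` with
`error_rate = 0.2`; partial adapter occurrences at the relevant read end
are allowed down to a minimum overlap of 3 bases. Among equal-cost
matches the 5' step removes the most bases and the 3' step the fewest —
a deliberate, pinned convention; adapters occur at most once in this
architecture, so the choice is immaterial on real-layout reads but makes
the implementation deterministic. Reads trimmed below 10 nt are emitted
but flagged; they cannot pass the alignment score gate anyway.

## Alignment

The reference is at most a few hundred entries of <= 100 nt, so each read
is aligned to *every* entry by full Smith–Waterman (numba kernels), not by
seeded heuristics — exhaustive search dominates any heuristic in
sensitivity and makes the scores exactly reproducible. Scoring: +2 match,
−6 mismatch (no base qualities are used, so the maximum penalty applies
throughout), −1 for N, gap open+extend 5+3 with 3 per extension, on the
+ strand only (mature tRNA reads are sense). An alignment is reported
when its score reaches `f(L) = a + b ln L`; the package default is the
permissive gate `(a, b) = (1, 8)` so that 10-nt perfect reads map, while
`(20, 8)` reproduces the conventional 23-nt minimum. Because
`2L − (a + b ln L)` is not monotone at L = 1, the "minimum mappable
length" is defined as one past the longest failing length.

MAPQ comes from a documented monotone bin table on the normalized score
gap `(best − second) / (2L)`: a tie gives 0, no second hit above the gate
gives 42–44, and intermediate gaps map through fixed thresholds
(`>0.5→40, >0.25→33, >0.15→27, >0.10→23, >0.05→17, >0.02→12, else 5`).
The table is anchored at the Phred semantics (q = 10 ⇔ 90% correctness)
and at the two extremes; the integers in between are this package's own
convention and are *not* claimed to equal any external aligner's internal
bins. What is tested is the behaviour that matters downstream: ties never
pass the MAPQ > 10 filter, unique hits always do, and on simulated
error-free reads ≥ 99% map to their true source with MAPQ > 10.

Second-best scores are tracked across entries (not within one entry):
for tRNA references the relevant ambiguity is between near-identical
isodecoders, which is exactly what this captures.

## Quantification

Counting is strict `MAPQ > 10` (11 passes, 10 fails). RPM divides by all
primary mapped reads regardless of MAPQ — the filter applies to the
numerator only — so assigned-RPM columns sum to less than 1e6 by the
ambiguous fraction; `denominator="passing"` gives exactly-1e6 columns
when wanted. Anticodon pooling is an integer group-by sum per
(amino acid, anticodon) within compartment and conserves totals exactly.
Percent contributions divide each member's RPM by its class sum (NaN
when the class is empty in a sample, never 0/0 invented). Log-scale
correlations use a 0.5 pseudocount. Spike-in linearity is an ordinary
least-squares fit of log10(RPM) on log10(amount), with undetected
species excluded and reported.

## Variant signatures

Per read: mismatches land at their reference positions (from MD),
each insertion once at the reference position of the preceding aligned
base (an insertion before any aligned base has no anchor and is
dropped), each deleted reference base at its own position, and — when the
read's 5'-most aligned base is an internal position p > 0 — one stall at
p. The stall is attributed to the read-start base itself: when RT
misincorporates-then-falls-off at a modified base, the signature appears
at that base's own index. Reads with 5' soft clips longer than 3 nt are
excluded from stall counting (likely untrimmed adapter) but still
contribute coverage and mismatches. Coverage spans aligned and deleted
reference positions; insertions add none. A read whose CIGAR and MD
disagree is skipped and counted, never mis-tabulated.

Variant fraction = (mismatch + insertion + deletion + stall) / coverage;
positions with coverage < 20 are masked (the threshold is a stability
choice — below ~20 reads the fraction is too noisy to interpret).
Detectability filtering keeps positions at or above 1% in *every*
sample; masked values fail the gate.

Structure annotation is rule-based and end-anchored: discriminator =
last base, acceptor stem = first 7 and the 7 before the discriminator,
T-loop at a fixed offset from the 3' end (0-based `L−23..L−17`), T-stem
flanking it, anticodon loop = 7 positions centered on the annotated
anticodon found in the central third, D-arm/D-loop between acceptor and
anticodon stems, variable loop in the central gap. Unassigned positions
inherit their 5' neighbour's label so every position is assigned exactly
once; when the anticodon is not found the annotation degrades to the
end-anchored features and the entry is flagged. This is a binning rule
for feature histograms, not a secondary-structure prediction.

## Differential testing

**Expression.** Median-of-ratios size factors (features with any zero
excluded from the median). Per feature, a negative-binomial LRT: full
model one mean per group, reduced model a single mean, size factors as
multiplicative offsets, `2(l_full − l_reduced) ~ chi2(groups − 1)`.
Dispersion is per feature, estimated by Cox–Reid-adjusted profile
likelihood under the full model, and — when the table has at least 10
non-zero features — shrunk toward a parametric mean-dispersion trend
`alpha(mu) = a0 + a1/mu` via a log-normal prior of variance 0.25 (an
empirical-Bayes step; plain per-feature ML is visibly anticonservative at
2–3 replicates per group, and the shrinkage restores type-I error to the
nominal level, which the test suite verifies under planted nulls). A
method-of-moments estimate is the fallback when the profile optimisation
fails. Fold changes are reported with a +0.5 pseudocount on the
normalized means (never inside likelihoods); for more than two groups
the fold change is max/min of group means. This is deliberately *not* a
re-implementation of any specific DE package's shrinkage machinery;
the accepted contract is simulation calibration.

**Variant usage.** Variant counts are paired with coverages, so group
effects are tested with a beta-binomial LRT: group-specific mean
fractions versus a common one, a shared per-base overdispersion rho
estimated by Cox–Reid-adjusted profile likelihood and shrunk toward the
cross-base median (log-normal prior, variance 0.25, skipped below 10
testable bases). Filters applied on top, in order: mean fraction >= 1%
in every group; BH-adjusted p < 0.01; max/min group-fraction fold
change > 1.5 (fractions smoothed +0.5/+1 for the reported fold change
only). Bases with zero coverage across a whole group are flagged and
skipped.

**Ordination.** Classical (Torgerson) MDS: double-centering of the
squared Euclidean distance matrix and eigendecomposition. For
intrinsically 2-D configurations the embedding reproduces the input
distances to machine precision (tested). Expression matrices are
log10(RPM + 1) before MDS/correlation.

## Simulator

The generator emulates the library architecture and the RT
phenomenology, with ground truth returned for every draw:

* **Expression**: per-isodecoder log-normal with sigma = 0.7 on the
  log10 scale (spanning roughly 3–4 orders of magnitude across entries,
  as observed in real tRNA pools), or any user profile.
* **RT walk**: source entries drawn proportional to abundance; the walk
  runs 3'→5' (RT starts at the tRNA 3' end). At each internal position
  it may stall — truncating the body so the read starts there; position
  0 cannot stall, reaching it means full length — or, if not stalled,
  misincorporate (uniform over the other three bases). A stalled
  position terminates the walk unmodified, so one site can carry the
  mixed mutation + truncation signature of T-loop m¹A; the effective
  mismatch rate at such a site is `misinc x (1 − stall)`.
* **m¹A preset**: one T-loop site per entry (19 bases from the 3' end)
  with stall probability drawn from 0.3–0.6 and misincorporation 0.1;
  `ModProfile.demethylated()` zeroes it for treatment-contrast tests.
* **Read layout**: `NN + TCCAACTGGATACTGG + rN + body[start:] + CCA +
  GTATCCAGTTGGAATT`, NN and rN uniform; then uniform substitution
  sequencing error (default 0.1%, no indels). Identical seed and
  configuration give byte-identical FASTQ.
* **Fixture reference**: independent random families (72–90 nt, so
  mutual divergence is far beyond 10%) with the anticodon planted at
  positions 34–36, an A at the m¹A site, and an A discriminator; family
  members differ at 1–5 positions, always including one in the 3'
  quarter so that even T-loop-truncated reads retain a distinguishing
  base. Real (amino acid, anticodon) labels are used so pooling and
  naming behave as on a genomic reference.
* **Buffered designs**: within chosen anticodon classes, group B moves
  abundance from one member to a sibling (down `fold`, sibling absorbs
  the difference) leaving every class total identical between groups.
* `simulate_counts` draws multinomial source counts without read
  synthesis, for fast tests of the quantification/differential stages.

**What the simulator does not model**: ligation sequence bias, realistic
Illumina error profiles (position- or context-dependent errors, indels),
RNA secondary-structure effects on RT beyond the planted per-position
rates, partial/3'-truncated adapters from short cycles, and
mitochondrial tRNA peculiarities. Passing tests therefore demonstrate
the correctness of the computational pipeline under the stated
generative model — not robustness to every bias of real libraries.

## Problem sizes used in the checks

End-to-end abundance recovery runs at 100,000 reads over a 12-entry
reference (r² ≥ 0.99, log scale); planted stall/misincorporation
recovery at 30,000 reads (within 3 binomial SE at coverage ≥ 500);
type-I calibration pools 1,500 NB features and 600 beta-binomial bases
over fixed seeds (both within [0.02, 0.08] at nominal 0.05); the
junction-composition check uses 100,000 reads. These sizes give each
check comfortable statistical resolution while keeping the whole suite
fast enough to run routinely.

## Known limitations

* MAPQ integers match this package's documented table, not any external
  aligner's undocumented bins; analyses gated on `MAPQ > 10` are
  reproducible here by construction, but MAPQ values are not
  interchangeable with other aligners' beyond the tie/unique anchors.
* The NB and beta-binomial tests are asymptotic chi-square LRTs with
  empirically calibrated plug-in dispersions; at 2 replicates per group
  or very low counts the calibration guarantee weakens.
* Structure annotation is heuristic; Sprinzl numbering is deliberately
  not used — positions are raw 0-based body indices (1-based in
  user-facing TSVs).
* Only + strand alignment; reverse-complement hits are not searched.
* The multi-group fold-change definition (max/min of group means) is a
  convention; other conventions change which borderline bases pass the
  1.5-fold gate.
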