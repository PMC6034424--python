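# Methods

`clonescape` estimates B-cell clone sizes from bulk antibody heavy-chain
gene rearrangement sequencing of genomic DNA. gDNA gives each cell one
template per rearranged allele, so read counts, suitably filtered and
replicated, carry information about cell counts. The pipeline is:
read-level QC → annotation-level filters → subject-wide collapsing →
clonal inference → clone-size metrics, diversity, rarefaction and
overlap. A simulator with known ground truth closes the loop for
testing.

## Read-level quality control

Reads are scanned 5'→3' with a 10-bp sliding window (step 1). At the
first window whose mean Phred quality drops below 20 the read is
truncated at that window's *start*, keeping only the clean prefix. The
prose description of windowed trimming is ambiguous about whether the
cut falls at the window's start or end; we cut at the start because it
is the conservative choice (no base of a failing window survives) and
matches the spirit of trimqual-style tools. The window mean is compared
exactly (`sum < threshold × window`) so float ties cannot flip a
boundary case.

After trimming, every base with quality < 20 is replaced by `N`
(qualities untouched), and a read is discarded if it has more than 10
N's or fewer than 100 bases. All thresholds are strict in the direction
stated: quality 20 is kept unmasked, exactly 10 N's and exactly 100
bases pass. The pipeline is idempotent: a second application changes
nothing, which is asserted as a property test.

Paired-read assembly is out of scope; the module accepts already-merged
reads. Run-level QC (fraction of clusters passing filter ≥ 90%,
fraction of Q30 bases ≥ 70%, both inclusive) is a separate check on the
sequencing run itself.

## Annotation filters

Inputs are AIRR Rearrangement TSV rows with `v_call`/`j_call`
(comma-separated ties allowed), CDR3 nucleotide and amino-acid strings,
`v_identity`, and a replicate label. Four rules apply before collapsing:

- **V identity**: discard below 60% germline identity (strictly below).
- **IMGT-150 trim**: positions 1–150 carry the FR1 amplification
  primers, so they are removed from mutation-bearing consideration; the
  retained sequence starts at position 151. A rearrangement whose first
  aligned position is *after* 150 is discarded ("after" strict: a start
  at exactly 150 is kept). The alternative reading — keeping only
  positions ≤ 150 — would retain exactly the primer-biased region, so
  it was rejected.
- **Cross-family V ties**: a tie set spanning two or more V families
  (family = locus prefix + subgroup digit, e.g. `IGHV3-23*01` → `IGHV3`)
  marks a likely hybrid PCR product and is discarded. J ties are never
  discarded; several human J genes are near-identical.
- **Replicate imbalance**: within a subject, a replicate whose
  valid-read count is five or more times lower than its best sibling
  (`valid ≤ max(others)/5`, boundary inclusive) is flagged for
  re-amplification rather than silently analysed.

The filters are pure predicates and commute; a property test applies
them in every order.

## Subject-wide collapsing

Two sequences are equal if they have the same length and differ only at
positions where either carries an `N`. This relation is not transitive
(`ANG`~`AAG`, `ANG`~`ACG`, but `AAG`≁`ACG`), so the partition is defined
procedurally: records are visited in descending copy order (ties broken
by sequence, then id) and each joins the first *seed* it matches, else
founds a new group. This makes the grouping copy-weighted,
deterministic, and independent of input order — determinism, not
transitivity, is the tested property. Each group's representative is
the member with the fewest N's (ties: more copies, then lexicographic),
so CDR3 translation stays maximally informative. Copy numbers are
summed per replicate; total copies are conserved exactly.

Because collapsing spans all replicates of a subject, a sequence seen
once in each of two libraries reaches subject-wide copy 2 and survives
the low-copy filter — the cross-replicate rescue. `rescue_low_copy`
reports how many sequences this saved.

## Clonal inference

Sequences are excluded from clone assignment when subject-wide copies
< 2, the CDR3 contains a stop codon, or any 30-nt window of the aligned
V region falls below 60% germline identity (an uncorrected indel
signature). N and gap positions are excluded from both numerator and
denominator of the window identity, and the threshold comparison is
done in exact rational arithmetic so a window at exactly 60% passes.
When no germline alignment is available the window check is skipped
with a logged warning rather than silently passing or failing reads.

Clone membership requires shared V gene (tie sets must intersect; the
clone keeps the running intersection), shared J gene, equal CDR3
nucleotide length, and ≥ 85% CDR3 amino-acid similarity (1 − normalised
Hamming distance; `X` matches anything) between *every* pair of
members. The clustering algorithm itself is not dictated by that
invariant, so we use greedy complete linkage seeded in descending copy
order with lexicographic tie-breaks: a sequence joins the first clone
where it matches all current members, else founds one. This honours the
pairwise invariant (asserted post hoc on every emitted clone), is
deterministic under input permutation (property-tested), and mirrors
how copy-weighted database pipelines behave. A seed-only ("single
representative") variant would admit clones violating the pairwise
requirement and was rejected.

## Clone-size metrics and sampling estimators

Three sizes per clone: **copies** (Σ read copies), **instances**
(Σ per-member replicate occurrences), **uniques** (member count).
Derived quantities: D20 = share of total copies in the 20 highest-copy
clones (fewer than 20 clones → 1.0; the routine generalises to any of
the three metrics); top-N rankings with deterministic tie-breaks
(metric, then copies, instances, uniques, id); clone counts at size
cut-offs; fraction of copies retained under copy cut-offs.

The DNA-input estimators use 1,000 pg/ng, 1.4 rearrangements/cell, and
6.7 pg/cell. `max_rearrangements` floors the result (counts are
integers): 100 ng → 20,895. `cells_per_ng` rounds 1000/6.7 = 149.25 to
the nearest ten → 150. `input_dna_for_b_cells` truncates to one decimal
(50/0.35 → 142.8); the exact quotient is trivially recoverable. No
rounding rule is canonical for these back-of-envelope numbers; the
choices above are fixed and documented rather than configurable.

## Diversity

Given proportional abundances p_i under one size metric (after an
optional instance cut-off and renormalisation), the Hill diversity is
ᵠD = (Σ p_i^q)^(1/(1−q)), with ⁰D = R exactly and the q→1 limit
exp(−Σ p_i ln p_i) used within 1e-9 of q = 1. Shannon H, Simpson
λ = Σ p_i² = 1/²D, Pielou J = H/ln R, and clonality C = 1 − J follow.
Two conventions needed fixing: J is computed with the standard positive
H (a sign-dropped variant would leave [0,1]); and "clonality as the
inverse of entropy" is implemented as the normalised complement 1 − H/ln R,
because literal 1/H is unbounded and not comparable across samples.
J and C are undefined at R = 1 (ln 1 = 0) and return `None` there.
Zero-abundance clones are excluded before the vector is built, so
0·ln 0 never arises. The implementation is cross-checked in tests
against scikit-bio's independent alpha-diversity routines.

## Rarefaction, overlap, clone tracking

Expected richness in a subsample is the exact hypergeometric form
E[S] = Σ_i [1 − C(N−N_i, n)/C(N, n)], evaluated with log-gamma to avoid
overflow; no resampling is used in the estimators themselves.
Individual-based rarefaction subsamples sequence copies; sample-based
rarefaction subsamples replicate libraries using the Boolean presence
matrix (T_i = replicates containing clone i). Monte-Carlo resampling
and exhaustive enumeration appear only as test oracles (agreement
within 3σ at 1e5 draws; exact on instances small enough to enumerate).

For stratified curves the clone-size cut-off is applied to replicate
presence (T_i ≥ k), which is the quantity the sample-based estimator is
defined on; the per-unique-sequence instance count is reported
separately everywhere else. The visual "curve levels off" judgement is
replaced by a reproducible surrogate: a stratum has plateaued when the
relative gain of the final step, (S(T) − S(T−1))/S(T), is below a
configurable epsilon (default 1%). Note that for sample-based curves
the final-step gain is driven entirely by clones present in a single
replicate, so strata with min presence ≥ 2 plateau under this rule by
construction; the rule is kept because it is the stated surrogate and
because the full-matrix (C1) stratum is the informative one for
sampling sufficiency.

Clonal overlap between two samples is the cosine similarity of their
clone abundance vectors aligned on the union of clone ids (absent → 0),
under any of the three size metrics; it is symmetric, scale-invariant
and in [0,1] for non-negative abundances. Multi-sample tracking exports
the Boolean presence matrix and Venn-style exactly-k / at-least-k
counts instead of rendering string plots.

## Simulator

The generator emulates the study design it is meant to exercise: one
subject, `n_replicates = 2` libraries, `n_clones = 200`, cells per
clone drawn from a heavy-tailed lognormal (μ = 2, σ = 1, rounded,
floor 1; a power-law option exists), about Poisson(2) SHM variants per
clone on top of the founder with founder-weighted Dirichlet cell
splits, 1,000 cells sampled multinomially per replicate, a lognormal
PCR factor (σ = 0.5) on copy numbers, per-base sequencing error 1e-3,
and an Illumina-like quality model (mean Q35 with a 2% low-quality
tail). Germline V/J segments come from a small bundled FASTA of
*synthetic*, stop-free, in-frame stand-ins — random sequences with
IGHV1–6/IGHJ1–6-style labels, not real alleles; clone inference only
consumes gene labels and CDR3s. Identical configs reproduce
byte-identical output.

SHM is placed uniformly over the V segment of each variant; the
junction is inherited intact from the clone's founding rearrangement,
while sequencing error hits every position including the CDR3. This is
a deliberate idealisation: at a 5% per-base variant divergence applied
to the junction as well, most within-clone variant pairs would fall
below the 85% CDR3 similarity rule (a direct calculation puts it at
~85% of pairs failing), i.e. the inference target itself would be
ill-posed on the simulated data. Holding the junction fixed makes
ground-truth clonal identity recoverable in principle, which is what a
recovery benchmark requires; real repertoires do accumulate junction
mutations, so measured F1 on this simulator is an upper bound on real
data.

Other things the simulator deliberately does not model: indels and
chimeric reads, SHM hotspot motifs, per-V-gene primer amplification
bias, isotypes, light chains, and UMI structure. Passing tests
therefore demonstrate correctness of the computations and robustness to
substitution noise and copy-number distortion — not performance on
artefact classes the generator never produces.

`evaluate_recovery` scores inferred clones against the truth by
pairwise precision/recall/F1 over clustered unique sequences, each
labelled by majority vote over its collapsed members; with no pairs on
either side the scores degenerate to 1.

## Problem sizes and numerical choices

Tests run the simulator at 60–500 clones with a few hundred to a
thousand cells per replicate, and recovery benchmarks at 200 clones ×
2 replicates over five seeds — sizes chosen so the full suite completes
in well under a minute while still exercising heavy-tailed size
distributions and multi-variant clones. Threshold comparisons that sit
exactly on documented filter boundaries (window mean, window identity) use exact
integer/rational arithmetic; everything else uses double precision.
Binomial coefficients are computed in log space. All randomness flows
from explicit seeds (`numpy.random.default_rng`); hypothesis-based
property tests are derandomised.

## Known limitations

Germline V/J assignment is taken as input (AIRR `v_call`/`j_call`), not
computed; novel-allele inference, lineage trees, and likelihood-based
clonal clustering are out of scope. The greedy complete-linkage
partition, like any order-defined rule, can split borderline lineages
that a global optimiser would merge. Copy numbers remain PCR-biased
measurements; the instances metric exists precisely because copies
cannot be taken at face value.
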