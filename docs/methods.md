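# Methods

## Scope and model

`snofam` analyses the copy-level regulation of snoRNA gene families. The
unit of analysis is an Rfam-style family: a set of genes (box C/D or box
H/ACA, never mixed) presumed to descend from one ancestral snoRNA. Inputs
are (a) a family-annotated snoRNA table with sequences, coordinates and
host-gene assignments, (b) a snoRNA × sample TPM matrix over a tissue panel
with replicates, and optionally (c) a host-gene GTF, (d) a per-base
conservation track (bedGraph, phastCons-style scores in [0, 1]) and (e) a
set of common SNP positions (BED). From these it derives per-snoRNA and
per-family summary tables and a per-class aggregate report.

All coordinates are 0-based half-open internally; GTF input/output is the
only place 1-based closed coordinates appear. Sequences are normalized at
ingest (uppercase, U→T), so RNA- and DNA-spelled copies of the same gene
compare as identical.

## Expression status

A snoRNA is *expressed* when its TPM reaches a threshold (default 1) in at
least one individual sample. The comparison is inclusive (`>= 1`) by
default; the literature this models phrases the rule both as "greater than
1 TPM" and "at least 1 TPM", and the two differ only for values exactly at
the boundary, so the convention is a single switch (`inclusive=False`).
The status is driven by individual samples, not tissue means; tissue means
(arithmetic mean of a tissue's replicates) drive everything downstream of
status: top-tissue calls, CVs, ranking, switches.

Ties in the top-tissue call resolve to the canonical tissue order of the
sample panel (order of first appearance in the sample map); an all-zero row
yields the sentinel `none`.

## Pairwise identity

Identity between two family members is defined through a global alignment
with unit reward per matched residue and no mismatch or gap penalty. The
optimal score of that alignment equals the length of the longest common
subsequence (LCS), so the implementation computes only the LCS length — the
score is unique even when optimal alignments are not — via a vectorized
row-sweep dynamic programme (`dp[i][j] = max(dp[i-1][j], dp[i-1][j-1]+eq,
dp[i][j-1])`, evaluated per row as a running maximum, exact because DP rows
are non-decreasing). Percent identity is `100 · LCS(a,b) / min(|a|,|b|)`,
which is 100 for a sequence nested inside a longer one; for that reason the
*identical pair* flag (families where read assignment between copies is
ambiguous) additionally requires string equality. Identity is computed
within families only; a per-member mean identity to all other members is
exported.

## Conservation and SNP density

The conservation score of a snoRNA is the mean per-nucleotide track score
over its interval. Nucleotides not covered by any track interval count as
zero by default (the average is over all nucleotides, i.e. divided by the
snoRNA length); `uncovered_zero=False` drops them from the denominator
instead. SNP density is `1000 · (number of SNP sites in [start, end)) /
length`.

## Host-transcript assignment and downstream-exon distance

For an intronic snoRNA the host gene's transcripts are sorted by exon count
(descending) then transcript name (ascending), and the first transcript in
which the snoRNA is fully intronic — inside the transcript span and
overlapping no exon — is assigned. "Fully intronic" is the only reading
under which a distance to the first downstream exon is well defined. The
distance is the strand-aware gap from the snoRNA 3′ end to the 5′-most
edge of the nearest downstream exon in transcript orientation, a
non-negative integer under end-exclusive arithmetic. If no transcript
qualifies, the snoRNA is reported as non-intronic and the distance column
carries the missing marker.

Family genomic context is classified over member host biotypes
(`coding` / `noncoding` / `intergenic`): `<X>_only` when all considered
members share context X, otherwise `mixed` — combinations of intergenic
with intronic members are mixed, so the four categories are exhaustive.
The classification is computed both over all members and over expressed
members only. `same_host` is defined for families with ≥ 2 expressed
members and is true iff all expressed members reside in one host gene.

## Variability statistics

CV is `100 · sd / mean` over per-tissue means, with the sample standard
deviation (ddof = 1) by default: the tissue panel is small, and the
convention is configurable (`ddof=0`) since either may be needed to match
externally computed tables. Family covariation is the CV of the per-tissue
sums over expressed members; mean member covariation is the mean of the
expressed members' individual CVs. Each family's signed perpendicular
distance from the x = y diagonal, `(family_cv − mean_member_cv)/√2`, is
negative when member variability exceeds family variability; the √2 scaling
is monotone and does not affect the rank test. Classes are compared with a
two-sided Mann–Whitney U test on these distances. Per-tissue variability
(within-tissue, across replicates) needs no separate code path: restrict
the sample panel to one tissue's replicates and rerun.

The size–abundance correlation relates a family's number of expressed
members to its average total abundance (mean over samples of the summed
member TPM; the sum includes unexpressed members by default — their TPM is
near zero either way — with a flag to restrict). Pearson by default,
Spearman as an option; the method is exposed because survey-style r values
are often reported without naming one.

## Switches

Expressed members are ranked by total abundance (sum of tissue means, ties
by ascending id). Per tissue, the expressed member with the highest tissue
mean is the top call; tissues where all expressed members average zero get
no call, and exact ties resolve to the member with the better overall rank
so floating-point ties cannot manufacture switches. A family *switches*
when ≥ 2 distinct members appear among its defined top calls; families
with fewer than two expressed members are never switch-eligible. No
significance is attached to switches — they are descriptive calls.

## Synthetic cohort generator

The generator emits a complete input bundle (annotation, FASTA, GTF,
bedGraph, BED, abundance matrix, sample map) plus truth tables, with these
study conditions as defaults:

- **Panel**: 7 tissues (brain, liver, prostate, breast, ovary, testis,
  skeletal muscle) × 3 replicates.
- **Families**: 200 C/D + 100 H/ACA. Sizes follow a
  singleton / small / large mixture: singletons with probability 0.405
  (C/D) / 0.286 (H/ACA); large families (20–50 members) with probability
  0.12 / 0.10 among the rest; remaining sizes 2 + geometric(p = 0.35).
  This reproduces the composition of the human Rfam snoRNA complement —
  many singletons, most members concentrated in a minority of large
  families (> 90% of copies in multi-member families).
- **Expression**: singletons expressed with probability 0.96; multi-member
  copies with probability 0.341 (C/D) / 0.372 (H/ACA), giving ~37–41%
  expressed per class overall. Expressed copies draw a base TPM of
  `max(10^N(1.2, 0.9), 2)` — spanning more than three orders of magnitude —
  modulated by a family-shared tissue factor (log-normal, normalized so the
  best tissue keeps every expressed copy above threshold) and a small
  per-member tissue jitter (clipped to [0.8, 1.25]). Unexpressed copies
  draw each sample uniformly from [0, 0.45·threshold], strictly below the
  boundary so status recovery is convention-independent.
- **Replicate noise** is multiplicative log-normal with CV 20%, mean 1,
  truncated to factors in [0.7, 1.45]. Truncation turns the planted
  fold-change margins into hard guarantees rather than high-probability
  ones; the truncation points sit ≈ 1.8 noise SDs from the centre, so the
  distortion of the noise distribution is modest.
- **Switches**: 18 C/D + 9 H/ACA families among those with ≥ 2 expressed
  members. Each switch family partitions the panel into 2–3 tissue blocks
  dominated by distinct members at ≥ 4 × the jitter ceiling of every other
  expressed member. In non-switch families the overall top member is
  raised, if necessary, to ≥ 4 × the runner-up in every tissue. With the
  truncated noise, the worst-case post-noise dominance ratio is
  4 · (0.8/1.25) · (0.7/1.45) ≈ 1.24 > 1, so the planted switch set is
  recovered exactly, with no spurious switches.
- **Sequences**: each family mutates a random ancestor (C/D 70–130 nt,
  H/ACA 110–145 nt) at 10% per site per copy, giving within-family
  identities centred in the low-to-mid 80s. 8 C/D + 5 H/ACA families get a
  planted identical pair; all other families are checked (and if needed
  re-mutated) to contain none.
- **Hosts**: per-family context category drawn with class-specific
  probabilities (C/D mostly coding-only; H/ACA mostly mixed, more
  intergenic-only); same-host planting with probability 0.60 (C/D) / 0.073
  (H/ACA) places all expressed copies in introns of one shared gene,
  otherwise every intronic copy gets its own gene. Host genes carry 1–4
  transcripts: a primary with one intron per snoRNA, plus optional decoys —
  one with *more* exons but an exon sitting on a snoRNA (exercising the
  skip-on-overlap rule), one with equal exon count and a later name
  (exercising the name tie-break), one with fewer exons (never chosen).
  Downstream-exon distances are drawn with a mode near 70 nt for C/D
  (log-normal around 70) and broader for H/ACA.
- **Conservation/SNPs**: expressed copies score ~N(0.80, 0.08) (clipped to
  [0.5, 1]), unexpressed ~N(0.30, 0.10) (clipped to [0, 0.6]); every fifth
  snoRNA's track interval is split in two to exercise split-invariance.
  SNP rates are 0.002/nt for expressed (conserved) and 0.02/nt for
  unexpressed copies.

What the generator does **not** emulate: read-level effects (multimapping
between near-identical copies, coverage bias), correlated expression
between families sharing a host, genome-scale intergenic spacing,
indel-style sequence divergence, and any class difference in the
family-vs-member variability balance (the diagonal-distance Mann–Whitney p
on synthetic data is therefore approximately uniform, unlike on real
surveys). Exact recovery on synthetic data therefore validates the
*computational* chain — parsing, interval arithmetic, strand handling,
thresholding, ranking — not robustness to quantification noise in real
TGIRT-seq data.

## Numerical and degenerate-input conventions

- CV with non-positive mean → NaN; singleton identity → error; empty
  distance lists → error; families with zero expressed members are skipped
  by the variability stage and carry `.`/NaN in summaries.
- Missing optional inputs (GTF, conservation, SNPs) drop the dependent
  columns entirely rather than writing zeros.
- Aggregate percentages name numerator and denominator explicitly; the
  survey statistics this models alternate between "all snoRNAs", "families
  with ≥ 2 members" and "families with ≥ 2 expressed members" as
  denominators, which is the main ambiguity hazard when comparing numbers.
- All randomness flows from one `numpy.random.Generator` seeded from the
  config; a seed determines the bundle byte-for-byte, and the pipeline is
  deterministic given its inputs.

## Problem sizes

Default test and acceptance runs use the 300-family cohort (~1,400–1,700
snoRNAs, 21 samples), which the full pipeline processes in a few seconds;
unit tests use 40-family cohorts. These sizes match the scale of the human
snoRNA complement (≈ 217 families, ≈ 1,400 Rfam-annotated copies), so no
down-scaling is involved.
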