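# Methods

## Coordinate model

All coordinates are 0-based, half-open internally; GFF3's 1-based closed
intervals are converted on parse, BED is consumed natively. A transcript is
its exons concatenated 5'→3' on the transcript strand, so position 0 of a
minus-strand transcript is the rightmost genomic base of its 3'-most
(genomically) exon. The stop codon is located from explicit `stop_codon`
features when present; otherwise the last three nucleotides of the
concatenated CDS are taken as the stop codon. Both dialects are common
(TAIR/Araport-style GFFs differ in whether CDS includes the stop), and both
round-trip through the parser. A GFF whose CDS *excludes* the stop codon and
that also lacks `stop_codon` features would be mislocated by 3 nt; the
parser cannot detect that case without sequence, and it is listed as a known
limitation. Transcripts whose coding span is not a multiple of 3 are flagged
and excluded from TSI aggregation with a warning rather than dropped at
parse time.

A read's biological 5' end is the leftmost aligned genomic base for `+`
strand alignments and the rightmost for `-` strand alignments. The end is
assigned to every transcript whose strand matches and whose exons contain
the base (no fractional weights across overlapping isoforms: the TSI is a
within-transcript ratio, insensitive to duplicated assignment; users who
need uniqueness can pre-filter to one isoform per gene). Reads matching no
transcript are tallied, and `assigned + discarded = total` holds per
library.

## Metagene and periodicity

The metagene anchors r = 0 at the FIRST nucleotide of the stop codon, so
"16–17 nt upstream" is r ∈ {−17, −16}; one convention is used everywhere.
Default window ±100 nt. Transcripts whose window exceeds their bounds
contribute only in-bounds positions. With normalization off the matrix total
equals the in-window count total (conservation is tested); per-transcript
normalization divides each window by its own sum before averaging, removing
the bias toward abundant transcripts, and is off by default so both views
are available.

Periodicity pools CDS counts (stop codon excluded) by position relative to
the CDS start across transcripts with CDS ≥ 30 nt. Frame fractions are
counts by position mod 3; the dominant period is the lag in [2, 10]
maximizing the unnormalized mean-subtracted autocorrelation of the pooled
profile. The unnormalized sum slightly favours short lags, which is
conservative for detecting the 3-nt signal against its harmonics at 6 and 9.

## Terminational Stalling Index

TSI = (sum of counts at r ∈ {−17, −16}) / (per-position mean over the 100
flank positions r ∈ [−67, −18] ∪ [−15, +34]). Two reading choices are fixed
deliberately:

* **boundary sum over flank mean** — the literal reading of "the number of
  read ends at the boundary" against "the mean number in the flank". A
  uniform profile therefore has TSI = 2, not 1; the target threshold of 3
  sits above that background. `boundary_stat="mean"` switches to a
  mean/mean ratio for users who prefer a background of 1.
* **flank geometry** — 50 positions on each side of the boundary block,
  excluding the boundary itself. The gap positions −15…−18 adjacent to the
  boundary are part of the flank except the boundary block itself. One-sided
  or truncated layouts are configuration options, not defaults.

A record is undefined (NaN, never an exception) when the flank mean is 0,
when the transcript has fewer than `min_total_reads = 10` reads, or when the
transcript cannot hold the full window (3'UTR shorter than 32 nt past the
stop); `truncate_flank` relaxes the last rule by averaging over available
positions, at the cost of cross-genotype comparability. No pseudocounts are
used; undefined values are excluded, not imputed. Genotype means are taken
over replicates with a defined TSI and require at least 2 defined
replicates.

## Target calling and statistics

Reference CTRD targets: mean reference TSI strictly greater than 3.
Pathway (mutant) targets: among reference targets, reference/mutant mean
TSI ≥ 2 (mutant mean 0 counts as an infinite fold and a target; an
undefined mutant mean leaves the call undefined and negative). Calls use
genotype *mean* TSI; per-replicate calling is available as an option since
the averaging level is a genuine free choice. Because the TSI is a ratio,
all calls are invariant under library depth rescaling.

The genotype-shift test defaults to the **paired** Wilcoxon signed-rank over
the common transcript set (the same transcripts are measured in both
genotypes); unpaired rank-sum is a flag. Zero differences and pairs with
undefined TSI are dropped; the exact null is used for n ≤ 25, the normal
approximation above. Overlap significance is the upper-tail hypergeometric
probability P(X ≥ k). When an external gene list (e.g. a NAD⁺-cap survey) is
intersected, the universe defaults to the intersected set itself and is
overridable — the appropriate universe is context-dependent and no default
suits every comparison. No multiple-testing correction is applied to single
planned comparisons; Benjamini–Hochberg is available for batches of
overlaps. Replicate concordance QC projects samples onto the top-2
principal axes of the column-centred log1p matrix (plain SVD).

## Decay kinetics

First-order decay is fitted per replicate by ordinary least squares of
ln(abundance) on time — with 4 time points ({0, 30, 60, 120} min) and 3
replicates this is the stable, convention-standard estimator; nonlinear
fitting would add variance without information at this design size. Each
replicate is normalized to its own t = 0 abundance (idempotent), optionally
divided first by a stable reference transcript's trajectory. Non-positive
points are dropped with a warning; fewer than 3 usable points voids the
replicate; λ ≤ 10⁻¹² (the tolerance absorbs float noise of a flat fit) is
flagged non-decaying and excluded from the half-life mean ± SD. Conditions
are compared by Welch's two-sided t-test on per-replicate half-lives —
half-lives are fitted per replicate and then averaged, not pooled across
replicates, so replicate-to-replicate variation propagates into the SD and
the test.

## Synthetic degradome

The generator emulates the *structure* the analysis assumes, with ground
truth. Per transcript, 5'P end positions follow the mixture

```
p = (1 − φ)·U(transcript) + φ·[ (1 − β)·lattice + β·boundary ]
β = 2s / (2s + n_codons)
```

where φ (`ctrd_fraction`, default 0.4) is the fraction of ends produced by
ribosome-tracked decay, the lattice spreads CTRD mass over the CDS with
`frame_bias` = 0.8 concentrated on codon 5' boundaries (frame 0), and the
boundary puts weight s (`stall_weight`, default 8) on each of the two
terminal-stalling positions {−17, −16} (50/50 split, a parameter) relative
to unit weight per codon position. β is monotone in s, so the expected TSI
is too (tested over an s grid); it also varies with CDS length, giving a
realistic TSI spread. With these defaults the expected reference TSI is
≈ 25 and an *xrn4*-like mutant (φ×0.5, s×0.25) ≈ 4.5 — the strong
reference-vs-mutant contrast of a nuclease knockout, a 5–6× drop.

Library totals are negative-binomial (mean = per-transcript expression,
log-normal across transcripts with mean 300 reads and spread σ = 0.5, so
~90% of transcripts exceed 100 reads; NB size = 10 gives ≈ 33% replicate
CV), positions multinomial. Defaults: 500 transcripts, 2 genotypes × 3
replicates, ~50% two-exon transcripts, both strands, five chromosomes.
Everything derives from one seed via spawned RNG streams keyed by
(genotype, replicate), so a library is exactly reproducible and replicates
differ. Expected TSI in the ground truth is the ratio of expectations
implied by the mixture (not E[ratio]; at the default depth the Jensen gap
is ≈ 2%, visible in the uniform-background check which measures ≈ 2.05
against the analytic 2.0).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: positional overdispersion beyond multinomial
sampling, sequence-dependent nuclease or ligation bias, overlapping
isoforms, batch effects (batches are emulated only as separate sample
sheets), alignment errors, and codon-specific dwell times. Decay time
courses are exact exponentials with multiplicative log-normal noise
(default sd 0.1), uniform across time points.

## Problem sizes

Simulation-based checks run at 500 transcripts × ~300 reads (the scale at
which boundary counts per transcript reach the tens, where the assay's
discrimination becomes interesting), 500 repetitions for half-life recovery,
and full enumeration for the exact-test oracles (N ≤ 12 universes, 2ⁿ sign
assignments for n ≤ 10). These sizes keep the whole suite in seconds while
leaving the stochastic margins wide (e.g. recovery sensitivity ≈ 96% against
a 90% requirement).
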