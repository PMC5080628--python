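# Methods

## Model and procedure

khscan estimates, for a pair of aligned in-frame coding sequences, how fast
each *class* of amino-acid replacement evolves relative to synonymous
change. The unit of classification is the elementary amino-acid change: an
unordered amino-acid pair {A1, A2} such that some sense codon of A1 differs
from some sense codon of A2 at exactly one nucleotide. Under the standard
genetic code there are exactly 75 such classes (verified exhaustively
against an independent enumeration of all 61 × 9 codon neighbors). Classes
are ranked 1..75 from most to least exchangeable; the pipeline's outputs
are

- K_s — synonymous substitutions per synonymous site,
- K_i — per-class rate, K_i* — cumulative rate of ranks 1..i,
- K_a = K_75* and K_h = K_10*,
- K_a/K_s and K_h/K_s with two-sided Fisher exact p-values,
- per-gene filter and candidate-PSG flags, and cohort-level supergene
  regressions of K_h/K_s on K_a/K_s.

### Counting

Aligned codon columns are compared one at a time. Columns containing a gap
or ambiguity character in either sequence, or a stop codon, are wholly
excluded from both substitutions and sites, which keeps numerators and
denominators consistent. Remaining columns classify as: identical;
synonymous (one difference, same amino acid); elementary (one difference,
different amino acids — incremented in the class of the pair);
multihit-synonymous (2–3 differences, same amino acid); or non-elementary
(2–3 differences, different amino acids). Non-elementary columns count as
one amino-acid change excluded from every class — this is deliberate: the
method defines K_i over *elementary* changes only, and the elementary /
non-elementary split is itself a reported quantity. The synonymous content
of every multi-difference column is credited to N_s as the mean number of
synonymous steps over the minimal mutational pathways (orderings of the
differing positions) that avoid stop codons; this keeps N_s unbiased at
low divergence. If every pathway passes through a stop (not possible for
two-difference synonymous pairs under the standard code), the column
contributes nothing.

Sites are mutation opportunities: each codon position contributes one site
unit split κ/(κ+2) to its transition neighbor and 1/(κ+2) to each
transversion neighbor, routed to L_s (synonymous neighbor), L_i of the
neighbor's class, or a stop-opportunity weight that is excluded without
renormalisation. Per codon, L_s + Σ L_i + stop weight = 3 exactly. L
values for a gene are the mean over its two sequences, computed over used
columns only.

All N/L bookkeeping uses exact rational arithmetic (`fractions.Fraction`;
κ is taken exactly as its float ratio p/q, making every weight an integer
over the common denominator p + 2q). Results are therefore independent of
summation order and exactly reproducible across implementations; floats
appear only at the rates layer.

### kappa

κ (transition/transversion rate ratio) is estimated from third positions
of fourfold-degenerate codon boxes where the first two nucleotides match
across the pair, using the Kimura two-parameter closed form
κ = [-½ ln(1-2P-Q) + ¼ ln(1-2Q)] / [-¼ ln(1-2Q)]. Policies: `per-gene`
(default; needs ≥ 50 comparable fourfold sites, falling back to the pooled
cohort estimate, then to 2.0), `global` (pooled over all genes), or
`fixed:X`. With no observed differences the estimator is uninformative and
returns the default 2.0; with transitions but no transversions κ is
undefined and capped at 50. Note that at K_s ≈ 0.02 a 500-codon gene has
~125 comparable fourfold sites but only ~2.5 differences, so per-gene
estimates are extremely noisy; cohort-level calibration work should use
the `global` policy, and the per-gene default mainly matters for long or
more diverged genes.

### Rates, test, screen

Rates use the Jukes–Cantor correction JC(p) = -(3/4) ln(1 - 4p/3), applied
to pooled proportions for cumulative classes (never averaging per-class
distances), which makes K_75* identically the standard pooled K_a.
Proportions ≥ 0.75 (possible for rare classes with tiny fractional site
pools) mark the rate undefined rather than raising. Significance comes
from Fisher's exact test on [[N, round(L)-N], [N_s, round(L_s)-N_s]] with
sites (and fractional N_s) rounded half-away-from-zero for the table only;
two-sided by default (`greater` available — Table-style PSG calling
combines p < 0.05 with the one-directional K_h/K_s > 1, so sidedness
mostly cancels). Genes are filtered when K_a > 0.05, K_s > 0.08,
K_s < 0.005 (reported in that order), or K_s is undefined; unfiltered
genes with K_h/K_s > 1 and p < 0.05 are candidate PSGs. For the twofold
analysis, genes with K_a > 0 are sorted by K_a descending (ties broken by
gene id), pooled in bins of 100 (configurable) by summing exact counts,
trailing remainder dropped, rates recomputed per supergene, and K_h/K_s
regressed on K_a/K_s through the origin (an intercept is optional; the
through-origin slope is the proportionality constant the twofold pattern
asserts).

## The exchangeability ranking

The true evolutionary index ranking of the 75 classes is not derivable
from first principles, and this package does not attempt to estimate one.
The packaged default (`data/ei_ranking_synthetic.tsv`) is a synthetic
stand-in that orders the classes by Grantham (1974) physicochemical
distance — most similar pair = rank 1 — generated by
`khscan.grantham.grantham_ranking()` and labelled as synthetic in the file
header. Its top ranks (I/L, I/M, L/M, F/I, M/V, F/Y, F/L, D/N, H/Q, K/R)
are physicochemically conservative exchanges, and its top-10 classes carry
~15% of nonsynonymous mutation opportunity, which under a realistic
purifying-selection gradient reproduces the observation that the most
exchangeable 10–12 classes carry roughly a quarter to a third of observed
amino-acid changes. Every entry point accepts a user ranking TSV, and the
test suite additionally runs on random rank permutations, so no package
result is tied to this particular order.

## Synthetic-data generator

`simulate` evolves each gene independently down two lineages from an
ancestor drawn from a codon distribution (default uniform over the 61
sense codons). Per codon, mutation proposals arrive as a Poisson process
with per-position transition : transversion intensities κ : 1, scaled so a
neutral site accrues `branch_length` expected substitutions per lineage
(`branch_length = 0.01` therefore emulates pairwise K_s ≈ 0.02, the
divergence regime of a very recently separated species pair). Synonymous
proposals are always accepted; a nonsynonymous proposal is accepted with
the acceptance probability ω of its class rank (single-nucleotide changes
always have a definite class); stop-creating proposals are rejected.
ω > 1 (positive selection) is simulated exactly by thinning from a
dominating intensity M = max(1, max ω): proposals run M times faster and
all acceptance probabilities divide by M. Every accepted event is logged,
so the per-gene truth table (N_s and per-class N_i, plus the number of
codons hit more than once) supports exact verification of the counting
engine on genes without multi-hit codons. Randomness comes from one
`numpy` SeedSequence per (seed, gene index), making cohorts reproducible
and order-independent.

What the generator does *not* emulate: indels and alignment error,
among-site and among-gene rate variation beyond the ω bands, codon-usage
and GC composition structure, more than two taxa, and assembly or
ortholog-calling noise. Passing tests therefore demonstrate correctness of
the counting/rate/test machinery and the qualitative selection signatures,
not robustness to real transcriptome artefacts.

## Calibration measurements (computed by the suite and acceptance script)

- Neutral cohorts (all ω = 1, κ = 2, 200 genes × 500 codons, K_s ≈ 0.02,
  global κ): replicate-mean K_i*/K_s lies within ±0.05 of 1 for every i
  (measured range ≈ 0.96–0.98). The small downward offset is structural:
  at this divergence ~5% of amino-acid changes land in codons hit more
  than once and are excluded as non-elementary, while N_s recovers its
  multi-hit content through pathway averaging. Per-gene Fisher type-I rate
  at α = 0.05 is ~0.03–0.05 (the exact test is conservative at these
  counts).
- Selection-structured cohorts (ω = 1 for ranks 1–10, ω = 0.1 elsewhere):
  cohort K_h/K_s exceeds K_a/K_s in effectively 100% of replicates, with
  K_h/K_s ≈ (0.1 + 0.9·s)⁻¹-fold larger where s is the top-10 opportunity
  share; supergene regression slopes are ≈ 4 under this two-band ω
  structure (a smooth ω gradient would give the shallower ≈ 2 slope seen
  in real data).
- Per-gene detection power is intrinsically low: with ω_h = 2 planted on
  500-codon genes within the K_s < 0.08 filter window, PSG recall is
  ≈ 0.3–0.45 while the background false-positive rate stays below 1%, so
  the planted-signal test asserts enrichment rather than majority recall.
  This mirrors the real-data situation where only a handful of PSGs emerge
  from thousands of orthologs.

## Numerical choices and limitations

- Problem sizes in tests and the acceptance script (cohorts of 200 × 500
  codons, 30–40 replicates, 100 selection replicates) were chosen as the
  smallest sizes at which the sampling error of each measured quantity is
  several times smaller than the tolerance being checked.
- Fractional sites are rounded half-away-from-zero only inside the exact
  test; rates always use exact fractional counts.
- The screen is deterministic: identical inputs and configuration give
  byte-identical outputs; gene order never affects results.
- No multiple-testing correction is applied to the PSG scan, matching the
  screening procedure this package implements; treat the output as a
  candidate list, not a controlled discovery set.
- Alternate genetic codes are accepted structurally (the class table is
  rebuilt and "top 10" means the supplied table's top ranks), but all
  packaged calibrations assume the standard code's 75 classes.
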