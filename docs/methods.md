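# Methods

This note documents the statistical procedures the package implements, the
choices made where the underlying methodology leaves room, and what the
synthetic data generator does and does not emulate.

## Read preprocessing

Small-RNA tags are 40 bp single-end reads laid out as 4-base 5′ barcode +
insert + 3′ adapter. Cleaning applies, in order:

1. **Quality truncation.** The read is cut at the first base with Phred
   quality ≤ 15; that base and everything downstream is discarded. The rule
   is idempotent and may empty a read.
2. **Barcode/adapter stripping.** The first 4 bases are removed
   positionally. The adapter is then located as the *leftmost* position at
   which the remaining suffix is an exact prefix of the adapter sequence
   (match anchored at the read's 3′ end, ≥ 1 adapter base, no mismatches,
   `N` never matches). Reads with no adapter evidence are discarded — an
   un-stripped read either ran past the sequenced length without reaching
   the adapter (insert longer than measurable) or is artefactual.
3. **Length gate.** Inserts ≤ 24 nt are discarded (below the piRNA size
   range); retained inserts are capped at 35 nt. Duplicate reads are kept
   throughout, since piRNA abundance is the signal of interest.

CAGE forward mates lose a fixed 9-base prefix (6-base barcode plus the
three template-switch guanines) positionally — the GGG is not verified,
because template-switch bases are frequently miscalled — and mates ≤ 15 nt
after trimming are discarded.

Counts are conserved: every input read is retained or discarded with a
reason code, and the per-sample report table tallies both.

## Cluster expression

Alignments are assigned to a cluster only when fully contained in its
interval ("mapped within"); an any-overlap mode is available behind a flag.
Multi-mapping reads contribute once per containing cluster. Per-cluster
depth arrays accumulate contained alignments per base.

A cluster is called expressed iff all three criteria hold: contained-read
count ≥ 100 (inclusive), RPKM ≥ 10 (inclusive), and maximum depth divided
by read count < 0.9 (exclusive). RPKM uses the count of *distinct*
genome-mapped reads as the library-size denominator. Intergenic enrichment
among expressed clusters is the upper hypergeometric tail
P(X ≥ observed expressed-and-intergenic), i.e. a one-tailed Fisher exact
test.

Report percentages are rounded half-up: whole percent for genome-mapping
rates and cluster fractions ≥ 1 %, two decimals for cluster fractions
below 1 %, one decimal for sequence-sharing fractions.

## piRNA hallmarks

- **Composition.** Per-position base frequencies are computed over the
  sequences long enough to cover the position (N calls excluded);
  information content is IC(i) = 2 + Σ_b f log₂ f bits, as in a sequence
  logo.
- **1U bias.** The presence of a 5′ uridine bias is tested with a
  one-sided exact binomial test of the first-base T count against a 0.25
  background, declared significant at p ≤ 0.001 with an observed fraction
  above background. The test and threshold are package choices — the
  hallmark itself is standard, but no specific test is canonical — and
  both are configurable.
- **Length modes.** Modes are local maxima of the integer length histogram
  with count ≥ 10 % of reads (configurable prominence); plateaus report
  their smallest length. This cleanly separates the unimodal 26–27 nt
  (MILI-like) profile from the bimodal 26–27 + 29–30 nt (MILI + MIWI)
  profile.
- **Sharing.** Cross-sample sharing is the fraction of unique query
  sequences (cluster-contained reads of the query sample) present verbatim
  among all genome-mapped unique sequences of the reference sample.
- **ncRNA contamination.** A read is explained by an annotated ncRNA iff
  it occurs as an exact full-length substring of an ncRNA sequence or its
  reverse complement; since only perfect matches count, exact substring
  search is equivalent to an alignment-based scan and is used here.

## Coverage correlation

Expressed clusters are divided into non-overlapping 100-base windows; the
trailing partial window is kept. A read belongs to the window containing
its 5′-most genomic coordinate — a documented choice, since boundary
straddlers have no canonical assignment. Profiles are per-window fractions
of the cluster total. For each cluster expressed in both samples of a
pair, the Pearson correlation is computed with the two-sided t
approximation (n − 2 df); only p ≤ 0.001 correlations are retained and
summarized by their median. The t approximation is accurate at the window
counts involved (≥ 10); no permutation test is performed.

## CAGE expression

CTSSs are the 5′-most coordinates of forward mates (interval start on +,
end − 1 on −), accumulated per base and strand with no mapping-quality
filter. Counts are normalized by mapping onto a reference power law: with
a fitted sample law R_s(x) = c_s·x^(−α_s) (least squares on log R vs
log x over distinct counts in [1, 1000]) and a reference law with exponent
α_ref totalling total_ref tags, matching reverse cumulatives gives

tpm = (c_ref/c_s)^(1/α_ref) · x^(α_s/α_ref).

The reference intercept is c_ref = total_ref / ζ(α_ref), since a library
following the law exactly totals Σ_{x≥1} R(x) = c·ζ(α) tags. Defaults
α_ref = 1.25 and total_ref = 10⁶ follow common practice for this
normalization; exponent, total, fit range and an explicit c_ref override
are all configurable. Normalization is strictly monotone and reduces to
the identity when the sample fit equals the reference.

Gene expression sums the tpm of each *unique* CTSS inside the union of
strand-oriented promoter windows [TSS − 1 kb, TSS + 0.5 kb] (inclusive at
both ends) over all TSSs of the gene; CTSS strand must match the gene
strand (flag to disable). Genes at ≥ 0.5 tpm are expressed.

The TF scenario filter reads "higher than the threshold" strictly
(> 0.5) and "no more than" as ≤ 0.5: an activator-side candidate (motif
enriched in promoters of brain-expressed clusters) must exceed the
threshold in adult brain and every testes stage; a repressor-side
candidate (motif enriched in testes-only clusters) must exceed it in
brain and stay at or below it in all testes stages. Retained candidates
are annotated with their scenario and whether their annotated role
(activator/repressor/both) is consistent with it.

## Target prediction

**Hit-table route.** Alignment hits below score 160 are dropped; each
piRNA keeps its single top-scoring gene among genes expressed (≥ 0.5 tpm)
in 14 dpp or adult brain, ties broken toward the smallest gene id. The
deadenylation test drops zero fold-change genes from both groups and
compares target vs non-target fold changes by Mann-Whitney. The U
statistic uses midranks; p is exact (full null enumeration via rank-sum
counting) for n₁ + n₂ ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections (degenerate variance
gives p = 1). Fold-change tables are consumed, not computed; the synthetic
generator emits log₂((a+1)/(b+1)) as a documented stand-in.

**Signature route.** Sense reads are placed at every exact zero-mismatch
genomic occurrence on both strands. Guide reads are placed at every
genomic alignment with zero mismatches in the 5′-most 10 bases (seed
anchored at the read's 5′ end on both strands) and a summed Phred quality
of non-seed mismatch positions ≤ 160; with the synthetic default of Q30
everywhere this allows at most 5 non-seed mismatches, while real quality
strings use their actual values. A target signature site is a guide
alignment overlapping an opposite-strand sense alignment by ≥ 1 base. The
precise geometry of the published signature is not fully specified in the
available description; overlap-only is the default, and an optional
ping-pong mode additionally requires the classic 10-base 5′–5′ register.
Repeat elements are pre-filtered to ≥ 75 % of their family consensus
length (rows without a consensus are skipped with a warning), and any
gene or retained repeat overlapping a site by ≥ 1 base is reported once
as a candidate target, with repeats tallied by family.

## Synthetic data

The generator produces a uniform-composition random genome (default
400 kb over 2 chromosomes) with 40 non-overlapping clusters of 1.5–3 kb,
80 % intergenic — small enough to run in seconds while leaving every
cluster large enough for windowed coverage. Study-scale annotation (214
clusters) is exercised in tests via a larger configuration.

Per-sample signal structure follows a `StageProfile`: total reads, the
fraction of reads originating inside clusters (0.07 for adult-brain-like,
0.005 for juvenile-brain-like, 0.99 for adult-testes-like samples), the
probability that a cluster-derived insert starts with T (0.8 for
piRNA-positive samples, 0.25 — i.e. background — for juvenile brain), and
a length mixture over modal lengths; a modal length m realizes as m or
m+1 with equal probability, emulating the 26~27-style peaks. Samples
sharing a `shared_pool_id` draw cluster inserts from the same population
of anchor positions (default 600 anchors over 25 % of clusters — the
study's brain-expressed subset is of that order), which makes their
unique-sequence populations largely coincide; disjoint pools share almost
nothing. Background reads are uniform over the non-cluster genome, so the
first-base background is uniform by construction. Reads are emitted as
barcode + insert + adapter truncated to 40 bp, with Q30 qualities and a
2 % rate of low-quality (Q ≤ 15) tails to exercise the truncation rule.
A read whose low-quality tail leaves a spurious shorter adapter match is
dropped at truth lookup, as an aligner would fail to place it.

CTSS counts are floor-of-Pareto draws, giving exactly
P(count ≥ x) = x^(−α) for integer x, allocated to promoter positions of
truth-expressed genes proportionally to truth tpm; silent genes receive
no tags. Planted target sites pair an exact sense read with a guide that
is the reverse complement of the locus carrying mismatches only outside
the seed, so the signature scan must recover all of them.

**What the generator does not emulate:** realistic genome composition and
repeat structure, sequencing errors beyond quality tails, chimeric or
contaminant reads, CAGEscan paired-end fragment structure, and the
cluster-level abundance heterogeneity of real piRNA clusters (active
clusters are uniformly abundant here). Passing recovery tests therefore
demonstrates correctness of the decision rules and their thresholds under
the declared signal structure, not robustness to every artefact of real
libraries.

## Problem sizes and determinism

Recovery checks run at 50 000 reads per sample over 40 clusters; oracle
equivalences run exhaustively for Fisher tables up to N = 20 plus a seeded
sweep to N = 60, full Mann-Whitney enumeration to n = 12, and signature
scans against per-offset enumeration on 20–50 kb genomes; power-law
recovery uses ~10⁴ CTSS sites. These sizes keep the whole suite and the
acceptance script in well under a minute each while leaving all
statistical margins wide (each planted effect clears its decision
threshold by at least 2×). All randomness flows through explicit
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs, including written files.
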