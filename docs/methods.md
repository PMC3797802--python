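# Methods

This note documents the models, parameters, and design choices behind
`pyrotax`, and what the synthetic-data results do and do not demonstrate.

## The evaluation strategy

For an environmental amplicon dataset the true community is unknown, so
taxonomic precision cannot be scored against truth. The pipeline instead
quantifies *concordance*: the same tags are classified by three methods with
different error modes — a word-frequency Bayesian classifier (NBC), an
alignment best-hit rule (BH), and a lowest-common-ancestor vote (LCA) — and
tags assigned identically by all three are taken as the reliable core.
Per-genus disagreement is summarized by two indices: the overestimation
index (share of a genus's tags claimed only by NBC) and the underestimation
index (share claimed only by BH and/or LCA). A genus with a high
overestimation index is likely inflated by the Bayesian classifier; a high
underestimation index marks a genus the Bayesian classifier systematically
misses although references at ≥ 95–97% identity exist.

## Synthetic gene and community model

The simulated gene is a 1,515 bp sequence of 10 conserved segments (30 bp,
relative substitution rate 0.1) alternating with 9 hypervariable segments
(100–195 bp, rate 1.0). Amplicon sizes match common pyrosequencing designs:
V1&V2 350 bp, V3&V4 455 bp, V5&V6 300 bp, V7&V8&V9 420 bp, primers (20 bp)
included. Primer sites are the last/first 20 bp of the flanking conserved
segments and are held invariant during evolution, so every reference is
amplifiable; all pairs except V1&V2 carry two two-fold-degenerate positions
per primer, mirroring real primer sets where one region's pair happens to be
non-degenerate.

Sequences evolve down the taxonomy under Jukes-Cantor: along a branch of
divergence *d* (expected substitutions/site), a site with relative rate *r*
changes with probability `3/4·(1 − exp(−4dr/3))`, making divergences
additive along paths and giving closed-form identity expectations used as
test oracles. Default per-rank branch divergences (phylum 0.12, class 0.06,
order 0.05, family 0.04, genus 0.05, within-genus 0.005) put sibling genera
at ~90% identity in variable segments — inside the 85% search prefilter,
outside the 95%/97% acceptance cutoffs — and conspecific references at
~99%. These are ordinary magnitudes for 16S divergence at those ranks;
they make genera *separable in principle* so that any observed disagreement
is attributable to the methods, not to an impossible community.

Reads: per region one amplicon library is drawn (templates sampled with
replacement from lognormal genus abundances, σ = 1), and both sequencing
directions read the same library — as in a real experiment where one PCR
pool is sequenced from both ends. Per-base substitution errors (default
0.005) and ambiguous bases (default 0.0005) are i.i.d.; the ambiguity rate
is set so that a 400 bp read survives the any-N quality filter ~80% of the
time, a realistic retention for pyrosequencing. Indels are off by default,
which keeps coordinates exact and the length-conservation invariant
testable; there is no chimera or homopolymer-noise model, so the pipeline's
MOTHUR-style denoising steps are out of scope by construction.

What the generator does **not** emulate: real rRNA secondary structure and
covariation, taxon-specific primer mismatch (primer sites are invariant, so
"primer coverage" bias is absent), chimeras, and 454 flowgram noise.
Consequently the synthetic concordance numbers are a *verification* of the
pipeline's bookkeeping and of each method's implementation — a noiseless run
must and does yield ~100% three-method agreement — not a prediction of
field-data concordance, which is dominated by database gaps and primer
bias.

## Classifiers

**NBC.** Canonical word-model formulation: word size 8; word prior
`Pr(w) = (n(w)+0.5)/(N+1)` over N training sequences; genus conditional
`(m(w)+Pr(w))/(M+1)` for a genus with M sequences; a query is scored by the
sum of log conditionals over its *distinct* words. Confidence: 100 bootstrap
trials, each scoring `⌊W/8⌋` words drawn with replacement from the query's W
distinct words; a rank's confidence is the fraction of trials whose winning
genus lies under the full-data winner's ancestor at that rank, so
confidence is monotone non-increasing with depth and the reported lineage is
truncated at the deepest rank meeting the threshold (default 0.80).
Bootstrap randomness is seeded per tag id (CRC32 mixed with the run seed),
making per-tag results independent of processing order. Candidate-genus
references are excluded from training: the model structurally cannot emit a
candidate name, which is what makes candidate genera BH-only.

**Alignment search.** Candidates are prefiltered by a shared exact 11-mer,
then aligned query-global/reference-infix with edlib (minimum edit
distance) and rescored from the traceback with blastn-like constants
(match +2, mismatch −3, gap open 5, gap extend 2). Identity is matches over
alignment columns. Bit score `S' = (λS − ln K)/ln 2` and e-value
`K·m·n·e^(−λS)` use λ = 0.625, K = 0.41 (exposed in config; no attempt is
made to reproduce any specific BLAST build's values). A literal e-value
ceiling of 1e−100 would reject *every* desk-scale alignment (a perfect
300 bp match has e ≈ 1e−150 only against megabase databases), so the
operative filter is its documented identity surrogate: hits below 85%
identity are discarded, and the e-value ceiling remains available in
config. Hits are ranked (bit score desc, identity desc, reference id asc) —
a total order, so ties are deterministic — and truncated to 50.

**BH / LCA.** BH takes the first hit at ≥ 97% identity (candidate genera
allowed). LCA keeps non-candidate hits at ≥ 95% identity within 10% of the
best qualifying bit score (min support 1) and returns the deepest shared
rank prefix. BH identity is computed over alignment columns (not query
length); whether the original convention used alignment or query length is
ambiguous, and the choice is pinned here.

## Read preparation

Fixed drop order — ambiguous bases, then primer, then length — makes reason
codes deterministic and the conservation identity
`input = kept + dropped(ambiguous) + dropped(primer) + dropped(length)`
testable. Primers must start within the first 3 bases of a read and may
mismatch at ≤ 2 positions (IUPAC classes; a read base matches a degenerate
primer letter if it belongs to the letter's class). Amplicons longer than
the read (V3&V4, V7&V8&V9) are trimmed with the sequencing-start primer
only, so the far primer cannot bias retention; the other regions require
both primers. Reverse-direction tags are reverse-complemented after
trimming so all classifiers see one strand — the original protocol does not
state whether this was done, but single-strand classification is what makes
the two directions comparable as duplicates. Length minima are
strictly-greater-than: V1&V2 > 250, V5&V6 > 200, V3&V4 and V7&V8&V9 >
300 bp. Depth normalization subsamples without replacement with a seeded
generator (numpy PCG64, recorded in the manifest), preserving input order;
the full-scale default depths are 32,000 per dataset and 24,000 for V987, and
scaled-down runs keep that 4:3 ratio.

## Curation

A reference is retained iff a classifier trained on the database's own
labels reproduces its genus at the 80% threshold. Using the database to
police itself means planted label noise is detectable exactly when genera
are separable: at the tested scale (20 genera × 20 references, 10% of
labels flipped across families) the filter removes all 40 planted errors
and keeps all 360 correct records, because a mislabeled record's sequence
still scores highest under its true genus. Candidate genera are exempt
(retained with status "exempt", shown as `0/n(0%)` in the retention table
since zero are *classifier-consistent*) and excluded from classifier
training. Percentages round half-up to one decimal, with trailing `.0`
dropped (`100%`, `0%`). Merging with a base database is by record id;
identical duplicate ids collapse, conflicting lineages for one id are an
error.

## Concordance accounting

A tag contributes one count to every genus any method assigned it: a tag
with three different genus calls adds one n1 to each of the three genera —
the only reading under which each genus's denominator equals "total tags
assigned to this genus by any method". LCA calls above genus count as
unassigned at genus. Candidate genera are excluded from three-method
partitions (they are structurally BH-only) and appear only in BH profiles.
Indices and displayed percentages round half-up to one decimal; internal
arithmetic is unrounded. Bray-Curtis distances are computed on unrounded
genus percentages; the UPGMA linkage is scipy's average linkage, emitted as
an ultrametric Newick tree (the clustering method is not dictated by the
concordance definition; UPGMA is the conventional choice for such profile
matrices and is recorded in config). In the threshold sweep the asserted
monotone quantity is the solely-NBC share of *total* tags (guaranteed by
assigned-set inclusion); the solely-NBC share of currently-assigned tags is
reported alongside but its denominator shrinks with the threshold. The
"mean Bray-Curtis" summaries average the two direction datasets per region.

## Problem sizes and determinism

The demo run uses 20 genera over 4 phyla (one candidate genus), 3
references per genus, libraries of 160 templates per region, and
normalization depth 100 (75 for V987) — sizes chosen so a complete run
finishes in ~10 s while every dataset retains enough tags for stable
percentages; the curation demonstration uses 20 genera × 20 references.
All stages derive their randomness from the run seed (per-stream seeds are
mixed with CRC32 of stream labels and kept below 2³¹), and a rerun with the
same config reproduces byte-identical outputs, which the test suite checks
via manifest digests.

## Known limitations

* Concordance on synthetic data is near-ceiling by design; the pipeline
  verifies method implementations and accounting, not field performance.
* The alignment engine optimizes edit distance, then rescores; for highly
  gapped alignments the affine-score optimum could differ. At ≥ 85%
  identity on substitution-dominated data the two coincide in practice, and
  an independent local affine aligner cross-checks identity in the tests.
* Karlin-Altschul constants are nominal; e-values are comparable within a
  run, not across tools.
* The taxonomy generator produces balanced trees with bounded family/order
  sizes; real taxonomies are far more skewed.
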