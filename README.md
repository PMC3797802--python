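# pyrotax

Which hypervariable region of the 16S rRNA gene, and which classification
method, should you trust for genus-level identification of the bacteria that
matter in activated sludge — nitrifiers, denitrifiers, polyphosphate/glycogen
accumulators, bulking and foaming filaments, potential pathogens?

`pyrotax` re-implements, as a tested and fully synthetic-data-driven
pipeline, an *unsupervised* evaluation strategy for that question: classify
the same amplicon reads ("pyrotags") with three independent methods and use
their concordance as a proxy for taxonomic precision, region by region.
Because the truth for an environmental sample is unknowable, agreement among
methods with different error modes is the measurable signal.

## What it computes

**Three assignment methods on one interface**

* **NBC** — a word-based naive-Bayes classifier with bootstrap confidence
  (the RDP-classifier formulation): word prior `Pr(w) = (n(w)+0.5)/(N+1)`,
  genus conditional `P(w|g) = (m(w)+Pr(w))/(M+1)`, score
  `Σ_w log P(w|g)` over the query's distinct 8-mers; confidence at a rank is
  the fraction of 100 bootstrap trials (each scoring a random eighth of the
  words) whose winner falls under that rank's node. Default acceptance: 80%
  confidence at genus.
* **BH** — best-hit: the top alignment hit (bit score, then identity, then
  reference id) at ≥ 97% identity donates its genus. The only route to
  *candidate* genera (provisionally named taxa such as 'Accumulibacter' that
  formal taxonomies lack).
* **LCA** — lowest common ancestor of all hits at ≥ 95% identity within 10%
  of the best bit score (min support 1): conflicting hits push the call
  above genus rank.

**Concordance statistics** per region × direction dataset and genus: the
partition of tags by which subset of methods assigned them (n3 / n2 / n1
with `n3 + Σn2 + Σn1 = total tags any method assigned`), and two bias
indices

* overestimation index = `100 · n1[NBC] / denominator` — tags only the
  naive-Bayes method claims;
* underestimation index = `100 · (n2[BH,LCA] + n1[BH] + n1[LCA]) /
  denominator` — tags the alignment-based methods claim but NBC misses;

plus genus abundance profiles (detection limit `100/depth` %), pairwise
Bray-Curtis dissimilarity `Σ|x−y| / Σ(x+y)` with UPGMA clustering of the
region × method datasets, a confidence-threshold sweep (0.5 / 0.8 / 0.95 /
1.0), and an across-region max/min fold summary of consistently assigned
tags.

**Reference curation.** Before classification, the reference database is
self-consistency filtered: a reference is kept only if the classifier,
trained on the database's own labels, reproduces its genus at the 80%
threshold (candidate genera are exempt). Retention is tabulated per genus in
the `retained/downloaded(pct%)` convention.

**Synthetic data with known truth.** A generator emulates the whole study:
a ranked taxonomy (domain → genus), ~1.5 kb 16S-like sequences with
alternating conserved/hypervariable segments evolved under Jukes-Cantor
(variable segments fast, conserved slow, primer sites invariant), degenerate
primers anchored in conserved segments (the V1&V2 pair is the only
non-degenerate one), directional reads with substitution/ambiguity errors,
uneven lognormal genus abundances, and controllable label noise for curation
tests. Every read carries its true genus, so each stage is testable
end-to-end without any download.

## Worked example

The numbered scripts under `analysis/` run the demo-scale study (20 genera
over 4 phyla, one candidate genus, 4 regions × 2 sequencing directions,
depth 100 per dataset, seed 1) and write summary tables under `results/`:

```
python analysis/01_simulate_community.py
python analysis/02_prepare_reads.py
python analysis/03_curate_database.py
python analysis/04_classify_tags.py
python analysis/05_concordance_analysis.py
```

Selected output (seed 1):

```
demo database: 57/60(95%) references classifier-consistent
label-noise recovery: 40/40 mislabeled eliminated; 360/360 correct retained
default run: 83.1% of genus-assigned tags concordant across all three methods
Bray-Curtis: direction duplicates 0.101 vs different regions 0.191 (mean, per method)
noiseless control: 100.0% three-method concordance
```

Reading these: curation keeps 57 of 60 demo references (the three
eliminations are genuine borderline sequences) and, when 10% of a 400-record
database is deliberately mislabeled across families, removes every planted
error without sacrificing a single correct record. On noisy reads, ~83% of
genus-assigned tags are claimed identically by all three methods — the
remainder is dominated by candidate-genus tags, which only best-hit can name
and which the naive-Bayes classifier confidently misattributes to sibling
genera (the overestimation mechanism). Profiles of the two sequencing
directions of one region sit closer in Bray-Curtis space (0.10) than
profiles of different regions (0.19): datasets cluster by region, i.e. the
choice of hypervariable region changes the apparent community more than the
choice of direction. With error-free, full-coverage reads the three methods
agree on 100% of tags — the pipeline itself introduces no disagreement.

The same pipeline is scriptable via the CLI
(`pyrotax --seed 1 --outdir runs/demo run-all`, stages also available as
`simulate`, `prep`, `curate-db`, `classify`, `concordance`, `report`) or the
library API (`pyrotax.run_pipeline`).

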