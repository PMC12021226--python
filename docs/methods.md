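# Methods

This note documents the models, rules and numerical choices behind
`dietbarcode`, in the order data flows through the pipeline.

## The analysis model

A fecal sample contains DNA fragments of the plants the animal ate, plus
several nuisance sources: PCR chimeras, DNA of the bait used to trap the
animal, and stray contamination (pollen, lab carry-over). The analysis
treats a short chloroplast barcode (a ~262 bp *rbcL* fragment) as the unit
of evidence: reads are collapsed to exact amplicon sequence variants
(ASVs), nuisance reads are removed by explicit filters, and each surviving
ASV is matched against a curated reference database and resolved to the
most specific taxonomic rank its matches allow. Diet is then summarized as
per-sample taxon presence, because read abundance within a fecal sample is
a poor quantitative proxy for intake; abundance is retained only as the
substrate for Bray–Curtis dissimilarity between samples.

## Reference database

* **Trimming.** Deposited reference sequences are longer than the
  amplified region. The region is located between two anchor primers,
  each allowed ≤ 2 mismatches (leftmost best occurrence); sequences
  missing an anchor are skipped and logged, never silently dropped. Real
  pipelines trim by multiple alignment; primer-anchored extraction is
  simpler, exactly testable, and sufficient for fixed-layout synthetic
  references.
* **Resolution classes.** After deduplication, each unique sequence is
  classed by its source-species set under the flora taxonomy:
  `species_specific` (one species), `genus_shared`, `family_shared`,
  `unassignable` (spans families). Percentages are reported over unique
  sequences, rounded half-up to one decimal — the convention of published
  database tables (6.25% prints as 6.3%), hence a dedicated
  `round_half_up` rather than Python's banker's rounding.
* **Curation.** Misidentification detection is input, not computation: a
  user blacklist (accession, reason) removes bad accessions before
  deduplication. The bait-confound rule generalizes a single published
  instance into a set rule: a species is bait-confounded iff *every* one
  of its sequences is shared with a bait species. Bait species and
  bait-confounded species are excluded; additionally, every entry carried
  by a bait species is dropped outright, so a distinguishable in-area
  species keeps only its bait-free sequences — a read matching a
  bait-shared sequence is inherently ambiguous and must not be credited
  to the wild plant.
* Species with no usable sequence are reported as *uncovered*; the
  package reports its own coverage accounting and does not attempt to
  reproduce any particular published species count, whose derivation
  involves retrieval details outside this scope.

## ASV processing

Order is fixed: dereplicate → remove chimeras → low-frequency filter →
rarefy. No stage creates ASVs; each stage logs per-sample read accounting.

* **Dereplication is exact.** There is no learned error model: an error
  read is its own ASV. This works because the synthetic error rate
  (1 × 10⁻³ substitutions/base, ~0.26 errors per 262 bp read) keeps true
  variants dominant, and the 1% filter then removes error ASVs — the same
  mechanism real pipelines lean on for contamination control. At
  realistically higher error rates an error-model denoiser would be
  needed; this is a known limitation.
* **Chimera rule.** An ASV is removed from a sample iff two parents in
  the *same sample*, each with ≥ 2× its abundance, compose it exactly at
  some breakpoint (`a = p[1..k] + q[k+1..L]`). Exact composition plus the
  2× multiplier follows the spirit of the standard de-novo bimera test;
  parents are required to be same-length (regions are fixed-length here).
  Parents are necessarily distinct from the candidate because they are
  strictly more abundant.
* **Low-frequency filter.** Strictly-below-1% per sample ("fewer than
  1.0%"): a count at exactly 1.0% of the sample total is retained. Applied
  per cell; all-zero ASVs are dropped.
* **Rarefaction.** Multivariate-hypergeometric subsampling (without
  replacement, matching `rrarefy` semantics) of every sample to the
  configured depth (default 1000); samples below depth are dropped with a
  warning — the handling of shallow samples is this package's policy, as
  the source workflow never encountered one. A required seed makes every
  run reproducible. The rarefaction *curve* is the exact hypergeometric
  expectation, not Monte-Carlo; the test suite checks that Monte-Carlo
  subsampling converges to it (3 SE at 1000 replicates).

## Taxonomic assignment

* **Identity.** Global alignment with match +1, mismatch −1, gap −2, end
  gaps penalized; identity = matches / alignment columns × 100. For
  equal-length pairs with ≤ 2 mismatches the gapless alignment is provably
  optimal under this scoring (any gap costs ≥ 5 score points), so a
  Hamming fast path covers exact and near-exact hits; everything else
  goes through the full aligner.
* **Gate.** 98.0% by default; *exactly* 98.0% passes (the boundary is
  ambiguous in common usage; ≥ is this package's documented, configurable
  choice).
* **Ties.** Entries within 1e-9 of the best identity form the tie set —
  exact ties only; search-heuristic score ties are not emulated. The union
  of tied source species is resolved by lowest common rank. A tie set
  spanning families yields status `unassigned` with an explicit reason.
* **Exclusions.** Matches attributable only to bait are
  `excluded_bait` at either tier. Fallback-tier (public-repository)
  assignments additionally pass a plausibility filter: every matched
  species must grow in the study area or be on a user allow-list of
  planted taxa; otherwise `excluded_implausible`. Ecological judgement is
  input (flags and allow-list); the filter mechanics are computation.

## Diet table and summaries

A taxon is the pair (resolved rank, name) *together with* the member
species behind the tie — two distinct tie sets resolving to the same
genus or family name are distinct taxa, displayed with `-1`/`-2` suffixes
ordered by overall frequency (descending; ties broken lexicographically
by member list). Presence requires ≥ 1 rarefied read from ≥ 1 assigned
ASV. Seasons come from a `season` column or from collection month binned
Mar–May / Jun–Aug / Sep–Nov / Dec–Feb. Frequency-of-occurrence percents
divide by the seasonal sample count, half-up to one decimal.

The packaged `table1.tsv` is a transcription of a published 72-taxon,
43-family, 100-sample diet summary (seasonal n = 22/35/32/11). The loader
validates on every load: row and family counts, overall = Σ seasonal
counts, and every printed percent against its recomputed value.

## Community statistics

* **Dissimilarity.** Bray–Curtis on rows normalized to relative
  abundances (Σ|x−y| / Σ(x+y)); Jaccard on presence (1 − |A∩B|/|A∪B|).
  Computed via `scipy.spatial.distance.pdist`, which implements these
  exact formulas.
* **NMDS.** Kruskal stress-1 minimized by iterative majorization (Guttman
  transform) with pool-adjacent-violators monotone regression on the
  dissimilarity ranks; ties use the primary approach (tied dissimilarities
  may take different disparities, implemented by ordering ties by current
  configuration distance). Default 20 restarts, convergence at 1e-6 stress
  change, 300 iterations max. The first restart is initialized from
  classical scaling (PCoA) — deterministic and exact whenever the matrix
  is Euclidean in k dimensions — because pure random starts stall in local
  minima, especially for 1-D embeddings; the rest are random. Stress
  > 0.2 is reported as uninterpretable. Embedding requires k < n.
* **PerMANOVA.** `SS_total = Σ_{i<j} d²_ij / N`; `SS_within` sums
  within-group pair terms scaled by group size; pseudo-F and R² follow.
  The p-value permutes labels with the +1 correction (never exactly
  zero), default 10 000 permutations. Type-I calibration is verified by
  simulation (≈ 5% rejections at α = 0.05 over 200 null datasets); the
  pseudo-F is cross-checked against an independent implementation in the
  test suite.
* **Coverage and diversity.** Sample coverage uses the singleton/
  doubleton estimator `Ĉ = 1 − (f1/n)[(n−1)f1/((n−1)f1+2f2)]` (with a
  Turing fallback when n = 1). Diversity is the Hill number of order 1
  (exp Shannon entropy; the order is configurable but 1 is the default
  and the one reported). Interpolation at m < n uses the exact
  hypergeometric expectation of subsample entropy, so the curve passes
  through the observed point at m = n to machine precision. Extrapolation
  anchors a hyperbolic path `H(m) = H_asy − (H_asy − H_obs)·(n/m)` at the
  observed point, tending to a singleton/doubleton-corrected asymptotic
  entropy (clamped to ≥ H_obs); the exact extrapolation family is an open
  design choice and this one is verified against the brute-force
  subsample oracle on small vectors rather than against any external
  package. Confidence bands are percentile bootstrap (2.5/97.5) over
  multinomial resamples of the count vector; the unseen-species bootstrap
  adjustment is deliberately omitted (a documented simplification that
  narrows bands slightly when coverage is low), and bands are widened if
  needed to bracket the point estimate.
* **Steel–Dwass.** For each group pair, the pooled two-sample rank sum is
  standardized with the tie-corrected variance and referred to the
  studentized-range distribution with k = number of groups and infinite
  degrees of freedom (the large-sample Steel–Dwass–Critchlow–Fligner
  procedure); exact enumeration appears only as a test oracle. A compact
  letter display derives group labels at a chosen α.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a local-database
metabarcoding study: a flora hierarchy with controlled sequence
divergence (family roots random; genera diverged from the root by
`within_family_div` substitutions; within a genus, species 1 carries the
genus backbone and each further species diverges at its own disjoint
block of `within_genus_div` positions, so that configured pairwise
distances are exact and `within_genus_div = 0` forces genus-ambiguous
identical sequences). Reads are multinomial draws from seasonal diet
profiles with i.i.d. substitution errors, same-sample two-parent
chimeras at a uniform breakpoint, bait reads, and contaminant reads from
a single out-of-area species per sample.

Default study conditions: 24 samples (6 per season) × 2000 merged reads,
262 bp region, error 1 × 10⁻³/base, 2% chimeras, 5% bait, 1%
contaminants. Spring/summer/autumn profiles hold six species
(0.35/0.20/0.15/0.10/0.10/0.10, rotating so seasons overlap but differ);
winter holds four (0.40/0.30/0.20/0.10), emulating the narrower
cold-season diet field studies observe. Every dietary proportion is ≥ 5%
so that true taxa clear the 1% filter with high probability — the
regime the analysis is designed for.

Not emulated: platform-specific error profiles and quality-score
structure (qualities are constant Q37 placeholders), indels, PCR
amplification bias, index hopping, paired-end merging, and
quality-trimming. Passing tests therefore demonstrate that the *defined
computations* are correct and that the pipeline recovers truth under a
substitution-only noise model; they do not certify performance on reads
whose error structure violates those assumptions.

## Determinism

One top-level seed drives everything. Stage-specific generators derive
from `SeedSequence([seed, stage, index])`, so per-sample streams are
independent but reproducible, and two runs from the same seed are
byte-identical at every written artifact (FASTA/FASTQ, tables,
ordinations, bootstrap bands) — asserted in the test suite.

## Problem sizes used in tests

The default test suite and the acceptance script run the full pipeline at
the default study conditions above (24 × 2000 reads), PerMANOVA
calibration at 200 null datasets × 999 permutations (16 samples, 4
groups), bootstrap bands at 200–1000 replicates, and oracle enumerations
on deliberately tiny inputs (6-read vectors, 20-species floras, 10-element
rank tests) where exhaustive computation is exact.
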