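# Methods

This note records the models behind each pipeline stage, the parameters that
matter, what the synthetic generators do and do not emulate, and the design
choices made where the design was genuinely open. Every empirical statement
here is one the test suite or `scripts/acceptance.py` actually computes.

## Gene identity and file dialects

Genes are uppercased HGNC-style symbol strings; no alias resolution is
attempted, so two sources naming the same locus differently count as
different genes. All tabular files are strict TSV (UTF-8, no quoting). Exon
files follow BED conventions (0-based, half-open); variant tables are
1-based. The conversion happens exactly once, when a variant is assigned to a
compound exon. Readers are total on writer output and fail with line-numbered
errors otherwise; the only silent-looking cleanup — edge-list self-loop and
symmetric-duplicate removal — is counted and reported on the returned object.

## Overlap accounting

For a focal disease F, each focal gene is classified by the number of *other*
disease sets containing it: 0 → unique, 1–2 → shared with at most two,
≥3 → shared with more than two. This reading makes the three classes a
partition of the focal set; a `count_focal` flag shifts the counts by one for
the alternative reading in which the focal set itself is counted. The
deconfounded pair used by the network stage is (A, B∖A): genes shared with
the focal set are excluded from the comparison set so literal gene overlap
cannot masquerade as network convergence. A comparison where B ⊆ A raises a
degenerate-comparison error rather than silently testing an empty set.

## Deleterious-mutation burden

The compound exon model of a gene is the union of its exon intervals across
all isoforms, merged into maximal non-overlapping blocks; touching blocks
(end == next start, half-open) merge, so the model is invariant under
duplicated isoform annotations. A variant is deleterious when it is missense
with allele frequency below the rare cutoff, or loss of function
(stop-gain, frameshift, canonical splice donor/acceptor — a closed
vocabulary; non-canonical splice-region variants fall into "other" and are
never counted). The rare cutoff defaults to 0.01 against the variant table's
own AF column; it is a convention, not a fitted value, and is exposed as a
flag.

The burden observation unit fed to the KS test is the per-compound-exon
count divided by exon length in bp, pooled across all genes of a set.
A `per_gene` option pools gene-level mean burdens instead; per-exon pooling
is the default because exon-level normalization is what defines the
statistic. The two-sample KS test uses the exact ECDF supremum distance and
the asymptotic Kolmogorov p-value at effective size n_a·n_b/(n_a+n_b).
The asymptotic p is anti-conservative below a few dozen observations per
group; the intended regime (hundreds of exons per set) is comfortably
asymptotic, and the test suite pins D against a brute-force ECDF oracle and
cross-checks p against an independent implementation.

## Percentile expression profiling

The percentile convention is linear interpolation on sorted values (index
(q/100)·(n−1)), pinned for bit-reproducibility; q defaults to 75.

*Transcripts*: a transcript's population expression is summarized by its mean
FPKM across samples before thresholding against the genome-wide 75th
percentile of those means (strict >). A `per_sample` option instead counts
per-sample threshold crossings and averages afterwards; the default is the
simpler reading. Per-gene counts of highly expressed transcripts are averaged
over the query set and over all annotated genes. Genes whose transcripts are
all below threshold contribute zero (they are not excluded), so a set mean is
comparable across sets of different detection rates.

*Proteins*: the cutoff is the 75th percentile of the pooled gene×tissue
value matrix — one global cutoff, matching the idea of "highly expressed
relative to the entire dataset" — with a `per_tissue_cutoff` alternative.
Per tissue, the summary reports the mean spectral count over set genes and
the fraction of set genes above the cutoff. The hematopoietic fold is the
mean above-cutoff ratio over hematopoietic cell columns divided by the mean
over all other tissues; it is +∞ when only hematopoietic ratios are non-zero
and NaN (with a warning) when all ratios vanish. Both ratios and counts are
scale-equivariant: multiplying the whole matrix by a constant changes
nothing, because the threshold scales with the data.

ΔΔCT: Δ = CT_target − CT_reference, ΔΔ = Δ − Δ_calibrator, rq = 2^(−ΔΔ).
Pure arithmetic; no amplification-efficiency correction is attempted.

## Pathway enrichment

Pathway sizes are measured after intersecting with the declared background
universe, and the query is restricted to the same universe, keeping the 2×2
margins consistent; the size filter (15–1000 genes) runs on the restricted
sizes. The test is the one-sided hypergeometric tail P(X ≥ k) — enrichment
only, since depletion is not of interest here. BH-FDR is computed within a
single disease's scan, not across diseases, so each phenotype's q-values are
self-contained. Significance is the dual rule p < 10⁻³ AND q < 0.01. The
overlap read-out counts pathway names significant in both of two scans over
the same database.

## Network seed-connectivity permutation test

The interaction graph is simple and undirected: symmetric duplicates and
self-loops are removed at read time, so each gene pair is one degree of
connectivity. The statistic is the number of edges between the focal seed
set A and the disjoint set B. The null replaces B with an equal-sized
uniform draw from a declared protein-coding background — node replacement
rather than degree-preserving rewiring, because it leaves the graph (and
thus every hub's study-bias) untouched while randomizing only which genes
are claimed by the disease. Design choices on points the procedure leaves
open, each exposed as a flag:

- draws are without replacement within a replicate (`with_replacement`
  flips this);
- draws exclude set A, preventing forced seed overlap
  (`allow_seed_overlap` flips it), but otherwise use the full declared
  background, including genes absent from the graph (they contribute zero);
- the empirical p is the add-one estimator (r+1)/(n+1), never exactly zero;
  when r = 0 the upper bound 1/n_perm is also reported and feeds the
  Bonferroni correction min(1, n_tests·p), which with 8 comparisons and
  50,000 permutations yields the 1.6×10⁻⁴ headline bound;
- candidate ranking by contributing connectivity (adjacent seed count)
  breaks ties by higher total degree, then lexicographic symbol, for
  determinism.

## Synthetic data: what is emulated, and what is not

The generators are first-class, tested code; their defaults define the study
conditions for every statistical guarantee in the test suite.

- **Catalog**: membership patterns (a set of diseases, a count) place genes
  in exactly those sets; remaining slots get unique genes. Pairwise overlaps
  equal the pattern sums exactly, by construction. The shipped default
  scenario realises nine diseases, 407 distinct genes, focal overlaps
  11/8/5/5/4/4/1/0 and sharing classes 8/17/5. Patterns rather than a
  pairwise overlap table are required because the sharing classes constrain
  *joint* memberships, which pairwise counts cannot express.
- **Exome**: 3–8 exons of 80–400 bp per gene (a realistic coding-gene
  shape), with an occasional contained duplicate isoform exon to exercise
  merging. Deleterious-class variants arrive by a Poisson process at
  0.02/bp in tolerated genes and half that in constrained (risk) genes —
  a 2:1 depletion representing purifying selection at an effect size the
  KS test should detect with hundreds of pooled exons. 75% of deleterious
  variants are missense, of which 90% draw rare AFs (Beta(0.2, 5) scaled
  below the 0.01 cutoff); the rest are LOF with rare AFs. Synonymous decoys
  at 0.03/bp verify the classifier. λ is the *placement* rate of
  deleterious-class variants; the post-classification rate is
  λ·(0.75·0.9 + 0.25) ≈ 0.925λ, which leaves the 2:1 group contrast intact.
- **Expression**: log-normal(μ=1, σ=1) baselines; 1–5 transcripts per gene
  over 45 samples (FPKM), and one gene×30-tissue matrix (6 fetal, 18 adult,
  6 hematopoietic columns). Risk genes are multiplied by the boost factor
  (default 3) in hematopoietic columns. With this boost the above-cutoff
  ratio in boosted tissues is ≈0.66 against ≈0.25 elsewhere, so the planted
  fold concentrates near 2.6 — comfortably recovering a ≥2-fold read-out.
- **Gene sets**: 400 decoy sets of 15–400 genes drawn uniformly from a
  5,000-gene universe, plus one planted set holding half of the focal
  disease's genes. 400 sets (not thousands) keeps the desk-scale scan fast
  while leaving the multiple-testing correction non-trivial.
- **Network**: Erdős–Rényi background (2,000 nodes, p=0.02) plus planted
  focal-vs-disease bipartite edges at p=0.1 (5× background).

Not emulated: linkage structure, real genome coordinates, mass-spec noise,
pathway co-membership correlation, degree heterogeneity of real
interactomes. Consequently the passing statistical tests certify the
*procedures* (calibration, power against planted effects, exact recovery of
planted designs) — they do not certify effect sizes on real databases, whose
headline values depend on database versions.

## Problem sizes and numerical choices

The suite's stochastic checks use: 200 null and 100 planted replicates for
the permutation test (999 and 2,000 inner permutations respectively), 500
null and 200 half-rate replicates for the burden KS (100 genes per group),
100 permuted-query enrichment scans, and 100 seeds for the hematopoietic
fold. These sizes put the Monte-Carlo error of each rate well inside its
acceptance band while keeping a full run on one CPU in about a minute.
Empirical p-values are never reported as zero (add-one estimator); FET
p-values come from the hypergeometric survival function; BH from the
standard step-up recursion. All randomness flows from explicit integer
seeds through numpy Generators; per-stage streams are derived as
(seed, stage-index) so stages are independently reproducible.

## Known limitations

- Symbol-level identity: without alias harmonization, cross-source symbol
  drift deflates overlaps and connectivity on real data.
- The asymptotic KS p-value is unreliable for sets contributing only a few
  exons; a permutation KS would be the remedy at small scale.
- The enrichment stage assumes the background universe is declared correctly;
  an overstated universe inflates significance.
- Node-replacement nulls preserve study bias but not the tested set's degree
  sequence; a degree-matched null would answer a different (also
  reasonable) question and is not implemented.
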