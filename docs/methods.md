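# Methods

This note documents the models, parameter choices and numerical
conventions behind `tissamp16s`, what the synthetic data does and does not
emulate, and the design decisions taken where the protocol left the design
open.

## Library layout arithmetic

The two-step PCR library is modeled from the primer sequences themselves
(`protocol.py`). PCR-1 amplifies a 467 nt V3–V4 region with fusion primers
(16S primer + partial adapter tail), giving the printed 522 bp product;
PCR-2 extends to full P5/P7, adding 30 nt on the forward side and
24 + 6 (index) + 6 (spacer) nt on the reverse side, hence 588 bp. The
segment lengths are derived from the primer strings, not hard-coded. The
printed 522 bp figure is 1 bp short of region + both 28 nt tails; we take
the printed values as given and do not reconcile the discrepancy.

## Index design

Step 1 scans all 4⁶ = 4096 hexamers in lexicographic order and accepts an
index iff it keeps Hamming distance ≥ 2 to, and is neither the complement
nor the reverse complement of, every previously accepted index. The scan
order of the original design was never published (it reported 466
candidates); lexicographic greedy is fixed here for determinism and yields
832 candidates. Matching the historical candidate count is explicitly a
non-goal.

Step 2 minimizes a balance objective we define to operationalize
"equivalent channel proportions" and "base fractions close to 25 %":
the sum over the six positions of |A/C-channel fraction − 0.5| plus the sum
of squared deviations of each base fraction from 0.25. Small instances
(≤ 5000 subsets) are solved exactly by enumeration; larger ones by a
balance-aware greedy seed followed by deterministic first-improvement swap
passes (ties always resolve toward the lexicographically smallest index).
On the full candidate pool the default 320-index panel reaches objective
0 — perfectly uniform base composition at every position. Panels smaller
than ~8 indexes cannot meaningfully satisfy the ±0.15 channel-balance band;
balance checking is skippable by flag for such degenerate panels. When a
requested panel size is infeasible, the error reports the size achievable
by the greedy construction (the exact maximum clique size is NP-hard and
not computed).

## Pair joining

Joining scans every admissible overlap length (longest first), counts
mismatches by vectorised byte comparison, and keeps the overlap with
minimal mismatch density; ties go to the longer overlap. This is a
documented deterministic substitute for the external joiner's internal
scoring, which differs slightly. N bases count as mismatches in the
density; at consensus positions the higher-quality base wins, ties keep
mate 1, and N always loses to a non-N base. The kit presets (min/max
overlap 10/70 for 2×250, 110/170 for 2×300, density cap 0.1) follow the
protocol. Intervals are 0-based half-open internally; reports are 1-based
inclusive.

## Template alignment and culling

Each dereplicated sequence is recruited to the reference template sharing
the most distinct 8-mers (ties to the lexicographically smallest template
id) and globally aligned to the template's ungapped sequence with match
+1, mismatch −1, gap open −2, gap extend −1 and free end gaps (Biopython's
`PairwiseAligner` provides the dynamic programming). The alignment is
projected into the reference column space; query bases inserted relative
to the template are dropped and counted (NAST-style), so the whole working
set lives in one column space as the later stages require.

Culling thresholds: identity is defined as matches divided by alignment
columns (aligned pairs plus in-span unpaired bases of either sequence);
the floor is 0.60, with a 0.50 coverage floor (aligned pairs / query
length). The identity floor was set empirically: under this scoring
scheme, random 467-mers against a 16S-like template reach identity
0.50–0.56 when they cover half the query, so a 0.50 floor would let a few
permille of junk through, while genuine reads sit at ≥ 0.9. 0.60 separates
the two populations with a wide margin. Both floors are configurable.

A fast path skips the dynamic programming when the query has the same
length as the ungapped template and ≥ 0.90 positional identity — the
projection is then the identity map. With substitution-dominated MiSeq
errors this covers almost every read; indel-carrying reads take the DP
path.

## Denoising

Pre-clustering processes uniques in decreasing abundance (ties by
sequence) in a single pass; each sequence merges into the most abundant
already-retained sequence within ≤ 3 column differences. A gap column
aligned to a base counts one difference and gap-vs-gap counts zero; each
gap column counts independently (no run compression). This deliberately
differs from the OTU-distance convention below, mirroring the two
different defaults of the source environment. Post-merge singletons are
withdrawn as presumed uncaught errors or sub-background taxa.

The chimera screen is a simplified reimplementation of the chunked
two-parent vote model of the cited de novo screener. Queries are processed
in increasing abundance; candidate parents are retained sequences at
≥ 2× the query's abundance. The query is cut into 4 equal column blocks;
for each block boundary the best left and right parents are chosen by
prefix/suffix match counts, and the best single-crossover model is
compared with the best single parent. With Y = columns only the model
explains and N = columns only the single parent explains, the score is
Y/(Y + 8·N + 0.5); a query is flagged iff the score reaches 0.28 and both
parents differ from it by ≥ 3 columns. β = 8, ε = 0.5, 4 chunks, skew 2
and the 0.28 threshold are the cited tool's defaults, stated here as this
package's defaults; all configurable. Flagged queries never serve as
parents.

## Classification

The naive-Bayes word model uses distinct 8-mers (presence/absence, not
multiplicity), priors (n_w + 0.5)/(N + 1) and per-genus conditionals
(m_w + prior)/(M_g + 1), following the classifier publication the
protocol delegates to. Bootstrap confidence resamples ⌊W/8⌋ of the W
distinct query words with replacement, 100 times, with a seeded generator;
per-rank confidence is the percentage of bootstrap winners agreeing with
the full-word winner's lineage at that rank. The 80 % cutoff is applied
at every rank (matching the "unclassified at a given level" semantics),
with hierarchical consistency enforced: once a rank is unclassified,
deeper ranks are too. Words are taken from the given strand only — read
orientation is resolved upstream by the aligner. Ties in the genus argmax
resolve lexicographically.

## OTU clustering

Pairwise distances are computed over the shared blunt columns; columns
where both sequences have gaps are excluded, substitutions count one, and
a maximal run of gap-vs-base columns counts once (one indel event). The
"0.03" cutoff is a fractional distance (97 % identity), the universal
convention; a cutoff below 0.005 triggers a warning in case a user passes
0.0003 expecting "0.03 %". Clustering is agglomerative average linkage
weighted by cluster member counts, merging while the minimal average
distance is ≤ the cutoff, with deterministic tie-breaking on the
lexicographically smallest member labels. Consensus taxonomy is an
abundance-weighted per-rank vote at 51 %; the representative is the most
abundant member (ties lexicographic) — the protocol never names a
representative rule; one is needed for tree building.

## Diversity statistics

Rarefaction subsamples without replacement via multivariate
hypergeometric draws (step 100, 1000 resamples by default) and always
includes the exact observed richness at full depth. The representative
tree is neighbor joining on the run-compressed distances, midpoint-rooted,
with negative NJ branch lengths clamped to zero. The original analysis
never states which tree its phylogenetic distances used, so generalized
UniFrac values here are internally consistent but not numerically
comparable to any published figure; this is the single most consequential
free choice in the statistics layer. Alpha presets: 0.6 for
dilution/background comparisons, 0.2 for tissue ordinations. PCoA uses
Gower double-centering and a symmetric eigendecomposition; negative
eigenvalues are reported but their axes dropped, and axis signs are fixed
by making the largest-magnitude loading positive. Heatmap export uses
log10(proportion + ε) with ε = smallest nonzero proportion / 10.

## Synthetic data: what it emulates, what it does not

`mocksim` generates a clade-structured strain set from a random 467 nt
core flanked by the real primer-binding sites: family ancestors at 8–12 %
substitution divergence from the core, one strain per genus at 3–5 % from
its family ancestor (so genus siblings sit ~6–10 % apart — comfortably
above the 3 % OTU radius). Primer-dropout strains get 3 substitutions
inside the forward primer site and fail the in-silico PCR (≤ 2 mismatches
per site). Classifier training data are separate ~1 % mutants of each
strain, so classification never sees its training sequences.

Reads carry substitutions at 0.1 %/base and indels at 0.001 %/base — the
MiSeq error structure the denoising stage is built around — plus optional
chimeras (two parents, one uniform crossover) and a constant base quality
of 38 (20 at errored bases). Quality scores are deliberately
uninformative: the pipeline never filters on them, so a realistic quality
model would add nothing testable. Not modeled: PCR efficiency bias (an
optional per-strain multiplier exists, off by default), polymerase batch
effects, optical artifacts, or real taxonomic databases. Passing tests
therefore demonstrate algorithmic correctness and quantitative recovery
under the stated error model — not robustness to real chemistry bias,
whose magnitude in the original data (deviations up to ~10 % per genus)
stems from wet-lab causes outside this package's scope.

The reagent-contaminant background defaults to 5 synthetic organisms in
distinct families at 3000 copies each. That load is an uncalibrated free
parameter (the true contaminant load of any reagent lot is unknown); the
default is chosen so the background is comparable to a mock at ~10³
copies per strain, placing the dilution-series crossover — where a
sample's profile collapses into the water-control cloud — between 10² and
10⁴ copies, the regime low-biomass chemistry exhibits. The
generalized-UniFrac background flag (alpha 0.6) uses a 0.2 distance
threshold, a qualitative default motivated by the wide separation between
genuine and background-dominated profiles; both are configurable.

## Evaluation conventions

Composition deviation is the per-taxon |measured − actual| in percentage
points over the union of taxa, with min/max/median summaries. Replicate
variability pools per-taxon pairwise absolute differences (in read %)
across replicates and reports their median; since a "standard error of a
median" has no standard definition, it is computed by seeded bootstrap
(1000 resamples). Pairwise (not vs-mean) differences are used.

## Problem sizes and determinism

The validation experiments run at depth 50,000 (even and staggered mocks)
and 3,000 per sample across six samples (dilution series); oracle
equivalence uses 100 seeded random instances per algorithm with 5–25
sequences or leaves each. These sizes give multinomial standard errors
well below the asserted tolerances (e.g. ~0.16 % per strain share at
depth 50,000 against a 1-percentage-point median bound). Every stochastic
component takes an explicit seed; repeated runs with the same seeds are
bit-identical.

## Known limitations

- The index-panel and candidate sets are deterministic but intentionally
  not identical to the historical sets (unpublished generation order).
- The template aligner is a general global aligner with a k-mer
  recruitment index, not a reimplementation of any specific aligner's
  database format; its scoring is a documented substitute.
- Chimera detection supports one crossover; multi-breakpoint chimeras are
  out of scope.
- Species-rank assignment is out of scope (short-read 16S cannot support
  it with confidence).
- UniFrac values depend on the representative tree; only comparisons made
  with the same tree are meaningful.
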