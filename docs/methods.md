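# Methods

## The cascade and its assumptions

The prioritization cascade is a deterministic filter chain over annotated
bi-allelic variant records. It assumes that annotation happened upstream
(VEP consequences on the canonical transcript, gnomAD v4 frequencies, CADD
v1.7, the eleven missense predictors, conservation tracks, MutPred2,
SpliceAI/MMSplice, gnomAD constraint metrics) and that each table row is
one bi-allelic variant×carrier-set record; multi-allelic decomposition is
the annotator's job. Coordinates are 1-based GRCh38; no liftover is
provided.

Criterion order is fixed (canonical → consequence class → frequency → CADD
→ segregation → branch rules). Rejection records the *first* failing
criterion; later criteria are still evaluated and stored in the trail
(verdict `not_applicable`, raw outcome in the inputs field) so that funnel
tallies remain auditable from the trail alone.

### Missing-data policy

Missingness is asymmetric by design:

* missing gnomAD frequency **passes** the frequency filter — absence from
  a database of ~800k exomes is itself evidence of rarity;
* missing CADD **fails** — a "top 1% deleterious" claim cannot be asserted
  without the score;
* missing genotype counts as **absent** in segregation (fail-closed; in
  family studies a false positive is costlier than a false negative);
* a missing canonical flag is `not_evaluable` and retains the variant
  (configurable to fail-closed via `Thresholds.canonical_fail_closed`);
* a missing last-exon flag retains the LoF variant with a warning;
* predictors with no call leave the vote's denominator entirely.

### Thresholds (defaults, with comparison strictness)

| parameter | default | comparison | unit/domain |
|---|---|---|---|
| `maf_max` | 0.001 | strict < | allele frequency |
| `cadd_min` | 20 | strict > | CADD PHRED |
| `vote_fraction` | 0.5 | strict > | credit fraction |
| `gerp_min` | 2.0 | strict > | GERP RS |
| `phastcons_min` | 0.3 | strict > | probability |
| `phylop_min` | 3.0 | inclusive ≥ | −log10 p |
| `conservation_min_positive` | 2 | ≥ | count of 3 |
| `mutpred_min` | 0.50 | inclusive ≥ | probability |
| `spliceai_confident` / `spliceai_high` | 0.5 / 0.8 | inclusive ≥ | Δ score |
| `mmsplice_medium` / `mmsplice_high` | 1.5 / 2.0 | strict > | \|score\| |
| `loeuf_max` | 0.6 | strict < | o/e upper bound |

Strictness at the boundaries is part of the contract and covered by tests:
CADD exactly 20 fails, a vote of exactly 50% fails, PhyloP exactly 3.0 is a
positive, MutPred2 exactly 0.50 is likely-pathogenic. MutPred2 inclusivity
was chosen because 0.50 is described as the *recommended* conservative
threshold, i.e. a score meeting it qualifies.

### Ensemble vote credits

Published prioritized-variant tables show half-point ensemble scores (6.5,
7.5, 10.5 of 11), implying partial credit, but no published definition of
it. We award 1 credit for a deleterious call, 0.5 for a tool's intermediate
category (e.g. PolyPhen-2 "possibly damaging", MutationAssessor "medium",
AlphaMissense "ambiguous"), 0 for benign, and exclude tools without a call
from the denominator. The token→category table ships in
`famprio.predictors` and is overridable per run.

### Segregation and trails

A family is *relevant* to a variant when at least one of its sequenced
members carries it; one trail is emitted per (variant, relevant family),
and a variant carried by nobody gets a single trail (family `None`) that
fails segregation. Multi-case families require presence in all sequenced
affected members; single-proband (double-primary) families reduce to
presence in the proband — with one sample no co-segregation evidence
exists, which is why those cohort rows rest entirely on the in-silico
filters.

## Network stage

Channel scores are combined by STRING's prior-corrected noisy-OR with
prior 0.041: each score is rescaled by `(s − p)/(1 − p)` (floored at 0),
combined as `1 − Π(1 − s′)`, and re-benchmarked by `c(1 − p) + p`. The
0.400 cut is inclusive ("minimum required score").

**PPI enrichment.** STRING's own calibration is not published in
reproducible detail, so two documented nulls are shipped instead, and the
package deliberately does not claim to reproduce STRING's printed
p-values. The default is a permutation null — `reps` uniform node sets of
the query's size, `p = (1 + #{draws ≥ observed}) / (reps + 1)` — which is
exactly valid by exchangeability but conservative under ties of the
integer edge count. The secondary `degree_poisson` null uses Chung–Lu pair
probabilities `min(k_i·k_j / 2m, 1)` summed into a Poisson mean; it is
degree-aware but approximate.

**MCL.** Dense-matrix Markov clustering: column-stochastic transition
matrix with self-loops at each node's maximum incident edge weight
(isolated nodes get 1.0 and come out as singletons), alternating expansion
(matrix power 2) and inflation (entrywise power 3.0, the STRING web
default, then column renormalization), pruning entries below 1e-5 but
never a column's maximum, stopping when the matrix changes by < 1e-6 or
at 100 iterations (non-convergence returns the current state with a
warning flag). Clusters are the connected components of the attractor
structure; each node joins the attractor holding its largest transition
mass, ties broken by lexicographic node order. Dense linear algebra is
appropriate because the clustered subgraphs here are the prioritized
protein sets (tens to a few hundred nodes), not whole interactomes.

**Gene-set enrichment** is the standard hypergeometric upper tail per GMT
term (terms intersected with the universe first) with Benjamini–Hochberg
step-up adjustment across tested terms. Note that BH *adjusted* values are
not idempotent as a transform (re-adjusting adjusted values inflates
them); the suite therefore checks order equivariance, `q ≥ p`, and
agreement with statsmodels instead.

## Synthetic data: what it emulates, what it does not

`simulate_cohort` emulates the *decision-relevant* structure of a familial
cohort: 22 families by default (15 multi-case with 2–4 sequenced
affecteds, 7 single-proband), ~200 background variants per sequenced
genome (Poisson), and 2 planted causal variants per family that are het in
every sequenced affected member. Declared score models:

* causal: CADD ~ U(20.1, 45); deleterious count ~ Binomial(11, 0.85);
  all-three-positive conservation with probability 0.9; AF = 0; LoF causal
  variants are never last-exon.
* background: CADD ~ N(10, 5) truncated at 0; deleterious count ~
  Binomial(11, 0.2); one AF draw shared by all three gnomAD fields, rare
  (U(0, 0.001)) with probability 0.4, otherwise common (U(0.001, 0.05));
  background variants are private to a single genome.

Sharing one AF draw across the three gnomAD columns keeps the frequency
filter's analytic pass probability exactly equal to the rare fraction, so
the background pass rate of the frequency+CADD+vote cascade has the closed
form `0.4 × Φ̄(2)/Φ̄(−2) × P(Bin(11, 0.2) ≥ 6) ≈ 1.1 × 10⁻⁴`, which the
end-to-end test checks within ±3 s.e.

The default causal model is intentionally *not* deterministic (a real
causal variant can fail an in-silico filter); the
`CohortSimParams.threshold_clearing()` preset (deleterious probability 1,
conservation probability 1) is the configuration under which 100% truth
recovery is a theorem, and is what the end-to-end tests and the acceptance
script use for the recall figure.

Not emulated: realistic kinship (pedigree topology is irrelevant to the
cascade — only affected/sequenced flags enter), linkage between variants,
annotation errors, batch effects between sequencing platforms, shared
background variants within families, and population structure in allele
frequencies. Passing tests therefore demonstrate the correctness of the
decision logic under the declared models, not performance on real
sequencing data.

`simulate_network` plants a partition: within-block edges (probability
0.8) carry channel scores high enough that > 95% survive the 0.400 filter;
between-block edges (probability 0.05) carry U(0, 0.35) channels and
mostly fall below it. `synthetic_prioritized_table` is a *deterministic,
labelled-synthetic* stand-in for a cohort-scale prioritized table: it
realizes configured margins exactly (per-family row counts, class-by-mode
totals, recurrence counts) with placeholder gene symbols, so the tally
stage can be validated against known totals; it is not a simulation of the
cascade.

## Problem sizes and numerical choices in the suite

The suite and the acceptance script run on one CPU in well under a minute
each: the end-to-end cohort is ~10,000 variant rows (22 families); MCL
recovery uses two 15-node blocks; the permutation-null calibration uses
500 trials at 199 reps on a 120-node Erdős–Rényi graph with query size 15
(chosen so the null edge-count distribution has enough spread that tie
conservatism stays small); the vote oracle recounts 10,000 random call
mappings. Hypothesis tests run derandomized with 50 examples.

## Known limitations

* The cascade consumes annotations; inconsistencies between them (e.g. a
  consequence term contradicting HGVS) are resolved by the consequence
  term first, HGVSc offset second.
* The permutation PPI p-value is conservative for very small queries on
  sparse graphs (heavily tied integer statistic).
* MCL is dense (O(n³) per iteration); for graphs beyond a few thousand
  nodes a sparse implementation would be needed.
* Fractional vote credits are a documented convention, not a published
  standard; override the mapping if your upstream annotator differs.
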