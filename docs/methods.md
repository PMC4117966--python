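# Methods

## Model

`hporank` scores a gene `g` against a patient term set
`P = {p_1, …, p_K}` drawn from a rooted is-a ontology. Specificity of a
term is its Resnik information content `IC(p) = -ln(n_p / N)`, where `N`
is the number of annotated genes and `n_p` the number of genes annotated
by `p` directly or through any descendant (true-path propagation).
Natural-log units are used throughout; the root has IC 0 and IC never
increases along child→ancestor edges.

Termwise similarity is the IC of the most informative *common* ancestor:
the candidate set is the intersection of the two terms' proper ancestor
sets, excluding the terms themselves unless they are equal. Thus
`sim(t, t) = IC(t)`, while the similarity of a parent to its own child
looks past the parent (the candidate set is the parent's ancestors).
Two terms whose only shared ancestor is the root score 0.

Term-set similarity is the best-match average. The asymmetric direction
averages each query term's best match in the target; the symmetric form
averages both directions. Gene scoring defaults to the asymmetric
direction with the patient as query and the gene's **direct** annotation
set as target; the symmetric form is available behind a keyword. Scoring
against the propagated annotation closure would let every shared
ancestor self-match and inflate all scores uniformly — the MICA already
accounts for ancestry — so the direct set is the correct target.

### Ranking and ties

Score ranking sorts descending; a block of `m` equal scores occupying
sorted positions `i…i+m-1` all receive `floor(mean) = i + (m-1)//2`, and
positions after the block resume sequentially. P-value ranking sorts
ascending; genes sharing a p-value are ordered within the block by
descending score (the gene in within-block score position `s_r` takes
rank `i-1+s_r`); genes identical in both p-value and score fall back to
the floored-mean rule. Output order within residual ties is
lexicographic by gene identifier so results are reproducible; scores are
rounded to 1e-9 before tie detection so mathematically equal scores that
differ in the last float ulp form one block.

### Null model and p-values

For each gene and each query length `K` in 1…10 the null is the score
distribution over random query sets drawn uniformly (without
replacement, unweighted) from the annotated-term universe — the terms
with defined IC. `K = 1` is enumerated exhaustively; `K ≥ 2` uses
Monte-Carlo samples (`M` = 100,000 at full fidelity, 10,000 in the desk
runs here — the Monte-Carlo error on a CDF value at M = 10,000 is below
0.005, well under any decision threshold in the evaluation). Query
lengths above 10 reuse the `K = 10` table. The one-sided p-value of an
observed score `s` is the fraction of null samples `≥ s`, floored at
`1/(M+1)` so p-value ranking never divides by an exact zero. Scores are
quantized to 1e-6 for storage and lookup — far below any meaningful IC
difference — so tables compress to score→count histograms in a single
tab-delimited archive whose header records M, seed and the universe.
Each (gene, K) pair draws from a dedicated random stream keyed by the
seed, a hash of the gene identifier and K, so a table is reproducible
regardless of which other genes are built in the same call.

P-value calibration note: against a small universe the null score
distribution is discrete with sizeable atoms, so null p-values are
*superuniform* — `P(p ≤ α) ≤ α` with equality at achievable levels —
rather than exactly U(0,1). The calibration tests assert exactly that
(empirical CDF equal to the nominal level at every achievable p-value,
never above it in between); a naive two-sided KS statistic against the
continuous uniform would be dominated by the largest atom and is not a
meaningful check at toy scale.

## Patient simulation

A disease model is a causative gene plus phenotype terms that directly
annotate it, each with penetrance `f_p ∈ (0, 1]` and an optional sex
restriction. Per patient: sex is drawn first (uniform; male when the
draw exceeds 0.5); each phenotype is admitted independently with
probability `f_p`, skipping sex-conflicting terms; the whole patient is
resampled (up to 1,000 attempts) until at least one term is present,
which preserves the relative penetrance structure instead of forcing an
arbitrary term. Corruption scenarios:

- **noise** — `floor(n_optimal / 2)` terms drawn uniformly without
  replacement from the universe terms that do not annotate the causative
  gene directly or indirectly. Floor is used for odd counts (the halving
  rule's even worked cases do not disambiguate; floor never exceeds
  half).
- **imprecision** — every optimal term replaced by a uniformly chosen
  proper ancestor other than the root; terms whose only proper ancestor
  is the root are kept unchanged (the replacement rule is undefined
  there); colliding replacements collapse because term sets are sets.
- **imprecision+noise** — the imprecision terms plus the *same* noise
  terms drawn for that base patient's noise row, so scenario contrasts
  are paired within a patient.

Replacing a term by an ancestor can only lower that term's best-match
contribution against the causative gene (IC is anti-monotone up the
DAG) — this per-term bound is the mechanism behind imprecision
degradation and is what the property tests assert. The *mean* score can
in rare corner cases rise when two replacements collide and a low-IC
term drops out of the average; this is a consequence of the set-collapse
rule, not of the similarity model.

The evaluation harness records, per patient, the causative gene's rank
under both ranking modes plus three covariates: `S`, the asymmetric
similarity of the actual (corrupted) terms to the optimal terms
normalized by the optimal set's self-similarity (1 for optimal patients;
clipped at 1 because a noise term that best-matches only the high-IC
optimal terms can push the raw ratio marginally above 1); the maximum IC
among the patient's terms; and the term count. Summaries are the
empirical rank CDF (median = lower median, keeping ranks integral),
per-scenario tables, and binned stratifications over `S`, max IC or term
count, with empty bins reported as missing rather than zero.

## Synthetic data

No real ontology or annotation corpus ships with the package; the
fixture generators build them to order, and the study preset emulates
the cohort conditions of the HPO-based simulation study this package
reproduces:

- ontology: 600 terms in a layered rooted DAG (depth ≤ 8, second parent
  with probability 0.3), of which ~587 end up annotating ≥ 1 gene — the
  annotated-term universe, mirroring how only a subset of a real
  ontology's terms carry annotations;
- genes: 150, direct annotation counts Poisson with mean 24.8 (the
  corpus-wide average of a real gene-phenotype release), terms sampled
  with weight ∝ depth², mimicking curation toward specific terms;
- diseases: 33, one causative gene each; per-disease annotation counts
  `round(N(19.7, 9))` clipped to [6, 50]; phenotypes are a subset of the
  causative gene's direct annotations (the gene receives a few extra
  annotations so the disease set is usually a strict subset);
- penetrance: Beta(2, 2.7), mean ≈ 0.43, chosen once so that the
  across-scenario mean patient term count lands near the reported cohort
  mean of ~9.4 given floor-halved noise counts and imprecision
  de-duplication; 2% of phenotypes carry a sex restriction.

What the synthetic corpus does *not* emulate: the clustered annotation
structure of real gene-phenotype corpora, where disease families share
large term blocks. Independent random annotation understates gene-gene
term overlap, so absolute ranks are easier than against a real corpus of
2,488 genes — the scaled study's optimal/noise ranked-first fractions
run higher than a real-data run's, the imprecision medians are not
comparable in absolute terms across universes of different size, and
p-value ranking (which mostly resolves score ties here) shows less
degradation than under real annotation bias. Passing tests demonstrate
the algorithmic contracts and the qualitative scenario ordering, not
real-HPO performance figures.

## Problem sizes and numerical choices

The test suite runs the cohort study at 33 diseases × 20 patients × 4
scenarios with M = 10,000 null samples (a desk-scale run of the same
design as the 100-patient acceptance script, which takes under a
minute); oracle-equivalence checks use ontologies of ≤ 50 terms where
brute-force recomputation is instant, and Monte-Carlo calibration uses a
12-term universe where all 220 3-subsets can be enumerated. Degenerate
inputs are rejected loudly: empty term sets, empty gene universes,
unresolvable terms (dropped with a warning before scoring; an error only
if nothing survives), unannotated genes (reported as unrankable),
zero-effective-penetrance diseases, noise pools smaller than the
requested draw. Cycles and ambiguous roots are fatal ontology errors
naming the offending edge.
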