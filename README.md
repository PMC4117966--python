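# hporank

Phenotype-driven gene prioritization by ontology semantic similarity,
with Monte-Carlo empirical p-values and a simulated-patient evaluation
harness.

## The problem

After exome or genome sequencing, a rare-disease patient typically
carries damaging-looking variants in dozens to hundreds of genes, and
each gene must be assessed against the patient's clinical presentation.
`hporank` automates that assessment: given a set of phenotype terms
describing the patient — e.g. Human Phenotype Ontology (HPO) terms
chosen by a clinician — it ranks any gene list by the semantic
similarity between the patient's terms and the phenotype terms annotated
to each gene. It is aimed at clinical-genomics analysts who want a
phenotype rank to combine with variant-level filters (the variant filter
hands over a gene subset; `hporank` re-ranks within it).

## The model

Terms live in a rooted is-a DAG. With `N` annotated genes and `n_p`
the number of genes a term `p` annotates directly or through any
descendant (the true-path rule), a term's specificity is its Resnik
information content:

    IC(p) = -ln(n_p / N)

The similarity of two terms is the IC of their most informative common
ancestor (MICA); a term set `P1` is compared to `P2` by the best-match
average

    sim(P1 -> P2) = (1/|P1|) * sum_{p in P1} max_{q in P2} IC(MICA(p, q))

and a gene's score against a patient is this asymmetric form with the
patient as query and the gene's direct annotations as target. Genes are
ranked by descending score, tied blocks receiving the floored mean of
their sorted positions.

Because heavily annotated genes reach high scores against random
queries more easily (annotation bias), each score can also be referred
to a per-gene, per-query-length null distribution built by Monte-Carlo
sampling of random query sets from the annotated-term universe; genes
are then ranked by the one-sided empirical p-value `P(null >= s)`,
p-value ties broken by score. Query lengths above 10 reuse the K = 10
tables; for K = 1 the universe is enumerated exactly.

The simulator generates patient cohorts from disease penetrance tables
under four scenarios: **optimal** (each disease phenotype admitted with
probability equal to its penetrance), **noise** (plus half as many terms
unrelated to the causative gene), **imprecision** (each term replaced by
a random non-root ancestor), and **imprecision+noise**.

## Worked example

Everything is driven either from Python (`hporank.*`) or the `hporank`
command. A self-contained run on a synthetic fixture:

```
hporank fixture --terms 40 --genes 12 --diseases 3 --seed 5 --out-dir demo
hporank build-null --obo demo/ontology.obo --annotations demo/annotations.tsv \
    --samples 5000 --seed 7 --out demo/null.tsv
# patient presentation: three terms of the first simulated disease
awk -F'\t' '$1=="OMIM:600000"{print $3}' demo/diseases.tsv | head -3 > demo/patient.txt
hporank rank --obo demo/ontology.obo --annotations demo/annotations.tsv \
    --patient demo/patient.txt --null demo/null.tsv --by pvalue
```

prints (first rows):

```
gene    score     p_value  rank
GENE0001  2.022809  0.0002   1
GENE0012  0.753921  0.0124   2
GENE0003  0.557992  0.046    3
GENE0004  0.557992  0.1      4
GENE0011  0.924196  0.1728   5
```

`GENE0001` — the disease's causative gene, whose annotations contain
all three patient terms — is ranked first with a mean per-term IC of
2.02 nats and an empirical p-value at 1/M resolution. Note `GENE0011`:
its raw score (0.92) beats genes ranked 2–4, but it carries many
annotations, so a score that high arises easily by chance and its
p-value demotes it — the annotation-bias correction at work. Ranking
by `--by score` instead orders genes 1, 11, 12, … directly by score.

The same pipeline at study scale, from Python:

```python
from hporank import *
from hporank.fixtures import make_study_fixture

ontology, index, diseases = make_study_fixture(seed=1)
cohort = build_cohort(diseases, ontology, index, n_per_disease=100, seed=2)
store = build_null_tables(index, M=10_000, seed=3)
results = evaluate_cohort(cohort, index, store)
print(summarize(results))
```

`summarize` reports, per scenario and ranking mode, the median and mean
causative-gene rank and the fraction of patients whose causative gene
lands in the top 1/10/20/100 — the cumulative-distribution view of
ranking performance.

## Limitations

The method is knowledge-based: a gene without phenotype annotations
cannot be ranked at all (such genes are reported as unrankable, never
silently dropped), and performance degrades when patient terms are less
specific than the gene's annotations — imprecision hurts far more than
unrelated noise. No multiple-testing correction is applied to the
per-gene p-values; they are a ranking statistic, not calibrated
significance tests across the genome.
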