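"""Synthetic ontologies, annotation sets and disease tables.

The generators emulate the structural features of a phenotype ontology
and its gene annotation corpus that drive the method: a rooted layered
is-a DAG (occasionally with multiple parents), direct gene annotation
biased toward specific (deep) terms, and single-gene diseases whose
phenotype terms are drawn from the causative gene's direct annotations
with per-term penetrance.

Two presets are provided.  ``make_toy_fixture`` builds desk-size inputs
for unit tests and examples.  ``make_study_fixture`` builds a scaled
cohort-study configuration: 33 single-gene diseases whose annotation
counts are approximately normal with mean 19.7 over the range 6-50, and
penetrance values drawn so that simulated patients average roughly nine
terms across the four corruption scenarios — the cohort profile of the
HPO-based simulation study this package reproduces.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from hporank.annotations import AnnotationIndex
from hporank.ontology import Ontology, Term
from hporank.simulate import DiseaseModel, DiseasePhenotype


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def random_ontology(
    n_terms: int,
    seed: int | np.random.Generator = 0,
    n_levels: int | None = None,
    p_second_parent: float = 0.3,
) -> Ontology:
    """Random rooted is-a DAG with a layered structure.

    Terms are organized in levels under a single root; each non-root term
    has one parent in the level above and, with probability
    ``p_second_parent``, a second parent (making a DAG rather than a
    tree).  Deterministic per seed.
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms (root plus two descendants)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_levels is None:
        n_levels = max(2, min(8, int(math.log2(n_terms))))

    levels: dict[str, int] = {_term_id(1): 0}
    by_level: dict[int, list[str]] = {0: [_term_id(1)]}
    terms: dict[str, Term] = {_term_id(1): Term(id=_term_id(1), name="synthetic root")}

    level_weights = np.array([2.0**lv for lv in range(1, n_levels + 1)])
    level_weights /= level_weights.sum()

    for i in range(2, n_terms + 1):
        tid = _term_id(i)
        if i - 1 <= n_levels:
            lv = i - 1  # guarantee every level is populated
        else:
            lv = 1 + int(rng.choice(n_levels, p=level_weights))
        pool = by_level.get(lv - 1) or [_term_id(1)]
        parents = {pool[int(rng.integers(0, len(pool)))]}
        if len(pool) > 1 and rng.random() < p_second_parent:
            parents.add(pool[int(rng.integers(0, len(pool)))])
        terms[tid] = Term(
            id=tid, name=f"synthetic term {i}", parents=frozenset(parents)
        )
        levels[tid] = lv
        by_level.setdefault(lv, []).append(tid)

    return Ontology(terms)


def _depths(ontology: Ontology) -> dict[str, int]:
    """Longest path length from the root for every term."""
    depth: dict[str, int] = {ontology.root: 0}
    pending = sorted(
        (t for t in ontology.terms if t != ontology.root),
        key=lambda t: len(ontology.ancestors(t)),
    )
    for t in pending:
        depth[t] = 1 + max(depth[p] for p in ontology.terms[t].parents)
    return depth


def random_annotations(
    ontology: Ontology,
    n_genes: int,
    rng: np.random.Generator,
    mean_terms: float = 8.0,
    fixed_counts: Sequence[int] | None = None,
) -> dict[str, set[str]]:
    """Assign direct annotations to genes, biased toward specific terms.

    Terms are drawn without replacement with probability proportional to
    depth squared, mimicking curation toward specific phenotype terms.
    ``fixed_counts`` pins the annotation count of the first genes (used
    to guarantee causative genes can carry their disease's phenotypes);
    remaining genes draw a Poisson count with the given mean, floored at
    one so every gene is annotated.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    depth = _depths(ontology)
    candidates = [t for t in sorted(ontology.terms) if t != ontology.root]
    weights = np.array([float(depth[t] ** 2) for t in candidates])
    weights /= weights.sum()
    direct: dict[str, set[str]] = {}
    fixed = list(fixed_counts or [])
    for gi in range(n_genes):
        gene = f"GENE{gi + 1:04d}"
        if gi < len(fixed):
            count = fixed[gi]
        else:
            count = max(1, int(rng.poisson(mean_terms)))
        count = min(count, len(candidates))
        chosen = rng.choice(len(candidates), size=count, replace=False, p=weights)
        direct[gene] = {candidates[i] for i in chosen}
    return direct


def random_disease_table(
    index: AnnotationIndex,
    causative_genes: Sequence[str],
    counts: Sequence[int],
    rng: np.random.Generator,
    penetrance_beta: tuple[float, float] = (2.0, 2.7),
    gender_restricted_rate: float = 0.02,
) -> list[DiseaseModel]:
    """One disease per causative gene, phenotypes drawn from its annotations."""
    models: list[DiseaseModel] = []
    for di, (gene, count) in enumerate(zip(causative_genes, counts)):
        annotations = sorted(index.direct[gene])
        if count > len(annotations):
            raise ValueError(
                f"gene {gene} has {len(annotations)} annotations, "
                f"cannot host a {count}-phenotype disease"
            )
        chosen = rng.choice(len(annotations), size=count, replace=False)
        phenotypes = []
        for ti in sorted(chosen):
            pen = float(rng.beta(*penetrance_beta))
            pen = min(max(pen, 0.01), 1.0)
            gender = "none"
            if rng.random() < gender_restricted_rate:
                gender = "male" if rng.random() > 0.5 else "female"
            phenotypes.append(
                DiseasePhenotype(
                    term=annotations[ti], penetrance=pen, gender_restriction=gender
                )
            )
        models.append(
            DiseaseModel(
                omim_id=f"OMIM:{600000 + di}",
                causative_gene=gene,
                phenotypes=tuple(phenotypes),
            )
        )
    return models


def make_toy_fixture(
    n_terms: int = 30,
    n_genes: int = 10,
    seed: int = 0,
    n_diseases: int = 3,
    mean_terms: float = 5.0,
) -> tuple[Ontology, AnnotationIndex, list[DiseaseModel]]:
    """Desk-size ontology + annotations + diseases for tests and examples.

    Every gene carries at least one term and every disease term directly
    annotates its causative gene; the returned index satisfies all
    annotation-store invariants by construction.  Deterministic per seed.
    """
    if n_diseases > n_genes:
        raise ValueError("cannot have more diseases than genes")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    ontology = random_ontology(n_terms, rng)
    max_count = max(2, min(n_terms // 3, int(2 * mean_terms)))
    counts = [int(rng.integers(2, max_count + 1)) for _ in range(n_diseases)]
    direct = random_annotations(
        ontology, n_genes, rng, mean_terms=mean_terms, fixed_counts=counts
    )
    index = AnnotationIndex(ontology, direct)
    genes = index.genes[:n_diseases]
    disease_counts = [
        min(counts[i], len(index.direct[genes[i]])) for i in range(n_diseases)
    ]
    models = random_disease_table(index, genes, disease_counts, rng)
    return ontology, index, models


def make_study_fixture(
    seed: int = 0,
    n_terms: int = 600,
    n_genes: int = 150,
    n_diseases: int = 33,
    annotation_count_mean: float = 19.7,
    annotation_count_sd: float = 9.0,
    annotation_count_range: tuple[int, int] = (6, 50),
    gene_mean_terms: float = 24.8,
    penetrance_beta: tuple[float, float] = (2.0, 2.7),
) -> tuple[Ontology, AnnotationIndex, list[DiseaseModel]]:
    """Scaled synthetic configuration of the simulated cohort study.

    Thirty-three single-causative-gene diseases with per-disease
    annotation counts drawn from a clipped normal (mean 19.7, range
    6-50); non-causative genes carry Poisson-distributed annotation
    counts matching the corpus-wide average of ~25 direct annotations
    per gene; penetrance is Beta-distributed with mean ~0.43 so that
    patient term counts across the four scenarios average roughly nine.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    ontology = random_ontology(n_terms, rng)
    lo, hi = annotation_count_range
    disease_counts = [
        int(np.clip(round(rng.normal(annotation_count_mean, annotation_count_sd)), lo, hi))
        for _ in range(n_diseases)
    ]
    # causative genes must hold at least the disease's terms; give them a
    # few extra annotations so disease terms are a strict subset sometimes
    causative_totals = [c + int(rng.poisson(5.0)) for c in disease_counts]
    direct = random_annotations(
        ontology,
        n_genes,
        rng,
        mean_terms=gene_mean_terms,
        fixed_counts=causative_totals,
    )
    index = AnnotationIndex(ontology, direct)
    causative = [f"GENE{i + 1:04d}" for i in range(n_diseases)]
    models = random_disease_table(
        index, causative, disease_counts, rng, penetrance_beta=penetrance_beta
    )
    for m in models:
        m.validate(index)
    return ontology, index, models
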