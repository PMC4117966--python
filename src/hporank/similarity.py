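"""Termwise and term-set semantic similarity, and the patient-vs-gene score.

The similarity of two terms is the information content of their most
informative common ancestor (MICA), after Resnik.  The common-ancestor set
excludes the terms themselves unless the two terms are equal, so
``sim(t, t) == IC(t)`` while for distinct terms the MICA is a strictly
proper common ancestor.

Two term sets are compared with a best-match average.  The asymmetric form
averages, over each query term, its best termwise match in the target:

    sim(P1 -> P2) = (1/|P1|) * sum_{p in P1} max_{q in P2} sim(p, q)

and the symmetric form is the mean of the two directions.  A gene is
scored against a patient with the asymmetric form, patient as query and
the gene's *direct* annotation set as target — the MICA already accounts
for ancestry, so scoring against the propagated closure would only add
self-matches on every shared ancestor and inflate all scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from hporank.annotations import AnnotationIndex


class EmptyTermSetError(ValueError):
    """Raised when a scoring call receives an empty term set."""


class UnrankableGeneError(KeyError):
    """Raised when a score is requested for a gene without annotations."""


@dataclass(frozen=True)
class TermSet:
    """A labelled set of ontology term accessions (a patient or a gene)."""

    terms: frozenset[str]
    label: str = ""

    def __init__(self, terms: Iterable[str], label: str = "") -> None:
        object.__setattr__(self, "terms", frozenset(terms))
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def _as_terms(term_set: TermSet | Iterable[str]) -> frozenset[str]:
    if isinstance(term_set, TermSet):
        return term_set.terms
    return frozenset(term_set)


def term_similarity(index: AnnotationIndex, p1: str, p2: str) -> float:
    """IC of the most informative common ancestor of two terms.

    Symmetric in its arguments.  ``p1`` and ``p2`` are excluded from the
    candidate ancestor set unless equal, so ``term_similarity(t, t)``
    equals ``IC(t)`` but the similarity of a parent to its child looks
    past the parent itself.  Terms whose only shared ancestor is the root
    score 0 (the root's IC).
    """
    ont = index.ontology
    t1, t2 = ont.resolve(p1), ont.resolve(p2)
    if t1 == t2:
        return index.information_content(t1)
    common = ont.ancestors(t1) & ont.ancestors(t2)
    if not common:
        return 0.0
    return max(index.ic.get(a, 0.0) for a in common)


def set_similarity_asymmetric(
    index: AnnotationIndex,
    query: TermSet | Iterable[str],
    target: TermSet | Iterable[str],
) -> float:
    """Best-match average of query terms against a target set (directed)."""
    q = _as_terms(query)
    t = _as_terms(target)
    if not q or not t:
        raise EmptyTermSetError("empty term set")
    return sum(max(term_similarity(index, p, g) for g in t) for p in q) / len(q)


def set_similarity_symmetric(
    index: AnnotationIndex,
    P1: TermSet | Iterable[str],
    P2: TermSet | Iterable[str],
) -> float:
    """Mean of the two asymmetric directions; invariant under swap."""
    return 0.5 * (
        set_similarity_asymmetric(index, P1, P2)
        + set_similarity_asymmetric(index, P2, P1)
    )


def gene_score(
    index: AnnotationIndex,
    patient: TermSet | Iterable[str],
    gene: str,
    symmetric: bool = False,
) -> float:
    """Similarity score of a gene against a patient term set.

    The default is the asymmetric direction with the patient as query and
    the gene's direct annotations as target; pass ``symmetric=True`` for
    the averaged two-direction form.  Higher scores indicate a stronger
    predicted relation.  Genes without annotations cannot be scored.
    """
    if gene not in index.direct:
        raise UnrankableGeneError(
            f"gene {gene!r} has no annotations and cannot be ranked"
        )
    target = index.direct[gene]
    if symmetric:
        return set_similarity_symmetric(index, patient, target)
    return set_similarity_asymmetric(index, patient, target)


class SimilarityKernel:
    """Vectorized best-match scoring over the annotated-term universe.

    Precomputes, per gene, the best termwise similarity from every
    universe term to the gene's direct annotation set:

        best_g[q] = max_{t in direct(g)} sim(q, t)

    so a gene score is just the mean of ``best_g`` over the patient's
    term indices.  This is the workhorse behind Monte-Carlo null-table
    construction and cohort evaluation; it is numerically identical to
    the set-based functions above (asymmetric, patient-as-query).
    """

    def __init__(self, index: AnnotationIndex) -> None:
        self.index = index
        self.terms: list[str] = list(index.universe)
        self.term_index: dict[str, int] = {t: i for i, t in enumerate(self.terms)}
        n = len(self.terms)
        self.ic_vector = np.array([index.ic[t] for t in self.terms])
        # anc[i, j] == True iff term j is a *proper* ancestor of term i.
        # Ancestors of universe terms are themselves in the universe
        # (propagated counts are monotone up the DAG).
        self.anc = np.zeros((n, n), dtype=bool)
        for i, t in enumerate(self.terms):
            for a in index.ontology.ancestors(t):
                self.anc[i, self.term_index[a]] = True
        self._best: dict[str, np.ndarray] = {}

    def term_indices(self, terms: Iterable[str]) -> np.ndarray:
        return np.array([self.term_index[t] for t in terms], dtype=np.intp)

    def best_match(self, gene: str) -> np.ndarray:
        """Vector of best termwise similarities to ``gene`` per universe term."""
        cached = self._best.get(gene)
        if cached is not None:
            return cached
        if gene not in self.index.direct:
            raise UnrankableGeneError(
                f"gene {gene!r} has no annotations and cannot be ranked"
            )
        target = self.index.direct[gene]
        target_idx = self.term_indices(target)
        # Union of proper ancestors over the target set: a common ancestor
        # of query q and any target term is an ancestor of q present here.
        anc_any = self.anc[target_idx].any(axis=0)
        cols = np.flatnonzero(anc_any)
        if cols.size:
            best = np.max(
                np.where(self.anc[:, cols], self.ic_vector[cols], 0.0), axis=1
            )
        else:
            best = np.zeros(len(self.terms))
        # Exact matches: a query term inside the target set matches itself.
        best[target_idx] = np.maximum(best[target_idx], self.ic_vector[target_idx])
        self._best[gene] = best
        return best

    def gene_score(self, patient_terms: Sequence[str] | np.ndarray, gene: str) -> float:
        """Asymmetric patient-vs-gene score (mean best match)."""
        idx = (
            patient_terms
            if isinstance(patient_terms, np.ndarray)
            else self.term_indices(patient_terms)
        )
        if idx.size == 0:
            raise EmptyTermSetError("empty term set")
        return float(self.best_match(gene)[idx].mean())

    def score_queries(self, gene: str, queries: np.ndarray) -> np.ndarray:
        """Scores for a batch of queries given as an (M, K) index array."""
        return self.best_match(gene)[queries].mean(axis=1)
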