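"""Gene-to-phenotype annotations, true-path propagation and information content.

A gene directly annotated with a term is implicitly annotated with every
ancestor of that term (the true-path rule).  The information content of a
term ``t`` is

    IC(t) = -ln( n_t / N )

where ``N`` is the number of annotated genes and ``n_t`` the number of
genes ``t`` annotates directly or via any descendant.  Natural-log units
are used throughout, so with N = 2,488 annotated genes the most specific
possible term (annotating a single gene) has IC = ln 2488 ~ 7.8.
"""

from __future__ import annotations

import logging
import math
from typing import IO, Iterable, Mapping

from hporank.ontology import Ontology

logger = logging.getLogger(__name__)


class UnannotatedTermError(KeyError):
    """Raised when IC is requested for a term that annotates no gene."""


class AnnotationIndex:
    """Gene/term annotation maps with propagated counts and IC values.

    Attributes
    ----------
    ontology : Ontology
    direct : dict[str, frozenset[str]]
        Gene -> directly annotated terms (primary accessions).
    propagated : dict[str, frozenset[str]]
        Term -> genes annotated directly or through any descendant.
    N : int
        Number of annotated genes (genes with >= 1 valid direct term).
    n_p : dict[str, int]
        Term -> propagated gene count; defined only on the annotated-term
        universe.
    ic : dict[str, float]
        Term -> information content in natural-log units; ``ic[root] == 0``.
    universe : list[str]
        Sorted accessions of terms annotating >= 1 gene (directly or
        indirectly).  This is the query/sampling universe; terms outside
        it have undefined IC.
    """

    def __init__(self, ontology: Ontology, direct: Mapping[str, Iterable[str]]):
        self.ontology = ontology
        self.direct: dict[str, frozenset[str]] = {}
        propagated: dict[str, set[str]] = {}
        for gene in sorted(direct):
            terms = frozenset(ontology.resolve(t) for t in direct[gene])
            if not terms:
                continue
            self.direct[gene] = terms
            for t in terms:
                for anc in ontology.ancestors_or_self(t):
                    propagated.setdefault(anc, set()).add(gene)

        if not self.direct:
            raise ValueError("annotation set is empty: no gene has a valid term")

        self.propagated: dict[str, frozenset[str]] = {
            t: frozenset(g) for t, g in propagated.items()
        }
        self.N: int = len(self.direct)
        self.n_p: dict[str, int] = {t: len(g) for t, g in self.propagated.items()}
        self.ic: dict[str, float] = {
            t: -math.log(n / self.N) for t, n in self.n_p.items()
        }
        self.ic[ontology.root] = 0.0  # n_p(root) == N exactly
        self.universe: list[str] = sorted(self.n_p)

    # -- queries -----------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        """Sorted identifiers of all annotated genes."""
        return sorted(self.direct)

    def information_content(self, term: str) -> float:
        tid = self.ontology.resolve(term)
        try:
            return self.ic[tid]
        except KeyError:
            raise UnannotatedTermError(
                f"term {tid!r} annotates no gene; its information content is undefined"
            ) from None

    def has_ic(self, term: str) -> bool:
        try:
            tid = self.ontology.resolve(term)
        except KeyError:
            return False
        return tid in self.ic

    def filter_terms(self, terms: Iterable[str], label: str = "input") -> list[str]:
        """Resolve terms, dropping (with a warning) any with undefined IC.

        Obsolete terms and terms outside the annotated universe cannot be
        scored; they are removed here rather than poisoning a scoring call.
        """
        kept: list[str] = []
        dropped: list[str] = []
        for t in terms:
            try:
                tid = self.ontology.resolve(t)
            except KeyError:
                dropped.append(t)
                continue
            if self.ontology.is_obsolete(tid) or tid not in self.ic:
                dropped.append(t)
            else:
                kept.append(tid)
        if dropped:
            logger.warning(
                "%s: dropped %d term(s) with undefined IC: %s",
                label,
                len(dropped),
                ", ".join(dropped[:10]),
            )
        return kept


def information_content(index: AnnotationIndex, term: str) -> float:
    """IC of a term: ``-ln(n_p(term) / N)``; raises for unannotated terms."""
    return index.information_content(term)


def load_annotations(
    gene2pheno_source: str | IO[str],
    ontology: Ontology,
    gene_column: int = 0,
    term_column: int = 1,
    sep: str = "\t",
) -> AnnotationIndex:
    """Read a tab-delimited gene-to-phenotype table into an index.

    One (gene identifier, term accession) pair per row; lines starting
    with ``#`` are skipped.  The column positions default to
    ``gene<TAB>term`` but are configurable to accommodate release
    dialects of the HPO ``genes_to_phenotype`` file (e.g. entrez-id,
    symbol, term-name, term-id layouts).

    Records whose term does not resolve in the ontology (even via alt_id)
    or is obsolete are skipped with one aggregate warning.  Genes left
    with zero valid terms are excluded from ``N``.
    """
    if isinstance(gene2pheno_source, str):
        with open(gene2pheno_source) as fh:
            return load_annotations(fh, ontology, gene_column, term_column, sep)

    direct: dict[str, set[str]] = {}
    skipped = 0
    ncols = max(gene_column, term_column) + 1
    for line in gene2pheno_source:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split(sep)
        if len(fields) < ncols:
            skipped += 1
            continue
        gene = fields[gene_column].strip()
        term = fields[term_column].strip()
        if not gene or not term:
            skipped += 1
            continue
        try:
            tid = ontology.resolve(term)
        except KeyError:
            skipped += 1
            continue
        if ontology.is_obsolete(tid):
            skipped += 1
            continue
        direct.setdefault(gene, set()).add(tid)

    if skipped:
        logger.warning("skipped %d annotation record(s) with unresolvable terms", skipped)

    empty = [g for g, ts in direct.items() if not ts]
    for g in empty:
        del direct[g]
    return AnnotationIndex(ontology, direct)
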