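"""Tie-resolved gene rankings by similarity score or by p-value.

Ranking by score sorts genes in descending score order; a block of m
genes sharing a score at sorted positions {i, ..., i+m-1} all receive the
rank floor(mean position) = i + (m-1)//2, and positions after the block
resume sequentially (competition-style positions feed the mean).

Ranking by p-value sorts ascending; genes sharing a p-value are ordered
among themselves by descending similarity score, the gene in within-tie
score position s_r taking rank i - 1 + s_r.  Genes identical in both
p-value and score fall back to the floored-mean-position rule.  Exact
(p, score) duplicates are listed in lexicographic gene order so output is
reproducible.

Genes without any annotation cannot be scored; they are reported in the
ranking's ``unrankable`` list rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from hporank.annotations import AnnotationIndex
from hporank.nullmodel import NullTableStore
from hporank.similarity import EmptyTermSetError, SimilarityKernel, TermSet, _as_terms


@dataclass(frozen=True)
class RankEntry:
    gene: str
    score: float
    rank: int
    p_value: float | None = None


@dataclass
class GeneRanking:
    """An ordered gene ranking plus the genes that could not be ranked."""

    entries: list[RankEntry]
    universe_size: int
    unrankable: list[str] = field(default_factory=list)
    by: str = "score"

    def rank_of(self, gene: str) -> int:
        for e in self.entries:
            if e.gene == gene:
                return e.rank
        raise KeyError(f"gene {gene!r} not in ranking")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def write_tsv(self, path_or_file: str | IO[str]) -> None:
        if isinstance(path_or_file, str):
            with open(path_or_file, "w") as fh:
                self.write_tsv(fh)
            return
        fh = path_or_file
        fh.write("gene\tscore\tp_value\trank\n")
        for e in self.entries:
            p = "" if e.p_value is None else f"{e.p_value:.6g}"
            fh.write(f"{e.gene}\t{e.score:.6f}\t{p}\t{e.rank}\n")
        for gene in self.unrankable:
            fh.write(f"{gene}\tNA\tNA\tunrankable\n")


def tied_ranks(sort_keys: Sequence[tuple], labels: Sequence[str]) -> list[tuple[int, int]]:
    """Order items by their sort keys and assign tie-resolved ranks.

    Items with identical keys form a tie block over consecutive sorted
    positions and all receive the floored mean of those positions; the
    ordering of a block's members in the output (not their rank) follows
    the labels lexicographically.  Returns ``(item_index, rank)`` pairs
    in final display order.
    """
    order = sorted(range(len(labels)), key=lambda i: (sort_keys[i], labels[i]))
    out: list[tuple[int, int]] = []
    pos = 0
    while pos < len(order):
        end = pos
        while end < len(order) and sort_keys[order[end]] == sort_keys[order[pos]]:
            end += 1
        m = end - pos
        rank = (pos + 1) + (m - 1) // 2  # floor of mean of 1-based positions
        for j in range(pos, end):
            out.append((order[j], rank))
        pos = end
    return out


def _prepare(
    index: AnnotationIndex,
    patient: TermSet | Iterable[str],
    universe: Iterable[str] | None,
    kernel: SimilarityKernel | None,
) -> tuple[list[str], list[str], np.ndarray, SimilarityKernel]:
    label = patient.label if isinstance(patient, TermSet) else "patient"
    terms = index.filter_terms(_as_terms(patient), label=label or "patient")
    if not terms:
        raise EmptyTermSetError(
            "patient term set is empty after removing terms with undefined IC"
        )
    genes = sorted(universe) if universe is not None else index.genes
    if not genes:
        raise ValueError("empty gene universe")
    rankable = [g for g in genes if g in index.direct]
    unrankable = [g for g in genes if g not in index.direct]
    if not rankable:
        raise ValueError("no gene in the requested universe has annotations")
    kernel = kernel or SimilarityKernel(index)
    term_idx = kernel.term_indices(terms)
    return rankable, unrankable, term_idx, kernel


def rank_by_score(
    index: AnnotationIndex,
    patient: TermSet | Iterable[str],
    universe: Iterable[str] | None = None,
    kernel: SimilarityKernel | None = None,
) -> GeneRanking:
    """Rank genes by descending similarity score with mean-position ties."""
    rankable, unrankable, term_idx, kernel = _prepare(index, patient, universe, kernel)
    scores = [kernel.gene_score(term_idx, g) for g in rankable]
    # round before comparing so mathematically tied scores that differ in
    # the last float ulp still form one tie block
    keys = [(-round(s, 9),) for s in scores]
    entries = [
        RankEntry(gene=rankable[i], score=scores[i], rank=r)
        for i, r in tied_ranks(keys, rankable)
    ]
    return GeneRanking(entries, len(rankable), unrankable, by="score")


def rank_by_pvalue(
    index: AnnotationIndex,
    store: NullTableStore,
    patient: TermSet | Iterable[str],
    universe: Iterable[str] | None = None,
    kernel: SimilarityKernel | None = None,
) -> GeneRanking:
    """Rank genes by ascending p-value; p ties break by descending score."""
    rankable, unrankable, term_idx, kernel = _prepare(index, patient, universe, kernel)
    K = len(term_idx)
    scores = [kernel.gene_score(term_idx, g) for g in rankable]
    pvals = [store.get(g, K).p_value(s) for g, s in zip(rankable, scores)]
    keys = [(p, -round(s, 9)) for p, s in zip(pvals, scores)]
    entries = [
        RankEntry(gene=rankable[i], score=scores[i], p_value=pvals[i], rank=r)
        for i, r in tied_ranks(keys, rankable)
    ]
    return GeneRanking(entries, len(rankable), unrankable, by="pvalue")


def rank_within_subset(
    index: AnnotationIndex,
    store: NullTableStore | None,
    patient: TermSet | Iterable[str],
    subset: Iterable[str],
    by: str = "score",
    kernel: SimilarityKernel | None = None,
) -> GeneRanking:
    """Re-rank within a restricted gene subset (e.g. variant-filtered genes).

    Identical semantics to the full-universe rankings but confined to
    ``subset``; p-values still come from the genome-wide null tables, so
    only the competition changes, not the statistics.  Subset members
    without annotations are reported as unrankable.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("empty gene subset")
    if by == "score":
        return rank_by_score(index, patient, universe=subset, kernel=kernel)
    if by == "pvalue":
        if store is None:
            raise ValueError("p-value ranking requires a null table store")
        return rank_by_pvalue(index, store, patient, universe=subset, kernel=kernel)
    raise ValueError(f"unknown ranking mode {by!r}")
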