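"""Monte-Carlo null score distributions and one-sided empirical p-values.

Preferentially annotated genes (those carrying many terms) reach high
similarity scores against random queries more easily than sparsely
annotated ones, which skews a raw score ranking.  To compensate, each
gene's score is referred to its own null distribution: for every gene and
every query length K, similarity scores of random query term sets drawn
uniformly from the annotated-term universe.  The one-sided p-value of an
observed score s is the fraction of null samples >= s, floored at
1/(M+1) so the estimate is never exactly zero.  Query lengths above 10
reuse the K = 10 table.

Scores are quantized to 1e-6 before storage and lookup — far below any
meaningful information-content difference — so tables compress to
score -> count histograms and ties are counted exactly.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

from hporank.annotations import AnnotationIndex
from hporank.similarity import SimilarityKernel

logger = logging.getLogger(__name__)

K_MAX_TABLE = 10
QUANTUM = 1e-6


def _quantize(scores: np.ndarray | float) -> np.ndarray | float:
    return np.round(np.asarray(scores) / QUANTUM) * QUANTUM


@dataclass
class NullTable:
    """Empirical null score distribution for one (gene, K) pair.

    ``values`` are the distinct quantized scores in ascending order with
    multiplicities ``counts``; ``M = counts.sum()`` samples in total.
    """

    gene: str
    K: int
    values: np.ndarray
    counts: np.ndarray
    _cum_below: np.ndarray | None = None
    _M: int | None = None

    @classmethod
    def from_samples(cls, gene: str, K: int, samples: np.ndarray) -> "NullTable":
        values, counts = np.unique(_quantize(samples), return_counts=True)
        return cls(gene=gene, K=K, values=values, counts=counts)

    @property
    def M(self) -> int:
        if self._M is None:
            self._M = int(self.counts.sum())
        return self._M

    @property
    def samples(self) -> np.ndarray:
        """Sorted expansion of the histogram back to M samples."""
        return np.repeat(self.values, self.counts)

    def p_value(self, score: float | np.ndarray) -> float | np.ndarray:
        """P(null score >= observed), floored at 1/(M+1)."""
        M = self.M
        if self._cum_below is None:
            self._cum_below = np.concatenate([[0], np.cumsum(self.counts)])
        below = self._cum_below
        idx = np.searchsorted(self.values, np.asarray(_quantize(score)), side="left")
        n_ge = M - below[idx]
        p = np.maximum(n_ge / M, 1.0 / (M + 1))
        return float(p) if np.isscalar(score) or np.ndim(score) == 0 else p


class NullTableStore:
    """Collection of null tables keyed by (gene, K).

    Lookups for K > 10 resolve to the K = 10 table, mirroring how tables
    are built only up to K = 10.
    """

    def __init__(
        self,
        universe: Sequence[str],
        metadata: dict[str, str] | None = None,
    ) -> None:
        self.universe: list[str] = list(universe)
        self.tables: dict[tuple[str, int], NullTable] = {}
        self.metadata: dict[str, str] = dict(metadata or {})

    def add(self, table: NullTable) -> None:
        self.tables[(table.gene, table.K)] = table

    def effective_K(self, K: int) -> int:
        return min(K, K_MAX_TABLE)

    def get(self, gene: str, K: int) -> NullTable:
        key = (gene, self.effective_K(K))
        try:
            return self.tables[key]
        except KeyError:
            raise KeyError(
                f"no null table for gene {key[0]!r} at query length K={key[1]}"
            ) from None

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.tables})

    # -- serialization -----------------------------------------------------

    def save(self, path_or_file: str | IO[str]) -> None:
        """Write the store as tab-delimited ``gene K score count`` rows.

        Header ``#`` lines record metadata (sample counts, seed, source
        checksums when provided) and the term universe, making the
        archive self-contained for later p-value computation.
        """
        if isinstance(path_or_file, str):
            with open(path_or_file, "w") as fh:
                self.save(fh)
            return
        fh = path_or_file
        for key in sorted(self.metadata):
            fh.write(f"#meta\t{key}\t{self.metadata[key]}\n")
        fh.write("#universe\t" + ",".join(self.universe) + "\n")
        fh.write("#gene\tK\tscore\tcount\n")
        for gene, K in sorted(self.tables):
            t = self.tables[(gene, K)]
            for v, c in zip(t.values, t.counts):
                fh.write(f"{gene}\t{K}\t{v:.6f}\t{c}\n")

    @classmethod
    def load(cls, path_or_file: str | IO[str]) -> "NullTableStore":
        if isinstance(path_or_file, str):
            with open(path_or_file) as fh:
                return cls.load(fh)
        fh = path_or_file
        metadata: dict[str, str] = {}
        universe: list[str] = []
        rows: dict[tuple[str, int], list[tuple[float, int]]] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#meta\t"):
                _, key, value = line.split("\t", 2)
                metadata[key] = value
                continue
            if line.startswith("#universe\t"):
                universe = line.split("\t", 1)[1].split(",")
                continue
            if line.startswith("#"):
                continue
            gene, k_str, score_str, count_str = line.split("\t")
            rows.setdefault((gene, int(k_str)), []).append(
                (float(score_str), int(count_str))
            )
        store = cls(universe, metadata)
        for (gene, K), pairs in rows.items():
            pairs.sort()
            values = np.array([p[0] for p in pairs])
            counts = np.array([p[1] for p in pairs], dtype=np.int64)
            store.add(NullTable(gene=gene, K=K, values=values, counts=counts))
        return store


def sample_k_subsets(
    rng: np.random.Generator, universe_size: int, K: int, M: int
) -> np.ndarray:
    """Draw M size-K subsets (as index rows) uniformly without replacement.

    Rows are drawn with replacement and rows containing duplicates are
    redrawn; for K << universe_size this needs only a few rounds and is
    far cheaper than per-row permutation.
    """
    if K > universe_size:
        raise ValueError(f"cannot draw {K} distinct terms from {universe_size}")
    out = rng.integers(0, universe_size, size=(M, K))
    if K > 1:
        while True:
            srt = np.sort(out, axis=1)
            bad = np.flatnonzero((np.diff(srt, axis=1) == 0).any(axis=1))
            if bad.size == 0:
                break
            out[bad] = rng.integers(0, universe_size, size=(bad.size, K))
    return out


def build_null_tables(
    index: AnnotationIndex,
    genes: Iterable[str] | None = None,
    K_range: Iterable[int] = range(1, K_MAX_TABLE + 1),
    M: int = 100_000,
    seed: int = 0,
    kernel: SimilarityKernel | None = None,
    metadata: dict[str, str] | None = None,
) -> NullTableStore:
    """Construct per-gene, per-query-length null score distributions.

    For each gene and each K >= 2, ``M`` query sets of K distinct terms
    are drawn uniformly from the annotated-term universe and scored with
    the asymmetric patient-as-query gene score.  For K = 1 the universe
    is enumerated exhaustively instead of sampled.  Deterministic for a
    given seed: each (gene, K) pair draws from its own child stream, so
    results do not depend on iteration order or gene subsetting.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    kernel = kernel or SimilarityKernel(index)
    gene_list = sorted(genes) if genes is not None else index.genes
    K_list = sorted(set(K_range))
    if any(k < 1 or k > K_MAX_TABLE for k in K_list):
        raise ValueError(f"K_range must lie within [1, {K_MAX_TABLE}]")
    U = len(kernel.terms)

    meta = dict(metadata or {})
    meta.update({"M": str(M), "seed": str(seed), "universe_size": str(U)})
    store = NullTableStore(kernel.terms, meta)

    for gene in gene_list:
        best = kernel.best_match(gene)
        for K in K_list:
            if K == 1:
                samples = best.copy()
            else:
                if K > U:
                    raise ValueError(
                        f"query length K={K} exceeds universe size {U}"
                    )
                gene_key = zlib.crc32(gene.encode())
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(gene_key, K))
                )
                queries = sample_k_subsets(rng, U, K, M)
                samples = best[queries].mean(axis=1)
            store.add(NullTable.from_samples(gene, K, samples))
    return store


def p_value(store: NullTableStore, gene: str, K: int, score: float) -> float:
    """One-sided empirical p-value of an observed score for one gene.

    Probability under the null (random query sets of length min(K, 10))
    of a score at least as large as observed; in (0, 1], non-increasing
    in the score, floored at 1/(M+1) when the score exceeds every sample.
    """
    return float(store.get(gene, K).p_value(score))
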