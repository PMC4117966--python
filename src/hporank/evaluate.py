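"""Cohort evaluation: causative-gene ranks, rank CDFs, stratified summaries.

For every simulated patient the causative gene is ranked against the
annotated gene universe both by similarity score and by p-value, and the
result is annotated with covariates that explain performance:

S
    Normalized similarity between the patient's actual (possibly
    corrupted) term set and the optimal term set: the asymmetric
    best-match average with the actual terms as query, divided by the
    optimal set's self-similarity.  S = 1 for optimal-scenario patients
    and decreases as noise and imprecision distort the presentation.
max_ic
    The maximum information content among the patient's terms — how
    specific the most specific descriptor is.
n_terms
    Patient term count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hporank.annotations import AnnotationIndex
from hporank.nullmodel import NullTableStore
from hporank.ranking import rank_by_pvalue, rank_by_score
from hporank.similarity import SimilarityKernel, set_similarity_asymmetric
from hporank.simulate import SimulatedPatient

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankResult:
    patient_id: str
    disease: str
    scenario: str
    causative_gene: str
    rank_by_score: int
    rank_by_pvalue: int | None
    S: float
    max_ic: float
    n_terms: int


def _normalized_similarity(
    index: AnnotationIndex, actual: Sequence[str], optimal: Sequence[str]
) -> float:
    """S: actual-vs-optimal similarity over optimal self-similarity."""
    self_sim = set_similarity_asymmetric(index, optimal, optimal)
    if self_sim == 0.0:
        return 1.0  # optimal terms carry no information; nothing to lose
    # clipped: noise that happens to best-match only the high-IC optimal
    # terms can nudge the raw ratio past 1
    return min(1.0, set_similarity_asymmetric(index, actual, optimal) / self_sim)


def evaluate_cohort(
    cohort: Iterable[SimulatedPatient],
    index: AnnotationIndex,
    store: NullTableStore | None = None,
    universe: Iterable[str] | None = None,
    kernel: SimilarityKernel | None = None,
) -> list[RankResult]:
    """Rank the causative gene for every patient in a cohort.

    Ranks by score always; by p-value when a null table store is given.
    Patients whose causative gene has no annotations are skipped with a
    warning (such genes cannot appear in any ranking).  Patient terms
    with undefined IC are dropped before scoring, mirroring the ranking
    functions.
    """
    kernel = kernel or SimilarityKernel(index)
    genes = sorted(universe) if universe is not None else index.genes
    results: list[RankResult] = []
    for patient in cohort:
        if patient.causative_gene not in index.direct:
            logger.warning(
                "patient %s: causative gene %s is unannotated and unrankable",
                patient.patient_id,
                patient.causative_gene,
            )
            continue
        actual = index.filter_terms(patient.terms, label=patient.patient_id)
        optimal = index.filter_terms(patient.optimal_terms, label=patient.patient_id)
        if not actual or not optimal:
            logger.warning(
                "patient %s: no scorable terms, skipped", patient.patient_id
            )
            continue
        by_score = rank_by_score(index, actual, universe=genes, kernel=kernel)
        r_score = by_score.rank_of(patient.causative_gene)
        r_pval: int | None = None
        if store is not None:
            by_pval = rank_by_pvalue(index, store, actual, universe=genes, kernel=kernel)
            r_pval = by_pval.rank_of(patient.causative_gene)
        results.append(
            RankResult(
                patient_id=patient.patient_id,
                disease=patient.disease,
                scenario=patient.scenario,
                causative_gene=patient.causative_gene,
                rank_by_score=r_score,
                rank_by_pvalue=r_pval,
                S=_normalized_similarity(index, actual, optimal),
                max_ic=max(index.ic[t] for t in actual),
                n_terms=len(actual),
            )
        )
    return results


def results_frame(results: Iterable[RankResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


class RankCDF:
    """Empirical cumulative distribution of causative-gene ranks."""

    def __init__(self, ranks: Sequence[int]) -> None:
        if len(ranks) == 0:
            raise ValueError("no ranks to summarize")
        self.ranks = np.sort(np.asarray(ranks))
        self.n = len(self.ranks)

    def __call__(self, r: float) -> float:
        """P(R <= r)."""
        return float(np.searchsorted(self.ranks, r, side="right") / self.n)

    def median(self) -> int:
        """Lower median, keeping ranks integral."""
        return int(self.ranks[(self.n - 1) // 2])

    def mean(self) -> float:
        return float(self.ranks.mean())


def rank_cdf(results: Iterable[RankResult], by: str = "score") -> RankCDF:
    """Rank CDF over a result list, by ``score`` or ``pvalue`` ranking."""
    ranks = _extract_ranks(results, by)
    return RankCDF(ranks)


def _extract_ranks(results: Iterable[RankResult], by: str) -> list[int]:
    if by == "score":
        return [r.rank_by_score for r in results]
    if by == "pvalue":
        ranks = [r.rank_by_pvalue for r in results]
        if any(r is None for r in ranks):
            raise ValueError("some results lack p-value ranks")
        return ranks  # type: ignore[return-value]
    raise ValueError(f"unknown ranking mode {by!r}")


def stratify(
    results: Sequence[RankResult],
    key: str = "S",
    bins: Sequence[float] | int = 10,
    r_values: Sequence[int] = (1, 10, 20, 100),
    by: str = "score",
) -> pd.DataFrame:
    """Binned conditional rank summaries (rank probability per covariate bin).

    Groups results by ``key`` (``S``, ``max_ic`` or ``n_terms``) into
    ``bins`` and reports, per bin, the count, mean and median rank, and
    P(R <= r) for each requested r.  Empty bins are reported with NaN
    summaries, never as zeros.
    """
    if key not in ("S", "max_ic", "n_terms"):
        raise ValueError(f"unknown stratification key {key!r}")
    df = results_frame(results)
    df["rank"] = _extract_ranks(results, by)
    binned = pd.cut(df[key], bins=bins, include_lowest=True)
    rows = []
    for interval, grp in df.groupby(binned, observed=False):
        row: dict[str, object] = {
            "bin": str(interval),
            "n": len(grp),
            "mean_rank": grp["rank"].mean() if len(grp) else float("nan"),
            "median_rank": grp["rank"].median() if len(grp) else float("nan"),
        }
        for r in r_values:
            row[f"P(R<={r})"] = (
                float((grp["rank"] <= r).mean()) if len(grp) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    results: Sequence[RankResult],
    r_values: Sequence[int] = (1, 10, 20, 100),
) -> pd.DataFrame:
    """Per-scenario summary: median/mean rank and CDF points, both rankings."""
    rows = []
    df = results_frame(results)
    have_pval = df["rank_by_pvalue"].notna().all()
    for scenario, grp in df.groupby("scenario", sort=True):
        sub = [r for r in results if r.scenario == scenario]
        for by in ("score", "pvalue") if have_pval else ("score",):
            cdf = rank_cdf(sub, by=by)
            row: dict[str, object] = {
                "scenario": scenario,
                "ranked_by": by,
                "n": len(sub),
                "median_rank": cdf.median(),
                "mean_rank": round(cdf.mean(), 2),
            }
            for r in r_values:
                row[f"P(R<={r})"] = round(cdf(r), 4)
            rows.append(row)
    return pd.DataFrame(rows)
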