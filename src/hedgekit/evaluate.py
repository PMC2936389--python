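"""Retrieval evaluation and population-size estimation for search strategies.

Three standard figures of merit compare a retrieved set against a
gold-standard set of relevant records:

    sensitivity (recall) = relevant retrieved / all relevant
    precision            = relevant retrieved / all retrieved
    NNR                  = all retrieved / relevant retrieved = 1 / precision

Reporting follows filter-study convention: percentages to one decimal, NNR to
the nearest integer (half away from zero).  Zero-denominator metrics raise
rather than returning sentinel values, so a malformed comparison cannot pass
silently.

When all candidate strategies are OR-ed together and assumed jointly
exhaustive (sensitivity ~ 1), screening a random sample of the joint
retrieval for relevance yields a design-based estimate of the total number of
relevant records in the database: N * k/n with a binomial confidence interval
scaled by N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .medline_io import Corpus, filter_by_year
from .query import (
    BooleanStrategy,
    CorpusIndex,
    MeshTree,
    QueryExpr,
    execute,
)

__all__ = [
    "RetrievalResult",
    "PerformanceReport",
    "PopulationEstimate",
    "sensitivity",
    "precision",
    "nnr",
    "evaluate_strategy",
    "compare_strategies",
    "format_comparison",
    "union_pool",
    "estimate_total_relevant",
    "round_pct",
    "round_nnr",
]


def round_pct(fraction: float) -> float:
    """A fraction as a percentage rounded to 1 decimal, half away from zero."""
    return math.floor(fraction * 1000 + 0.5) / 10


def round_nnr(value: float) -> int:
    """NNR rounded to the nearest integer, half away from zero."""
    return int(math.floor(value + 0.5))


@dataclass(frozen=True)
class RetrievalResult:
    """A retrieved id set joined with a gold-standard relevant id set.

    The relevant-retrieved intersection is always recomputed from the two
    inputs; it cannot be supplied independently.
    """

    retrieved_ids: frozenset[str]
    relevant_ids: frozenset[str]

    def __init__(self, retrieved_ids: Iterable[str], relevant_ids: Iterable[str]):
        object.__setattr__(self, "retrieved_ids", frozenset(retrieved_ids))
        object.__setattr__(self, "relevant_ids", frozenset(relevant_ids))

    @property
    def relevant_retrieved(self) -> frozenset[str]:
        return self.retrieved_ids & self.relevant_ids

    @classmethod
    def from_counts(
        cls, retrieved: int, relevant: int, relevant_retrieved: int
    ) -> "RetrievalResult":
        """Build a result with the given set sizes (ids are synthesized).

        Lets published count triples be replayed through the same metric code
        paths as real retrievals.
        """
        if relevant_retrieved > min(retrieved, relevant):
            raise ValueError("relevant_retrieved exceeds retrieved or relevant")
        shared = [f"s{i}" for i in range(relevant_retrieved)]
        ret_only = [f"r{i}" for i in range(retrieved - relevant_retrieved)]
        rel_only = [f"g{i}" for i in range(relevant - relevant_retrieved)]
        return cls(shared + ret_only, shared + rel_only)


def sensitivity(result: RetrievalResult) -> float:
    """Fraction of all relevant records that were retrieved (recall)."""
    if not result.relevant_ids:
        raise ValueError("sensitivity is undefined for an empty gold standard")
    return len(result.relevant_retrieved) / len(result.relevant_ids)


def precision(result: RetrievalResult) -> float:
    """Fraction of retrieved records that are relevant."""
    if not result.retrieved_ids:
        raise ValueError("precision is undefined when nothing was retrieved")
    return len(result.relevant_retrieved) / len(result.retrieved_ids)


def nnr(result: RetrievalResult) -> float:
    """Number needed to read: records to screen per relevant record found."""
    if not result.relevant_retrieved:
        raise ValueError("NNR is undefined when no relevant record was retrieved")
    return len(result.retrieved_ids) / len(result.relevant_retrieved)


@dataclass(frozen=True)
class PerformanceReport:
    """All three metrics for one strategy on one labelled corpus.

    ``precision`` and ``nnr`` are ``None`` when undefined (nothing retrieved /
    no relevant record retrieved).
    """

    name: str
    retrieved_count: int
    relevant_count: int
    relevant_retrieved_count: int
    sensitivity: float
    precision: float | None
    nnr: float | None

    @property
    def sensitivity_pct(self) -> float:
        return round_pct(self.sensitivity)

    @property
    def precision_pct(self) -> float | None:
        return None if self.precision is None else round_pct(self.precision)

    @property
    def nnr_rounded(self) -> int | None:
        return None if self.nnr is None else round_nnr(self.nnr)

    @classmethod
    def from_result(cls, result: RetrievalResult, name: str = "") -> "PerformanceReport":
        retrieved = len(result.retrieved_ids)
        hits = len(result.relevant_retrieved)
        return cls(
            name=name,
            retrieved_count=retrieved,
            relevant_count=len(result.relevant_ids),
            relevant_retrieved_count=hits,
            sensitivity=sensitivity(result),
            precision=precision(result) if retrieved else None,
            nnr=nnr(result) if hits else None,
        )


def evaluate_strategy(
    strategy: BooleanStrategy | QueryExpr,
    corpus: Corpus | CorpusIndex,
    relevant_ids: Iterable[str],
    mesh_tree: MeshTree | None = None,
    year_range: tuple[int, int] | None = None,
    explode_default: bool = False,
    name: str = "",
) -> PerformanceReport:
    """Execute a strategy and score it against a gold-standard id set.

    ``corpus`` may be a prebuilt :class:`~hedgekit.query.CorpusIndex`; the
    gold-standard-in-corpus check is then skipped (an index may legitimately
    cover a date-limited subset that excludes some gold-standard records).
    """
    relevant = frozenset(relevant_ids)
    if not relevant:
        raise ValueError("the gold-standard set is empty")
    if isinstance(corpus, Corpus):
        missing = relevant - corpus.ids
        if missing:
            raise ValueError(
                f"{len(missing)} gold-standard ids are not in the corpus "
                f"(e.g. {sorted(missing)[0]!r})"
            )
    retrieved = execute(
        strategy, corpus, mesh_tree=mesh_tree, year_range=year_range,
        explode_default=explode_default,
    )
    if not name and isinstance(strategy, BooleanStrategy):
        name = strategy.name
    return PerformanceReport.from_result(
        RetrievalResult(retrieved, relevant), name=name
    )


def compare_strategies(
    strategies: Sequence[tuple[str, BooleanStrategy | QueryExpr]],
    corpus: Corpus,
    relevant_ids: Iterable[str],
    mesh_tree: MeshTree | None = None,
    year_range: tuple[int, int] | None = None,
    explode_default: bool = False,
) -> pd.DataFrame:
    """One row per strategy: counts, sensitivity %, precision %, NNR.

    The corpus is tokenized once and shared across all strategies.
    """
    if not strategies:
        raise ValueError("at least one strategy is required")
    relevant = frozenset(relevant_ids)
    missing = relevant - corpus.ids
    if missing:
        raise ValueError(
            f"{len(missing)} gold-standard ids are not in the corpus "
            f"(e.g. {sorted(missing)[0]!r})"
        )
    if year_range is not None:
        corpus = filter_by_year(corpus, *year_range)
    index = CorpusIndex(corpus)
    rows = []
    for name, strategy in strategies:
        report = evaluate_strategy(
            strategy, index, relevant, mesh_tree=mesh_tree,
            explode_default=explode_default, name=name,
        )
        rows.append(
            {
                "strategy": name,
                "retrieved": report.retrieved_count,
                "relevant_retrieved": report.relevant_retrieved_count,
                "sensitivity_pct": report.sensitivity_pct,
                "precision_pct": report.precision_pct,
                "nnr": report.nnr_rounded,
            }
        )
    return pd.DataFrame(rows)


def format_comparison(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a comparison table."""
    header = f"{'Strategy':<28} {'Retrieved [relevant]':>22} {'Sens(%)':>8} {'Prec(%)':>8} {'NNR':>5}"
    lines = [header, "-" * len(header)]
    for _, row in table.iterrows():
        retrieved = f"{row['retrieved']:,} [{row['relevant_retrieved']}]"
        prec = "-" if pd.isna(row["precision_pct"]) else f"{row['precision_pct']:.1f}"
        nnr_s = "-" if pd.isna(row["nnr"]) else f"{int(row['nnr'])}"
        lines.append(
            f"{row['strategy']:<28} {retrieved:>22} {row['sensitivity_pct']:>8.1f} "
            f"{prec:>8} {nnr_s:>5}"
        )
    return "\n".join(lines) + "\n"


def union_pool(
    strategies: Sequence[BooleanStrategy | QueryExpr],
    corpus: Corpus | CorpusIndex,
    mesh_tree: MeshTree | None = None,
    year_range: tuple[int, int] | None = None,
    explode_default: bool = False,
) -> frozenset[str]:
    """Union of the retrievals of several strategies (their OR-connection).

    Equals executing a single OR over the compiled single-line forms.
    """
    if not strategies:
        raise ValueError("at least one strategy is required")
    if year_range is not None and isinstance(corpus, Corpus):
        corpus = filter_by_year(corpus, *year_range)
    index = corpus if isinstance(corpus, CorpusIndex) else CorpusIndex(corpus)
    pool: frozenset[str] = frozenset()
    for strategy in strategies:
        pool |= execute(
            strategy, index, mesh_tree=mesh_tree, explode_default=explode_default
        )
    return pool


_CI_METHODS = {
    "wald": "normal",
    "wilson": "wilson",
    "clopper-pearson": "beta",
}


@dataclass(frozen=True)
class PopulationEstimate:
    """Estimated count of relevant records in a database of joint retrievals.

    ``point = joint_retrieved * sample_relevant / sample_size``; the interval
    is a binomial CI for the sample proportion scaled by ``joint_retrieved``
    and truncated below at zero.
    """

    point: float
    ci_low: float
    ci_high: float
    joint_retrieved: int
    sample_size: int
    sample_relevant: int
    ci_level: float
    ci_method: str


def estimate_total_relevant(
    joint_retrieved: int,
    sample_size: int,
    sample_relevant: int,
    ci_level: float = 0.95,
    method: str = "wald",
) -> PopulationEstimate:
    """Estimate how many relevant records a joint retrieval pool contains.

    Parameters
    ----------
    joint_retrieved : int
        Size of the OR-pool of all strategies (assumed to capture every
        relevant record).
    sample_size, sample_relevant : int
        Size of the screened random sample drawn from the pool, and how many
        of its records were judged relevant.
    ci_level : float
        Confidence level, default 0.95.
    method : str
        ``"wald"`` (default), ``"wilson"`` or ``"clopper-pearson"``.
    """
    if sample_size <= 0:
        raise ValueError("sample_size must be positive")
    if not 0 <= sample_relevant <= sample_size <= joint_retrieved:
        raise ValueError(
            "need 0 <= sample_relevant <= sample_size <= joint_retrieved"
        )
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}")
    p_low, p_high = proportion_confint(
        sample_relevant, sample_size, alpha=1.0 - ci_level, method=_CI_METHODS[method]
    )
    return PopulationEstimate(
        point=joint_retrieved * sample_relevant / sample_size,
        ci_low=max(0.0, joint_retrieved * float(p_low)),
        ci_high=joint_retrieved * float(p_high),
        joint_retrieved=joint_retrieved,
        sample_size=sample_size,
        sample_relevant=sample_relevant,
        ci_level=ci_level,
        ci_method=method,
    )
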