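"""Term mining: tokenization, term-document matrices and differential term selection.

The empirical route to a topic search filter starts from two corpora: a small
*development set* of known-relevant records and a large random *population
set* from the same database.  Candidate free-text terms are single words that
are common in the development set (document prevalence at or above a floor,
default 5%) yet rare in the population at large (at or below a ceiling,
default 2%).  Ranking the survivors by development-set document frequency and
keeping the top k yields the vocabulary from which Boolean strategies are
assembled.  The same machinery ranks MeSH descriptors by record frequency for
manual curation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer

from .medline_io import Corpus, MedlineRecord

__all__ = [
    "tokenize",
    "token_stream",
    "TermDocumentMatrix",
    "TermPrevalence",
    "SelectionConfig",
    "build_tdm",
    "compute_prevalence",
    "candidate_terms",
    "select_overrepresented",
    "mesh_frequency",
    "prevalence_report",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def token_stream(text: str) -> list[str]:
    """Lowercase token sequence of a text, split on any non-alphanumeric run.

    Order and repeats are preserved; no token is dropped.  This is the raw
    stream used for phrase adjacency in query matching.
    """
    return _TOKEN_RE.findall(text.lower())


def tokenize(record: MedlineRecord | str) -> set[str]:
    """Mining vocabulary of a record: distinct lowercase words of title+abstract.

    Splits on non-alphanumerics, then drops purely numeric tokens and tokens
    of length 1.  No stemming and no stopword removal: inflectional variants
    ("nurse"/"nurses"/"nursing") stay distinct, and ubiquitous words are left
    for the differential-prevalence filter to remove.
    """
    if isinstance(record, str):
        text = record
    else:
        text = f"{record.title} {record.abstract}"
    return {t for t in token_stream(text) if len(t) > 1 and not t.isdigit()}


@dataclass(frozen=True)
class TermDocumentMatrix:
    """Binary presence matrix (term x document) over a corpus.

    ``presence[i, j]`` is 1 iff ``terms[i]`` occurs at least once in the title
    or abstract of the record with id ``doc_ids[j]``.  Every term occurs in at
    least one document.
    """

    terms: tuple[str, ...]
    doc_ids: tuple[str, ...]
    presence: sp.csr_matrix

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def doc_counts(self) -> np.ndarray:
        """Number of documents containing each term (row sums)."""
        return np.asarray(self.presence.sum(axis=1)).ravel()

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet export: one (term, doc_id) row per nonzero entry."""
        coo = self.presence.tocoo()
        return pd.DataFrame(
            {
                "term": [self.terms[i] for i in coo.row],
                "doc_id": [self.doc_ids[j] for j in coo.col],
            }
        )


@dataclass(frozen=True)
class TermPrevalence:
    """Document frequency of one term in one corpus."""

    term: str
    doc_count: int
    n_docs: int

    @property
    def prevalence(self) -> float:
        return self.doc_count / self.n_docs

    @property
    def prevalence_2dp(self) -> float:
        """Prevalence rounded to 2 decimals, as reported in prevalence tables."""
        return float(f"{self.prevalence:.2f}")


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for differential term selection.

    min_dev_prevalence : float
        Candidate floor — a term must appear in at least this fraction of
        development-set records (inclusive).  Default 0.05.
    max_pop_prevalence : float
        Specificity ceiling — at most this fraction of population-set records
        (inclusive; a term never seen in the population counts as 0).
        Default 0.02.
    top_k : int
        Number of most-overrepresented terms to keep.  Default 25.
    """

    min_dev_prevalence: float = 0.05
    max_pop_prevalence: float = 0.02
    top_k: int = 25

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_dev_prevalence <= 1.0:
            raise ValueError("min_dev_prevalence must be in [0, 1]")
        if not 0.0 <= self.max_pop_prevalence <= 1.0:
            raise ValueError("max_pop_prevalence must be in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def build_tdm(corpus: Corpus) -> TermDocumentMatrix:
    """Build the binary term-document matrix of a corpus.

    Raises ``ValueError`` on an empty corpus or a corpus with no minable terms.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a term-document matrix from an empty corpus")
    vectorizer = CountVectorizer(analyzer=lambda rec: sorted(tokenize(rec)), binary=True)
    try:
        doc_term = vectorizer.fit_transform(corpus.records)
    except ValueError as exc:  # sklearn: "empty vocabulary"
        raise ValueError("corpus contains no minable terms") from exc
    terms = tuple(vectorizer.get_feature_names_out())
    return TermDocumentMatrix(
        terms=terms, doc_ids=corpus.pmids, presence=doc_term.T.tocsr()
    )


def compute_prevalence(tdm: TermDocumentMatrix) -> list[TermPrevalence]:
    """Per-term document counts and prevalences, in matrix term order."""
    counts = tdm.doc_counts()
    return [
        TermPrevalence(term=t, doc_count=int(c), n_docs=tdm.n_docs)
        for t, c in zip(tdm.terms, counts)
    ]


def candidate_terms(
    dev_prev: Sequence[TermPrevalence], config: SelectionConfig = SelectionConfig()
) -> list[str]:
    """Terms whose development-set prevalence meets the floor (inclusive)."""
    return [tp.term for tp in dev_prev if tp.prevalence >= config.min_dev_prevalence]


def select_overrepresented(
    dev_prev: Sequence[TermPrevalence],
    pop_prev: Sequence[TermPrevalence],
    config: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """The top-k development-frequent terms that are rare in the population.

    Among the development-set candidates, keeps terms with population
    prevalence at or below the ceiling (absent terms count as prevalence 0),
    ranks by development document count descending with alphabetical
    tie-break, and returns the first ``top_k``.
    """
    pop = {tp.term: tp.prevalence for tp in pop_prev}
    by_term = {tp.term: tp for tp in dev_prev}
    eligible = [
        by_term[t]
        for t in candidate_terms(dev_prev, config)
        if pop.get(t, 0.0) <= config.max_pop_prevalence
    ]
    eligible.sort(key=lambda tp: (-tp.doc_count, tp.term))
    return [tp.term for tp in eligible[: config.top_k]]


def mesh_frequency(corpus: Corpus) -> list[tuple[str, int]]:
    """MeSH descriptors ranked by the number of records carrying them.

    Counting is descriptor-level (subheadings ignored; a descriptor counts
    once per record).  Ties break alphabetically.  Judging a descriptor's
    relevance to the topic is left to the curator; this only supplies the
    frequency ranking.
    """
    counts: Counter[str] = Counter()
    for rec in corpus:
        counts.update({h.descriptor for h in rec.mesh_headings})
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def prevalence_report(
    dev_prev: Sequence[TermPrevalence],
    pop_prev: Sequence[TermPrevalence],
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Side-by-side prevalence table for the development-set terms.

    One row per development-set term with counts, 2-decimal prevalences in
    both corpora and a flag marking the selected (top-k overrepresented)
    terms; sorted selected-first by development count.
    """
    pop = {tp.term: tp for tp in pop_prev}
    selected = set(select_overrepresented(dev_prev, pop_prev, config))
    rows = []
    for tp in dev_prev:
        ptp = pop.get(tp.term)
        rows.append(
            {
                "term": tp.term,
                "dev_count": tp.doc_count,
                "dev_prevalence": tp.prevalence_2dp,
                "pop_count": ptp.doc_count if ptp else 0,
                "pop_prevalence": ptp.prevalence_2dp if ptp else 0.0,
                "selected": tp.term in selected,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["selected", "dev_count", "term"], ascending=[False, False, True]
    ).reset_index(drop=True)
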