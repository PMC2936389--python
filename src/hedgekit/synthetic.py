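"""Seeded generator of labelled MEDLINE-like corpora with controlled prevalences.

Search-filter development needs corpora whose per-term document prevalences
are known exactly: a small relevant class (the development-set analogue) and
a large background class (the population-sample analogue).  The generator
plants each profiled term in a record independently with its class-conditional
prevalence, pads abstracts with pronounceable filler words drawn from a
vocabulary disjoint from the profiled terms (so prevalence accounting stays
exact), assigns MeSH headings the same way, and is bit-reproducible under a
fixed seed.

This emulates the *structure* of real bibliographic corpora, not their
language: terms are class-conditionally independent Bernoulli draws with no
topical correlation, which is sufficient to exercise term selection, query
execution and evaluation, but says nothing about how correlated real
vocabulary behaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .medline_io import Corpus, MedlineRecord, MeshHeading

__all__ = [
    "HeadingProfile",
    "CorpusSpec",
    "LabelledCorpus",
    "generate",
    "nurse_staffing_default_spec",
    "NURSE_STAFFING_TERM_COUNTS",
    "COMMON_TERM_PREVALENCES",
]


@dataclass(frozen=True)
class HeadingProfile:
    """Class-conditional assignment probabilities for one MeSH descriptor.

    When ``subheading`` is set, an assigned heading carries it with
    probability ``p_subheading``.
    """

    p_relevant: float
    p_background: float
    subheading: str | None = None
    p_subheading: float = 1.0


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a labelled synthetic corpus.

    term_profile maps each profiled term to its
    (prevalence in relevant class, prevalence in background class) pair.
    ``filler_vocab`` may pin an explicit filler vocabulary; by default one is
    generated, disjoint from the profiled terms.
    """

    n_relevant: int
    n_background: int
    term_profile: Mapping[str, tuple[float, float]]
    mesh_profile: Mapping[str, HeadingProfile] = field(default_factory=dict)
    filler_vocab_size: int = 2000
    filler_vocab: tuple[str, ...] | None = None
    tokens_per_abstract: tuple[int, int] = (60, 120)
    title_term_prob: float = 0.3
    year_range: tuple[int, int] = (1982, 2006)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relevant < 0 or self.n_background < 0:
            raise ValueError("record counts must be >= 0")
        for term, (p_rel, p_bg) in self.term_profile.items():
            if not (0.0 <= p_rel <= 1.0 and 0.0 <= p_bg <= 1.0):
                raise ValueError(f"prevalences for {term!r} must be in [0, 1]")
            if term != term.lower() or len(term) < 2 or term.isdigit():
                raise ValueError(
                    f"profiled term {term!r} would not survive tokenization "
                    "(must be lowercase, length >= 2, not purely numeric)"
                )
        lo, hi = self.tokens_per_abstract
        if not 0 <= lo <= hi:
            raise ValueError("tokens_per_abstract must be a (low, high) range")


@dataclass(frozen=True)
class LabelledCorpus:
    """A corpus together with the ids of its relevant (gold-standard) records."""

    corpus: Corpus
    relevant_ids: frozenset[str]

    @property
    def relevant(self) -> Corpus:
        return Corpus(
            records=tuple(r for r in self.corpus if r.pmid in self.relevant_ids),
            label="relevant",
        )

    @property
    def background(self) -> Corpus:
        return Corpus(
            records=tuple(r for r in self.corpus if r.pmid not in self.relevant_ids),
            label="background",
        )


_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"


def _filler_vocabulary(
    rng: np.random.Generator, size: int, forbidden: frozenset[str]
) -> tuple[str, ...]:
    """Pronounceable nonsense words, distinct and disjoint from ``forbidden``."""
    vocab: list[str] = []
    seen: set[str] = set(forbidden)
    while len(vocab) < size:
        n_syll = int(rng.integers(2, 5))
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if word not in seen:
            seen.add(word)
            vocab.append(word)
    return tuple(vocab)


def generate(spec: CorpusSpec) -> LabelledCorpus:
    """Draw a labelled corpus from a :class:`CorpusSpec`.

    Records are numbered sequentially from 1, relevant class first.  Each
    profiled term present in a record is placed in the title with probability
    ``title_term_prob`` and otherwise in the abstract; filler words pad the
    abstract to a length drawn uniformly from ``tokens_per_abstract``.
    Identical seeds produce bit-identical corpora.
    """
    rng = np.random.default_rng(spec.seed)
    profiled = frozenset(spec.term_profile)
    if spec.filler_vocab is not None:
        overlap = profiled & set(spec.filler_vocab)
        if overlap:
            raise ValueError(
                f"filler vocabulary overlaps profiled terms: {sorted(overlap)[:5]}"
            )
        vocab = tuple(spec.filler_vocab)
    else:
        vocab = _filler_vocabulary(rng, spec.filler_vocab_size, profiled)
    if not vocab:
        raise ValueError("filler vocabulary is empty")

    n_total = spec.n_relevant + spec.n_background
    terms = sorted(spec.term_profile)
    descriptors = sorted(spec.mesh_profile)

    # presence[i, j]: does record i carry profiled term j / descriptor j
    def _class_presence(probs_rel, probs_bg) -> np.ndarray:
        rel = rng.random((spec.n_relevant, len(probs_rel))) < np.asarray(probs_rel)
        bg = rng.random((spec.n_background, len(probs_bg))) < np.asarray(probs_bg)
        return np.vstack([rel, bg]) if n_total else np.zeros((0, len(probs_rel)), bool)

    term_presence = _class_presence(
        [spec.term_profile[t][0] for t in terms],
        [spec.term_profile[t][1] for t in terms],
    )
    mesh_presence = _class_presence(
        [spec.mesh_profile[d].p_relevant for d in descriptors],
        [spec.mesh_profile[d].p_background for d in descriptors],
    )

    lo, hi = spec.tokens_per_abstract
    lengths = rng.integers(lo, hi + 1, size=n_total)
    years = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n_total)

    records: list[MedlineRecord] = []
    for i in range(n_total):
        present = [terms[j] for j in np.flatnonzero(term_presence[i])]
        in_title = rng.random(len(present)) < spec.title_term_prob
        title_terms = [t for t, flag in zip(present, in_title) if flag]
        abstract_terms = [t for t, flag in zip(present, in_title) if not flag]

        n_filler = max(0, int(lengths[i]) - len(abstract_terms))
        filler = [vocab[k] for k in rng.integers(0, len(vocab), size=n_filler)]
        abstract_words = abstract_terms + filler
        rng.shuffle(abstract_words)

        title_filler = [vocab[k] for k in rng.integers(0, len(vocab), size=3)]
        title_words = title_terms + title_filler
        rng.shuffle(title_words)

        headings = []
        for j in np.flatnonzero(mesh_presence[i]):
            prof = spec.mesh_profile[descriptors[j]]
            subs: tuple[str, ...] = ()
            if prof.subheading is not None and rng.random() < prof.p_subheading:
                subs = (prof.subheading,)
            headings.append(MeshHeading(descriptor=descriptors[j], subheadings=subs))

        records.append(
            MedlineRecord(
                pmid=str(i + 1),
                title=" ".join(title_words).capitalize() + ".",
                abstract=" ".join(abstract_words) + ("." if abstract_words else ""),
                mesh_headings=tuple(headings),
                pub_year=int(years[i]),
            )
        )

    return LabelledCorpus(
        corpus=Corpus(records=tuple(records), label="synthetic"),
        relevant_ids=frozenset(str(i + 1) for i in range(spec.n_relevant)),
    )


# --------------------------------------------------------------------------
# nurse-staffing reference profile

#: Per-term document counts in the nurse-staffing reference corpora:
#: term -> (count among 78 relevant records, count among 10,000 sampled records).
NURSE_STAFFING_TERM_COUNTS: dict[str, tuple[int, int]] = {
    "nurse": (55, 79),
    "hospitals": (50, 114),
    "staffing": (49, 10),
    "nursing": (45, 186),
    "nurses": (39, 114),
    "staff": (22, 88),
    "stay": (21, 146),
    "registered": (20, 40),
    "units": (20, 173),
    "mix": (17, 17),
    "relationships": (17, 181),
    "organizational": (15, 30),
    "ratios": (16, 173),
    "odds": (16, 189),
    "intensive": (15, 143),
    "adjusted": (14, 175),
    "teaching": (13, 52),
    "falls": (12, 33),
    "rns": (10, 8),
    "satisfaction": (11, 143),
    "skill": (10, 22),
    "proportion": (11, 179),
    "medicare": (10, 57),
    "multivariate": (11, 189),
    "tract": (11, 192),
}

#: Common terms that are frequent in BOTH classes and therefore never
#: selected by the differential filter ("patients" is the canonical example:
#: ~65% of relevant vs ~77% of background records).  They matter because the
#: bundled strategies use one of them ("outcomes") as an AND-operand.
COMMON_TERM_PREVALENCES: dict[str, tuple[float, float]] = {
    "patients": (0.65, 0.77),
    "outcomes": (0.60, 0.10),
}

# Heading rates are flat (unexploded) stand-ins: "Health Services
# Administration" is near-universal in the relevant class because in a real
# database virtually every staffing study carries some descendant of it, and
# matching there happens via explosion, which flat synthetic headings lack.
_NURSE_STAFFING_MESH: dict[str, HeadingProfile] = {
    "Nursing Staff, Hospital": HeadingProfile(0.60, 0.003),
    "Personnel Staffing and Scheduling": HeadingProfile(0.45, 0.002),
    "Hospital Units": HeadingProfile(0.20, 0.004),
    "Outcome and Process Assessment (Health Care)": HeadingProfile(0.35, 0.008),
    "Health Services Administration": HeadingProfile(0.95, 0.015),
    "Nursing Administration Research": HeadingProfile(0.15, 0.001),
    "Intensive Care Units": HeadingProfile(
        0.15, 0.004, subheading="manpower", p_subheading=0.6
    ),
}


def nurse_staffing_default_spec(seed: int = 0) -> CorpusSpec:
    """The nurse-staffing study conditions as a corpus recipe.

    78 relevant and 10,000 background records; the 25 differential free-text
    terms at their reference document-count fractions (e.g. "staffing" in
    49/78 relevant and 10/10,000 background records); two common
    non-differential terms ("patients", "outcomes"); plus the MeSH
    descriptors used by the bundled strategies at plausible class rates so
    that both [tiab] and [mh] retrieval paths are exercised.
    """
    term_profile = {
        term: (dev / 78, pop / 10_000)
        for term, (dev, pop) in NURSE_STAFFING_TERM_COUNTS.items()
    }
    term_profile.update(COMMON_TERM_PREVALENCES)
    return CorpusSpec(
        n_relevant=78,
        n_background=10_000,
        term_profile=term_profile,
        mesh_profile=dict(_NURSE_STAFFING_MESH),
        seed=seed,
    )
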