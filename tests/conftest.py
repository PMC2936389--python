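"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by the most naive route
available (per-record truth evaluation, per-record scans) so they stay
independent of the set-algebra implementations they check.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

from hedgekit.medline_io import Corpus, MedlineRecord, MeshHeading
from hedgekit.query import (
    BooleanStrategy,
    LineRef,
    MeshTree,
    OpNode,
    QueryExpr,
    TermNode,
)
from hedgekit.synthetic import CorpusSpec, HeadingProfile, generate

# ---------------------------------------------------------------------------
# naive per-record truth-evaluation oracle (independent of hedgekit.query)

_WORD_RE = re.compile(r"[a-z0-9]+")


def _words(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


def _has_phrase(words: list[str], phrase: list[str]) -> bool:
    k = len(phrase)
    return any(words[i : i + k] == phrase for i in range(len(words) - k + 1))


def oracle_record_matches(
    expr: QueryExpr,
    record: MedlineRecord,
    lines: tuple[QueryExpr, ...] = (),
    mesh_tree: MeshTree | None = None,
    explode_default: bool = False,
) -> bool:
    """Truth-evaluate a query expression against one record, recursively."""
    if isinstance(expr, LineRef):
        return oracle_record_matches(
            lines[expr.number - 1], record, lines, mesh_tree, explode_default
        )
    if isinstance(expr, TermNode):
        if expr.field == "tiab":
            phrase = _words(expr.text)
            title, abstract = _words(record.title), _words(record.abstract)
            if len(phrase) == 1:
                return phrase[0] in title or phrase[0] in abstract
            return _has_phrase(title, phrase) or _has_phrase(abstract, phrase)
        explode = explode_default if expr.explode is None else expr.explode
        wanted = {expr.text.lower()}
        if explode and mesh_tree is not None:
            wanted |= set(mesh_tree.descendants(expr.text))
        for h in record.mesh_headings:
            if h.descriptor.lower() in wanted:
                if expr.subheading is None:
                    return True
                if expr.subheading.lower() in (s.lower() for s in h.subheadings):
                    return True
        return False
    values = [
        oracle_record_matches(sub, record, lines, mesh_tree, explode_default)
        for sub in expr.operands
    ]
    if expr.op == "OR":
        return any(values)
    if expr.op == "AND":
        return all(values)
    return values[0] and not values[1]  # NOT


def oracle_execute(
    strategy: BooleanStrategy,
    corpus: Corpus,
    mesh_tree: MeshTree | None = None,
    explode_default: bool = False,
) -> frozenset[str]:
    result = strategy.lines[-1]
    return frozenset(
        r.pmid
        for r in corpus
        if oracle_record_matches(
            result, r, strategy.lines, mesh_tree, explode_default
        )
    )


# ---------------------------------------------------------------------------
# random strategy generator for engine equivalence checks

_RANDOM_TERMS = [
    "nurse", "nurses", "staffing", "staff", "hospitals", "outcomes",
    "mix", "skill", "ratios", "units", "stay", "medicare",
]
_RANDOM_PHRASES = ["skill mix", "length of stay", "nurse staffing"]
_RANDOM_DESCRIPTORS = [
    "Nursing Staff, Hospital",
    "Hospital Units",
    "Intensive Care Units",
    "Personnel Staffing and Scheduling",
]


def random_expression(rng: np.random.Generator, depth: int, max_line: int) -> QueryExpr:
    """A random query expression; may reference strategy lines below max_line."""
    if depth <= 0 or rng.random() < 0.35:
        kind = rng.random()
        if kind < 0.15 and max_line >= 1:
            return LineRef(int(rng.integers(1, max_line + 1)))
        if kind < 0.35:
            desc = _RANDOM_DESCRIPTORS[rng.integers(len(_RANDOM_DESCRIPTORS))]
            sub = "manpower" if rng.random() < 0.3 else None
            return TermNode(desc, field="mh", subheading=sub)
        if kind < 0.5:
            return TermNode(_RANDOM_PHRASES[rng.integers(len(_RANDOM_PHRASES))])
        return TermNode(_RANDOM_TERMS[rng.integers(len(_RANDOM_TERMS))])
    op = ("OR", "AND", "NOT")[rng.integers(3)]
    n = 2 if op == "NOT" else int(rng.integers(2, 4))
    return OpNode(op, tuple(random_expression(rng, depth - 1, max_line) for _ in range(n)))


def random_strategy(rng: np.random.Generator, name: str = "random") -> BooleanStrategy:
    n_lines = int(rng.integers(1, 6))
    lines = tuple(
        random_expression(rng, depth=2, max_line=i) for i in range(n_lines)
    )
    return BooleanStrategy(name=name, lines=lines)


# ---------------------------------------------------------------------------
# fixtures

SMALL_ENGINE_SPEC = CorpusSpec(
    n_relevant=30,
    n_background=70,
    term_profile={
        "nurse": (0.7, 0.2),
        "nurses": (0.5, 0.15),
        "staffing": (0.6, 0.1),
        "staff": (0.3, 0.25),
        "hospitals": (0.6, 0.3),
        "outcomes": (0.5, 0.3),
        "mix": (0.2, 0.1),
        "skill": (0.2, 0.1),
        "ratios": (0.25, 0.1),
        "units": (0.3, 0.2),
        "stay": (0.3, 0.2),
        "medicare": (0.1, 0.05),
    },
    mesh_profile={
        "Nursing Staff, Hospital": HeadingProfile(0.6, 0.1),
        "Health Services Administration": HeadingProfile(0.8, 0.2),
        "Outcome and Process Assessment (Health Care)": HeadingProfile(0.4, 0.2),
        "Hospital Units": HeadingProfile(0.3, 0.1),
        "Intensive Care Units": HeadingProfile(
            0.3, 0.1, subheading="manpower", p_subheading=0.5
        ),
        "Personnel Staffing and Scheduling": HeadingProfile(0.4, 0.05),
    },
    filler_vocab_size=40,
    tokens_per_abstract=(8, 16),
    seed=11,
)


@pytest.fixture(scope="session")
def engine_corpus() -> Corpus:
    """A dense 100-record corpus where random strategies match often."""
    return generate(SMALL_ENGINE_SPEC).corpus


@pytest.fixture(scope="session")
def small_labelled():
    """A small labelled corpus for evaluation tests."""
    return generate(SMALL_ENGINE_SPEC)


@pytest.fixture()
def toy_corpus() -> Corpus:
    """Three hand-built records with known tokens and headings."""
    return Corpus(
        records=(
            MedlineRecord(
                pmid="1",
                title="Hospital nurse staffing and patient mortality.",
                abstract="The skill mix of staff varied across units.",
                mesh_headings=(
                    MeshHeading("Nursing Staff, Hospital", ("manpower",), True),
                    MeshHeading("Hospital Units"),
                ),
                pub_year=2003,
            ),
            MedlineRecord(
                pmid="2",
                title="Length of stay in intensive care.",
                abstract="Registered nurses and patient outcomes.",
                mesh_headings=(
                    MeshHeading("Intensive Care Units", ("manpower", "organization & administration")),
                ),
                pub_year=1999,
            ),
            MedlineRecord(
                pmid="3",
                title="Skill and grade mix in nursing teams.",
                abstract="",
                mesh_headings=(),
                pub_year=2006,
            ),
        ),
        label="toy",
    )


MESH_TREE_TEXT = """\
N02\tHealth Personnel
N02.360\tNursing Staff
N02.360.475\tNursing Staff, Hospital
N02.421\tHealth Services Administration
N02.421.143\tPersonnel Staffing and Scheduling
N02.421.143.150\tNurse-Patient Ratio
N05.715\tHospital Units
N05.715.360\tIntensive Care Units
"""


@pytest.fixture()
def mesh_tree() -> MeshTree:
    return MeshTree.from_text(MESH_TREE_TEXT)
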