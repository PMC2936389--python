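"""PubMed-style Boolean search strategies: parsing, compilation and execution.

A strategy is an ordered list of numbered lines, each a Boolean expression
over field-tagged terms, with ``#n`` referring back to an earlier line; the
last line is the result.  Two field tags are supported: ``[tiab]`` (a word or
phrase matched against title/abstract tokens) and ``[mh]`` (a MeSH descriptor,
optionally qualified as ``Descriptor/subheading`` and optionally exploded down
a MeSH tree).  Execution is pure set algebra over a local corpus: OR is union,
AND is intersection, NOT is binary set difference.

Deliberately NOT emulated: PubMed's automatic term mapping, truncation,
proximity operators and default MeSH explosion without a tree — strategies
behave identically wherever they are executed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from .medline_io import Corpus, MedlineRecord, filter_by_year
from .textmine import token_stream

__all__ = [
    "TermNode",
    "OpNode",
    "LineRef",
    "QueryExpr",
    "BooleanStrategy",
    "QueryParseError",
    "MeshTree",
    "CorpusIndex",
    "parse_expression",
    "parse_strategy",
    "read_strategy",
    "format_expression",
    "format_strategy",
    "compile_single_line",
    "match_tiab",
    "match_mesh",
    "execute",
]

TIAB = "tiab"
MH = "mh"


class QueryParseError(ValueError):
    """Raised on malformed strategy text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class TermNode:
    """A field-tagged search term.

    ``field`` is ``"tiab"`` or ``"mh"``.  For ``[tiab]``, ``text`` is a single
    word or a multi-word phrase.  For ``[mh]``, ``text`` is the descriptor and
    ``subheading`` the optional qualifier.  ``explode`` of ``None`` defers to
    the executor's default.
    """

    text: str
    field: str = TIAB
    subheading: str | None = None
    explode: bool | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("term text must be non-empty")
        if self.field not in (TIAB, MH):
            raise ValueError(f"unknown field {self.field!r}")
        if self.field == TIAB and self.subheading is not None:
            raise ValueError("[tiab] terms carry no subheading")


@dataclass(frozen=True)
class OpNode:
    """Boolean combination: OR/AND are n-ary, NOT is binary set difference."""

    op: str  # "AND" | "OR" | "NOT"
    operands: tuple["QueryExpr", ...]

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR", "NOT"):
            raise ValueError(f"unknown operator {self.op!r}")
        if self.op == "NOT" and len(self.operands) != 2:
            raise ValueError("NOT takes exactly two operands (A NOT B)")
        if len(self.operands) < 2:
            raise ValueError("boolean operators need at least two operands")


@dataclass(frozen=True)
class LineRef:
    """Back-reference ``#n`` to an earlier strategy line."""

    number: int


QueryExpr = Union[TermNode, OpNode, LineRef]


@dataclass(frozen=True)
class BooleanStrategy:
    """A named, ordered, numbered Boolean search strategy.

    Line numbers run consecutively from 1; every ``#n`` reference resolves to
    an earlier line; the highest-numbered line is the result.
    """

    name: str
    lines: tuple[QueryExpr, ...]  # lines[i] is line i+1

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("a strategy needs at least one line")
        for i, expr in enumerate(self.lines, start=1):
            for ref in _line_refs(expr):
                if not 1 <= ref.number < i:
                    raise QueryParseError(
                        f"reference #{ref.number} does not point to an earlier line",
                        line=i,
                    )

    @property
    def result_line(self) -> int:
        return len(self.lines)

    def line(self, number: int) -> QueryExpr:
        return self.lines[number - 1]


def _line_refs(expr: QueryExpr) -> Iterable[LineRef]:
    if isinstance(expr, LineRef):
        yield expr
    elif isinstance(expr, OpNode):
        for sub in expr.operands:
            yield from _line_refs(sub)


# --------------------------------------------------------------------------
# lexer + recursive-descent parser


@dataclass(frozen=True)
class _Token:
    kind: str  # WORD | QUOTED | TAG | LINEREF | LPAREN | RPAREN
    value: str


_TOKEN_RE = re.compile(
    r"""
    \s*(?:
        (?P<QUOTED>"[^"]*")
      | (?P<LINEREF>\#\d+)
      | (?P<TAG>\[[A-Za-z:]+\])
      | (?P<LPAREN>\()
      | (?P<RPAREN>\))
      | (?P<WORD>[^\s()\[\]"#]+)
    )
    """,
    re.VERBOSE,
)

_OPERATORS = {"AND", "OR", "NOT"}


def _lex(text: str, line: int | None = None) -> list[_Token]:
    if text.count('"') % 2:
        raise QueryParseError("unbalanced quotes", line=line)
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise QueryParseError(f"cannot tokenize {text[pos:]!r}", line=line)
            break
        pos = m.end()
        kind = m.lastgroup
        assert kind is not None
        tokens.append(_Token(kind, m.group(kind)))
    return tokens


class _Parser:
    def __init__(self, tokens: Sequence[_Token], line: int | None = None):
        self.tokens = list(tokens)
        self.pos = 0
        self.line = line

    def peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of expression", line=self.line)
        self.pos += 1
        return tok

    def _is_operator(self, tok: _Token | None, name: str) -> bool:
        return tok is not None and tok.kind == "WORD" and tok.value.upper() == name

    # precedence: NOT > AND > OR; parentheses override; left-associative
    def parse(self) -> QueryExpr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise QueryParseError(
                f"unexpected token {self.peek().value!r}", line=self.line
            )
        return expr

    def parse_or(self) -> QueryExpr:
        operands = [self.parse_and()]
        while self._is_operator(self.peek(), "OR"):
            self.next()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else OpNode("OR", tuple(operands))

    def parse_and(self) -> QueryExpr:
        operands = [self.parse_not()]
        while self._is_operator(self.peek(), "AND"):
            self.next()
            operands.append(self.parse_not())
        return operands[0] if len(operands) == 1 else OpNode("AND", tuple(operands))

    def parse_not(self) -> QueryExpr:
        left = self.parse_atom()
        while self._is_operator(self.peek(), "NOT"):
            self.next()
            left = OpNode("NOT", (left, self.parse_atom()))
        return left

    def parse_atom(self) -> QueryExpr:
        tok = self.next()
        if tok.kind == "LPAREN":
            expr = self.parse_or()
            closing = self.peek()
            if closing is None or closing.kind != "RPAREN":
                raise QueryParseError("unbalanced parentheses", line=self.line)
            self.next()
            return expr
        if tok.kind == "RPAREN":
            raise QueryParseError("unbalanced parentheses", line=self.line)
        if tok.kind == "LINEREF":
            return LineRef(int(tok.value[1:]))
        if tok.kind == "QUOTED":
            return self._term(tok.value[1:-1], quoted=True)
        if tok.kind == "TAG":
            raise QueryParseError(f"field tag {tok.value!r} without a term", line=self.line)
        # WORD: gather a multi-word unquoted run up to an operator/terminator
        words = [tok.value]
        while True:
            nxt = self.peek()
            if (
                nxt is None
                or nxt.kind != "WORD"
                or nxt.value.upper() in _OPERATORS
            ):
                break
            words.append(self.next().value)
        return self._term(" ".join(words), quoted=False)

    def _term(self, text: str, quoted: bool) -> TermNode:
        text = text.strip()
        if not text:
            raise QueryParseError("empty term", line=self.line)
        field, explode = TIAB, None
        nxt = self.peek()
        if nxt is not None and nxt.kind == "TAG":
            self.next()
            tag = nxt.value[1:-1].lower()
            if tag == "tiab":
                field = TIAB
            elif tag in ("mh", "mesh"):
                field = MH
            elif tag in ("mh:noexp", "mesh:noexp"):
                field, explode = MH, False
            else:
                raise QueryParseError(f"unknown field tag [{tag}]", line=self.line)
        if field == MH:
            parts = text.split("/")
            if len(parts) > 2:
                raise QueryParseError(
                    f"at most one subheading allowed in {text!r}", line=self.line
                )
            sub = parts[1].strip() if len(parts) == 2 else None
            return TermNode(parts[0].strip(), field=MH, subheading=sub, explode=explode)
        return TermNode(text, field=TIAB)


def parse_expression(text: str, line: int | None = None) -> QueryExpr:
    """Parse a single Boolean expression (the single-line dialect)."""
    tokens = _lex(text, line=line)
    if not tokens:
        raise QueryParseError("empty expression", line=line)
    return _Parser(tokens, line=line).parse()


_LINE_RE = re.compile(r"^\s*(\d+)[.)]?\s+(\S.*)$")


def parse_strategy(text: str, name: str = "strategy") -> BooleanStrategy:
    """Parse numbered-line strategy text (``<number> <expression>`` per line).

    Line numbers must run consecutively from 1 and ``#n`` references must
    point to earlier lines; violations raise :class:`QueryParseError` naming
    the line.
    """
    lines: list[QueryExpr] = []
    for raw in text.splitlines():
        if not raw.strip():
            continue
        m = _LINE_RE.match(raw)
        if m is None:
            raise QueryParseError(
                f"expected '<number> <expression>', got {raw.strip()!r}",
                line=len(lines) + 1,
            )
        number = int(m.group(1))
        if number != len(lines) + 1:
            raise QueryParseError(
                f"line numbers must be consecutive from 1 (got {number})",
                line=len(lines) + 1,
            )
        lines.append(parse_expression(m.group(2), line=number))
    if not lines:
        raise QueryParseError("strategy text contains no lines")
    return BooleanStrategy(name=name, lines=tuple(lines))


def read_strategy(path: str | Path, name: str | None = None) -> BooleanStrategy:
    path = Path(path)
    return parse_strategy(path.read_text(encoding="utf-8"), name=name or path.stem)


# --------------------------------------------------------------------------
# serialization


_PRECEDENCE = {"OR": 0, "AND": 1, "NOT": 2}


def format_expression(expr: QueryExpr) -> str:
    """Render an expression in the single-line dialect (reparses identically)."""
    if isinstance(expr, LineRef):
        return f"#{expr.number}"
    if isinstance(expr, TermNode):
        if expr.field == MH:
            text = expr.text + (f"/{expr.subheading}" if expr.subheading else "")
            tag = "[mh:noexp]" if expr.explode is False else "[mh]"
            return f'"{text}"{tag}'
        return f"{expr.text}[tiab]"
    parts = []
    for sub in expr.operands:
        rendered = format_expression(sub)
        if isinstance(sub, OpNode) and _PRECEDENCE[sub.op] <= _PRECEDENCE[expr.op]:
            rendered = f"({rendered})"
        parts.append(rendered)
    if expr.op == "NOT":
        return f"{parts[0]} NOT {parts[1]}"
    return f" {expr.op} ".join(parts)


def format_strategy(strategy: BooleanStrategy) -> str:
    """Render a strategy back to numbered-line text."""
    return "".join(
        f"{i}\t{format_expression(expr)}\n"
        for i, expr in enumerate(strategy.lines, start=1)
    )


def compile_single_line(strategy: BooleanStrategy) -> QueryExpr:
    """Inline all ``#n`` references into one expression.

    The result retrieves exactly the same set as line-wise execution of the
    strategy on any corpus.
    """
    resolved: dict[int, QueryExpr] = {}

    def substitute(expr: QueryExpr) -> QueryExpr:
        if isinstance(expr, LineRef):
            return resolved[expr.number]
        if isinstance(expr, OpNode):
            return OpNode(expr.op, tuple(substitute(sub) for sub in expr.operands))
        return expr

    for i, expr in enumerate(strategy.lines, start=1):
        resolved[i] = substitute(expr)
    return resolved[strategy.result_line]


# --------------------------------------------------------------------------
# MeSH tree


class MeshTree:
    """A MeSH hierarchy loaded from two-column (tree number, descriptor) text.

    Tree numbers are dot-separated (e.g. ``N02.360.475``); a descriptor's
    descendants are all descriptors whose tree number extends one of its tree
    numbers.  Descriptors may occupy several tree positions.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self._by_descriptor: dict[str, list[str]] = {}
        self._entries: list[tuple[str, str]] = []
        for tree_number, descriptor in entries:
            self._entries.append((tree_number, descriptor))
            self._by_descriptor.setdefault(descriptor.lower(), []).append(tree_number)

    @classmethod
    def from_text(cls, text: str) -> "MeshTree":
        entries = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = re.split(r"\t|\s{2,}", line.strip(), maxsplit=1)
            if len(parts) != 2:
                raise ValueError(
                    f"line {lineno}: expected 'tree-number<TAB>descriptor', got {line!r}"
                )
            entries.append((parts[0].strip(), parts[1].strip()))
        return cls(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "MeshTree":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))

    def descendants(self, descriptor: str) -> frozenset[str]:
        """Lowercased descriptor names strictly below ``descriptor`` in the tree."""
        prefixes = [tn + "." for tn in self._by_descriptor.get(descriptor.lower(), [])]
        out = {
            desc.lower()
            for tn, desc in self._entries
            if any(tn.startswith(p) for p in prefixes)
        }
        out.discard(descriptor.lower())
        return frozenset(out)


# --------------------------------------------------------------------------
# matching and execution


def _contains_phrase(stream: Sequence[str], phrase: Sequence[str]) -> bool:
    k = len(phrase)
    if k == 0 or k > len(stream):
        return False
    phrase = list(phrase)
    return any(list(stream[i : i + k]) == phrase for i in range(len(stream) - k + 1))


def match_tiab(record: MedlineRecord, text: str) -> bool:
    """Exact-token title/abstract match for a word or phrase.

    Single terms match case-insensitively against the token streams of the
    title or abstract, with no stemming or substring matching ("staff" does
    not match "staffing").  Phrases must occur as consecutive tokens and never
    cross the title/abstract boundary.
    """
    query = token_stream(text)
    if not query:
        return False
    title = token_stream(record.title)
    abstract = token_stream(record.abstract)
    if len(query) == 1:
        return query[0] in title or query[0] in abstract
    return _contains_phrase(title, query) or _contains_phrase(abstract, query)


def match_mesh(
    record: MedlineRecord,
    descriptor: str,
    subheading: str | None = None,
    explode: bool = False,
    mesh_tree: MeshTree | None = None,
) -> bool:
    """MeSH heading match, optionally qualified and optionally exploded.

    The descriptor matches a record heading case-insensitively; a subheading,
    if given, must be carried by that same heading.  With ``explode`` the
    descriptor's descendants in ``mesh_tree`` also match (a tree is required).
    """
    if explode and mesh_tree is None:
        raise ValueError("explode=True requires a MeSH tree")
    wanted = {descriptor.lower()}
    if explode:
        assert mesh_tree is not None
        wanted |= mesh_tree.descendants(descriptor)
    sub = subheading.lower() if subheading is not None else None
    for heading in record.mesh_headings:
        if heading.descriptor.lower() not in wanted:
            continue
        if sub is None or sub in (s.lower() for s in heading.subheadings):
            return True
    return False


class CorpusIndex:
    """Reusable pre-tokenized view of a corpus for strategy execution.

    Tokenizes every record once; build it when several strategies run against
    the same corpus and pass it to :func:`execute` in place of the corpus.
    Phrase adjacency is checked on space-joined token streams, which is exact
    because tokens contain no whitespace.
    """

    def __init__(self, corpus: Corpus):
        self.records = corpus.records
        self._tokens: list[set[str]] = []
        self._title_text: list[str] = []
        self._abstract_text: list[str] = []
        for r in corpus.records:
            title = token_stream(r.title)
            abstract = token_stream(r.abstract)
            self._tokens.append(set(title).union(abstract))
            self._title_text.append(f" {' '.join(title)} ")
            self._abstract_text.append(f" {' '.join(abstract)} ")

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(r.pmid for r in self.records)

    def eval_term(
        self,
        node: TermNode,
        mesh_tree: MeshTree | None,
        explode_default: bool,
    ) -> frozenset[str]:
        if node.field == TIAB:
            query = token_stream(node.text)
            if not query:
                return frozenset()
            if len(query) == 1:
                word = query[0]
                return frozenset(
                    r.pmid
                    for r, toks in zip(self.records, self._tokens)
                    if word in toks
                )
            needle = f" {' '.join(query)} "
            return frozenset(
                r.pmid
                for r, title, abstract in zip(
                    self.records, self._title_text, self._abstract_text
                )
                if needle in title or needle in abstract
            )
        explode = explode_default if node.explode is None else node.explode
        return frozenset(
            r.pmid
            for r in self.records
            if match_mesh(r, node.text, node.subheading, explode, mesh_tree)
        )


def execute(
    query: Union[BooleanStrategy, QueryExpr],
    corpus: Union[Corpus, CorpusIndex],
    mesh_tree: MeshTree | None = None,
    year_range: tuple[int, int] | None = None,
    explode_default: bool = False,
) -> frozenset[str]:
    """Run a strategy or expression against a corpus; returns retrieved PMIDs.

    ``corpus`` may be a prebuilt :class:`CorpusIndex` to amortize tokenization
    over many executions.  ``year_range`` (inclusive) limits the corpus before
    matching, as a date-limited database search would.  ``explode_default``
    makes bare ``[mh]`` terms explode down ``mesh_tree`` (mimicking PubMed's
    default); it requires a tree.
    """
    if isinstance(corpus, CorpusIndex):
        if year_range is not None:
            raise ValueError(
                "year_range cannot be combined with a prebuilt CorpusIndex; "
                "filter the corpus before indexing"
            )
        index = corpus
    else:
        if year_range is not None:
            corpus = filter_by_year(corpus, *year_range)
        index = CorpusIndex(corpus)
    line_sets: dict[int, frozenset[str]] = {}

    def evaluate(expr: QueryExpr) -> frozenset[str]:
        if isinstance(expr, LineRef):
            return line_sets[expr.number]
        if isinstance(expr, TermNode):
            return index.eval_term(expr, mesh_tree, explode_default)
        sets = [evaluate(sub) for sub in expr.operands]
        if expr.op == "OR":
            return frozenset().union(*sets)
        if expr.op == "AND":
            out = sets[0]
            for s in sets[1:]:
                out &= s
            return out
        return sets[0] - sets[1]  # NOT

    if isinstance(query, BooleanStrategy):
        for i, expr in enumerate(query.lines, start=1):
            line_sets[i] = evaluate(expr)
        return line_sets[query.result_line]
    return evaluate(query)
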