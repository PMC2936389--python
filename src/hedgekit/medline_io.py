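"""Reading, writing and subsetting MEDLINE-format bibliographic corpora.

The MEDLINE tagged export format (``PMID-``, ``TI  -``, ``AB  -``, ``MH  -``,
``DP  -`` lines, with indented continuation lines) is the lingua franca of
PubMed exports and of search-filter development work.  This module wraps the
:mod:`Bio.Medline` parser in a :class:`Corpus` container, adds a writer (which
Biopython does not provide), and supplies the corpus manipulations a filter
study needs: PMID lists, seeded random sampling and publication-year limits.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

import numpy as np
from Bio import Medline

__all__ = [
    "MeshHeading",
    "MedlineRecord",
    "Corpus",
    "MedlineParseError",
    "parse_medline",
    "write_medline",
    "read_medline",
    "read_pmid_list",
    "write_pmid_list",
    "sample_corpus",
    "filter_by_year",
]

TextSource = Union[str, Path, IO[str]]


class MedlineParseError(ValueError):
    """Raised when a MEDLINE stream or PMID list is malformed."""


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH descriptor attached to a record.

    Parameters
    ----------
    descriptor : str
        Canonical heading text, e.g. ``"Nursing Staff, Hospital"``.
    subheadings : tuple of str
        Qualifiers such as ``"manpower"``; may be empty.
    major_topic : bool
        True when the heading (or one of its qualifiers) was starred as a
        major topic in the source record.
    """

    descriptor: str
    subheadings: tuple[str, ...] = ()
    major_topic: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("MeSH descriptor must be non-empty")


@dataclass(frozen=True)
class MedlineRecord:
    """A single bibliographic record (PMID, title, abstract, MeSH, year)."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_headings: tuple[MeshHeading, ...] = ()
    pub_year: int | None = None
    journal: str | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.pub_year is not None and not 1000 <= self.pub_year <= 9999:
            raise ValueError(f"pub_year must be a 4-digit year, got {self.pub_year!r}")


@dataclass(frozen=True)
class Corpus:
    """An ordered, duplicate-free collection of :class:`MedlineRecord`."""

    records: tuple[MedlineRecord, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise MedlineParseError(f"duplicate PMID {rec.pmid!r} in corpus")
            seen.add(rec.pmid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MedlineRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MedlineRecord:
        return self.records[i]

    @property
    def pmids(self) -> tuple[str, ...]:
        return tuple(r.pmid for r in self.records)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(r.pmid for r in self.records)


# --------------------------------------------------------------------------
# parsing


def _as_text(source: TextSource) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8", errors="replace")
    return source


_YEAR_RE = re.compile(r"\b(\d{4})\b")


def _parse_heading(text: str) -> MeshHeading:
    parts = text.split("/")
    major = any(p.startswith("*") for p in parts)
    parts = [p.lstrip("*") for p in parts]
    return MeshHeading(
        descriptor=parts[0], subheadings=tuple(parts[1:]), major_topic=major
    )


def _iter_blocks(text: str) -> Iterator[tuple[int, str]]:
    """Yield (1-based starting line number, block text) for each record block."""
    lines = text.splitlines()
    start: int | None = None
    buf: list[str] = []
    for i, line in enumerate(lines, start=1):
        if line.strip():
            if start is None:
                start = i
            buf.append(line)
        elif buf:
            assert start is not None
            yield start, "\n".join(buf)
            start, buf = None, []
    if buf:
        assert start is not None
        yield start, "\n".join(buf)


def parse_medline(source: TextSource, label: str = "") -> Corpus:
    """Parse MEDLINE tagged text into a :class:`Corpus`.

    Records are blank-line separated blocks; indented lines continue the
    previous tag.  ``MH`` values are split into descriptor and ``/``-separated
    subheadings, with a leading ``*`` marking the major topic.  The publication
    year is the first 4-digit token of the ``DP`` field.

    Raises
    ------
    MedlineParseError
        On a block without a PMID (names the line number) or a duplicate PMID.
    """
    text = _as_text(source)
    records: list[MedlineRecord] = []
    for lineno, block in _iter_blocks(text):
        parsed = Medline.read(io.StringIO(block + "\n"))
        if "PMID" not in parsed:
            raise MedlineParseError(f"record block starting at line {lineno} has no PMID")
        dp = parsed.get("DP", "")
        m = _YEAR_RE.search(dp)
        records.append(
            MedlineRecord(
                pmid=parsed["PMID"],
                title=parsed.get("TI", ""),
                abstract=parsed.get("AB", ""),
                mesh_headings=tuple(_parse_heading(h) for h in parsed.get("MH", [])),
                pub_year=int(m.group(1)) if m else None,
                journal=parsed.get("JT") or None,
            )
        )
    return Corpus(records=tuple(records), label=label)


def read_medline(path: str | Path, label: str = "") -> Corpus:
    """Read a MEDLINE file; ``"-"`` reads standard input."""
    if str(path) == "-":
        import sys

        return parse_medline(sys.stdin.read(), label=label)
    return parse_medline(Path(path), label=label or str(path))


# --------------------------------------------------------------------------
# writing


def _format_heading(h: MeshHeading) -> str:
    text = h.descriptor + "".join("/" + s for s in h.subheadings)
    return "*" + text if h.major_topic else text


def write_medline(corpus: Corpus, stream: IO[str] | None = None) -> str:
    """Serialize a corpus to MEDLINE tagged text.

    Lines are not wrapped, so the output reparses to an identical corpus.
    An empty abstract or title emits no AB/TI line.
    """
    out = io.StringIO()
    for rec in corpus:
        out.write(f"PMID- {rec.pmid}\n")
        if rec.title:
            out.write(f"TI  - {rec.title}\n")
        if rec.abstract:
            out.write(f"AB  - {rec.abstract}\n")
        for h in rec.mesh_headings:
            out.write(f"MH  - {_format_heading(h)}\n")
        if rec.pub_year is not None:
            out.write(f"DP  - {rec.pub_year}\n")
        if rec.journal:
            out.write(f"JT  - {rec.journal}\n")
        out.write("\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# --------------------------------------------------------------------------
# PMID lists


def read_pmid_list(source: TextSource) -> list[str]:
    """Read a one-PMID-per-line file; blank lines are ignored, order kept."""
    text = _as_text(source)
    pmids: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        token = line.strip()
        if not token:
            continue
        if not token.isdigit():
            raise MedlineParseError(
                f"line {lineno}: expected a numeric PMID, got {token!r}"
            )
        pmids.append(token)
    return pmids


def write_pmid_list(ids: Union[Corpus, Iterable[str]], stream: IO[str] | None = None) -> str:
    if isinstance(ids, Corpus):
        ids = ids.pmids
    text = "".join(f"{pmid}\n" for pmid in ids)
    if stream is not None:
        stream.write(text)
    return text


# --------------------------------------------------------------------------
# subsetting


def sample_corpus(corpus: Corpus, n: int, seed: int) -> Corpus:
    """Draw a uniform random sample of ``n`` records without replacement.

    The same seed always yields the same sample; sampled records keep their
    original corpus order.
    """
    if not 0 <= n <= len(corpus):
        raise ValueError(f"cannot sample {n} records from a corpus of {len(corpus)}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(corpus), size=n, replace=False))
    return Corpus(
        records=tuple(corpus.records[i] for i in idx),
        label=f"{corpus.label} (sample n={n})" if corpus.label else f"sample n={n}",
    )


def filter_by_year(corpus: Corpus, start_year: int, end_year: int) -> Corpus:
    """Keep records with ``start_year <= pub_year <= end_year`` (inclusive).

    Records without a publication year are dropped, mirroring a date-limited
    database search where unindexed dates cannot match.
    """
    if start_year > end_year:
        raise ValueError("start_year must not exceed end_year")
    kept = tuple(
        r
        for r in corpus
        if r.pub_year is not None and start_year <= r.pub_year <= end_year
    )
    return Corpus(records=kept, label=corpus.label)
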