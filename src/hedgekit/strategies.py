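"""Bundled empirically derived nurse-staffing search strategies.

Three ready-made PubMed-dialect strategies for identifying nurse staffing
research (studies relating nurse staffing levels to nursing and patient
outcomes), each trading sensitivity against precision differently:

- ``sensitive`` — casts the widest net; for systematic reviews and alerts.
- ``precise``  — minimises screening burden at the cost of missed records.
- ``balanced`` — a compromise between the two.

They combine differential free-text terms (e.g. ``staffing[tiab]``) with MeSH
headings (e.g. ``"Nursing Staff, Hospital"[mh]``) and serve both as working
filters and as fixtures exercising every feature of the strategy dialect.
"""

from __future__ import annotations

from .query import BooleanStrategy, parse_strategy

__all__ = ["STRATEGY_TEXTS", "builtin_strategy", "builtin_names"]

_SENSITIVE = """\
1\tstaff[tiab] OR staffing[tiab] OR organizational[tiab] OR skill mix[tiab] OR length of stay[tiab] OR medicare[tiab]
2\t"Nursing Staff, Hospital"[mh]
3\t"Personnel Staffing and Scheduling"[mh]
4\t"Intensive Care Units/manpower"[mh]
5\t"Nursing Administration Research"[mh]
6\t#1 OR #2 OR #3 OR #4 OR #5
7\t"health services administration"[mh]
8\tnurse[tiab] OR nurses[tiab] OR hospitals[tiab] OR nursing[tiab]
9\t"hospital units"[mh]
10\t#8 OR #9
11\t#6 AND #7 AND #10
"""

_PRECISE = """\
1\t"Outcome and Process Assessment (Health Care)" [mh]
2\t"Hospital Units" [mh]
3\thospitals[tiab]
4\t#1 OR #2 OR #3
5\tnurse[tiab] or nurses[tiab]
6\tstaffing[tiab]
7\t"Nursing Staff, Hospital" [mh]
8\t#6 OR #7
9\toutcomes[tiab]
10\t#4 AND #5 AND #8 AND #9
"""

_BALANCED = """\
1\t"Outcome and Process Assessment (Health Care)" [mh]
2\t"Hospital Units" [mh]
3\thospitals[tiab]
4\t#1 OR #2 OR #3
5\t(nurse[tiab] OR nurses[tiab]) AND staffing[tiab]
6\t"Nursing Staff, Hospital" [mh]
7\t#5 OR #6
8\t#4 AND #7
"""

STRATEGY_TEXTS: dict[str, str] = {
    "sensitive": _SENSITIVE,
    "precise": _PRECISE,
    "balanced": _BALANCED,
}


def builtin_names() -> list[str]:
    return sorted(STRATEGY_TEXTS)


def builtin_strategy(name: str) -> BooleanStrategy:
    """Parse one of the bundled strategies by name."""
    try:
        text = STRATEGY_TEXTS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin strategy {name!r}; available: {builtin_names()}"
        ) from None
    return parse_strategy(text, name=name)
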