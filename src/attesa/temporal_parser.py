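"""Formal language of temporal waiting-time expressions.

The grammar is a set of pattern *families* (interval, range, precise date,
month+year, bare duration) built from shared, named sub-patterns — a number,
a time unit, a trigger word — so that, e.g., the same time-unit fragment
serves both an interval of time and a precise time.  Families live in a YAML
config and are compiled into plain regular expressions by substituting
``{{NAME}}`` placeholders recursively; users can add families without code
changes.

The scanner matches every family at every character position, keeps maximal
spans per family, applies shared context guards (word boundaries at the match
edges, no digit adjacency, no trailing "fa" = "ago"), and resolves overlaps by
family priority, then span length, then leftmost position.  The result is a
deterministic, non-overlapping, left-to-right list of matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Optional

from ._resources import default_grammar_config

_PLACEHOLDER_RE = re.compile(r"\{\{([A-Z0-9_]+)\}\}")
_AGO_RE = re.compile(r"\s+fa\b")

FAMILY_NAMES = ("interval", "range", "precise_date", "month_year", "bare_duration")

#: canonical unit for each surface token the grammar can capture
UNIT_CANON = {
    "giorno": "day", "giorni": "day", "gg": "day", "g": "day",
    "settimana": "week", "settimane": "week", "sett": "week", "set": "week",
    "mese": "month", "mesi": "month",
    "anno": "year", "anni": "year", "aa": "year",
}


class GrammarError(ValueError):
    """Raised when a family references an undefined sub-pattern or fails to compile."""


@dataclass(frozen=True)
class PatternFamily:
    name: str
    priority: int
    regexes: tuple[re.Pattern, ...]


@dataclass
class Grammar:
    families: dict[str, PatternFamily]
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def normalizer_config(self) -> dict[str, Any]:
        return self.config.get("normalizer", {})


@dataclass
class TemporalMatch:
    """One matched temporal expression on the processed text."""

    span: tuple[int, int]
    family: str
    raw_slice: str
    value: Optional[float] = None
    unit: Optional[str] = None          # canonical: day/week/month/year
    range_low: Optional[float] = None
    range_high: Optional[float] = None
    day: Optional[int] = None
    month: Optional[int] = None
    year: Optional[int] = None
    trigger: Optional[str] = None


def _expand(pattern: str, subpatterns: dict[str, str], family: str, depth: int = 0) -> str:
    if depth > 10:
        raise GrammarError(f"family {family!r}: sub-pattern recursion too deep")

    def repl(m: re.Match) -> str:
        name = m.group(1)
        if name not in subpatterns:
            raise GrammarError(f"family {family!r}: undefined sub-pattern {name!r}")
        return _expand(subpatterns[name], subpatterns, family, depth + 1)

    return _PLACEHOLDER_RE.sub(repl, pattern)


def compile_grammar(config: Optional[dict[str, Any]] = None) -> Grammar:
    """Compile the family patterns, substituting named sub-patterns recursively."""
    if config is None:
        config = default_grammar_config()
    subs = config.get("subpatterns", {})
    families: dict[str, PatternFamily] = {}
    for name, fam in config.get("families", {}).items():
        regexes = []
        for pat in fam["patterns"]:
            expanded = _expand(pat, subs, name)
            try:
                regexes.append(re.compile(expanded))
            except re.error as exc:
                raise GrammarError(f"family {name!r}: invalid pattern: {exc}") from exc
        families[name] = PatternFamily(name=name, priority=int(fam["priority"]),
                                       regexes=tuple(regexes))
    return Grammar(families=families, config=config)


# ---------------------------------------------------------------------------
# shared context guards (applied identically by scanner and oracle)
# ---------------------------------------------------------------------------

def _is_word(c: str) -> bool:
    return c.isalnum() or c == "_"


def passes_guards(text: str, start: int, end: int) -> bool:
    """Edge context checks a candidate span must satisfy regardless of family.

    - the span must start and end on word boundaries (so a unit never matches
      inside a longer word, and a number never matches inside an ICD code);
    - the span must not be followed by " fa" ("ago"): that is a past event.
    """
    if start >= end:
        return False
    if start > 0 and _is_word(text[start - 1]) and _is_word(text[start]):
        return False
    if end < len(text) and _is_word(text[end - 1]) and _is_word(text[end]):
        return False
    if _AGO_RE.match(text, end):
        return False
    return True


def _match_to_obj(family: str, m: re.Match, span: tuple[int, int], text: str) -> TemporalMatch:
    g = m.groupdict()
    out = TemporalMatch(span=span, family=family, raw_slice=text[span[0]:span[1]])
    if g.get("unit"):
        out.unit = UNIT_CANON.get(g["unit"])
    if g.get("value"):
        out.value = float(g["value"])
    if g.get("low"):
        out.range_low = float(g["low"])
    if g.get("high"):
        out.range_high = float(g["high"])
    if g.get("day"):
        out.day = int(g["day"])
    if g.get("month"):
        out.month = int(g["month"])
    if g.get("year"):
        out.year = int(g["year"])
    if g.get("monthname"):
        from ._resources import default_lexicon

        # day completion to the 1st is the normalizer's job; only the month
        # number is resolved here
        out.month = default_lexicon()["months"][g["monthname"]]
    if g.get("trigger"):
        out.trigger = g["trigger"]
    return out


def _family_candidates(fam: PatternFamily, text: str) -> list[tuple[tuple[int, int], re.Match]]:
    """All guard-passing matches of a family, maximal by span containment."""
    raw: list[tuple[tuple[int, int], re.Match]] = []
    for rx in fam.regexes:
        for i in range(len(text)):
            m = rx.match(text, i)
            if m is None or m.end() == i:
                continue
            if passes_guards(text, i, m.end()):
                raw.append(((i, m.end()), m))
    # keep spans not strictly contained in another span of the same family
    keep: list[tuple[tuple[int, int], re.Match]] = []
    for span, m in raw:
        contained = any(
            (o[0] <= span[0] and span[1] <= o[1] and o != span) for o, _ in raw
        )
        if not contained:
            keep.append((span, m))
    # dedupe identical spans (two alternative patterns may both match)
    seen: set[tuple[int, int]] = set()
    out = []
    for span, m in keep:
        if span not in seen:
            seen.add(span)
            out.append((span, m))
    return out


def scan(grammar: Grammar, text: str) -> list[TemporalMatch]:
    """All maximal, non-overlapping temporal matches, left to right.

    Overlaps are resolved by family priority, then longest span, then
    leftmost start — a deterministic total order.
    """
    candidates: list[tuple[int, int, int, str, re.Match, tuple[int, int]]] = []
    for fam in grammar.families.values():
        for span, m in _family_candidates(fam, text):
            candidates.append(
                (-fam.priority, -(span[1] - span[0]), span[0], fam.name, m, span)
            )
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    chosen: list[tuple[str, re.Match, tuple[int, int]]] = []
    occupied: list[tuple[int, int]] = []
    for _, _, _, name, m, span in candidates:
        if any(span[0] < e and s < span[1] for s, e in occupied):
            continue
        occupied.append(span)
        chosen.append((name, m, span))
    chosen.sort(key=lambda c: c[2][0])
    return [_match_to_obj(name, m, span, text) for name, m, span in chosen]
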