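"""Post-processing: from temporal matches to Normalized Temporal Information.

An NTI is the canonical waiting time in days that a referral text prescribes.
Post-processing completes missing information (a month+year expression gets
day 1), deletes inconsistent values (dates before the referral, impossible
calendar dates, horizons beyond two years), selects one indication when a
text contains several, and converts everything to days.

Conversion conventions: 1 week = 7 days, 1 month = 30 days, 1 year = 365
days.  A range takes its day value from the upper bound by default (being
late starts after the outer bound); configurable to lower/midpoint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Any, Iterable, Optional

from ._resources import default_lexicon
from .preprocess import PreprocessedText, preprocess
from .temporal_parser import Grammar, TemporalMatch, compile_grammar, scan

_UNIT_DAYS = {"day": 1, "week": 7, "month": 30, "year": 365}

DEFAULT_MAX_HORIZON = 730
DEFAULT_RANGE_POLICY = "upper"


@dataclass
class NTI:
    """Normalized temporal information: a prescribed waiting time in days."""

    days: int
    value: float
    unit: str                      # day/week/month/year/date
    kind: str                      # interval/range/precise_date
    source_span: tuple[int, int]   # [start, end) on the RAW text
    anchor_date: Optional[date] = None


def to_days(value: float, unit: str) -> int:
    """Convert a duration to days (week x7, month x30, year x365)."""
    if value <= 0:
        raise ValueError(f"non-positive duration value: {value}")
    if unit not in _UNIT_DAYS:
        raise ValueError(f"unknown unit: {unit!r}")
    return round(value * _UNIT_DAYS[unit])


def _resolve_year(year: int, window_base: int = 2000) -> int:
    if year < 100:
        return window_base + year if year < 50 else 1900 + year
    return year


def resolve_match(
    match: TemporalMatch,
    referral_date: Optional[date],
    raw_span: tuple[int, int],
    range_policy: str = DEFAULT_RANGE_POLICY,
    two_digit_year_window: int = 2000,
) -> Optional[NTI]:
    """Turn a scanner match into an NTI, or None when inconsistent.

    Date-kind matches are anchored to the referral date (the physician wrote
    the text then); a target on or before the referral date is a past-event
    mention and is deleted.
    """
    fam = match.family
    if fam in ("interval", "bare_duration"):
        return NTI(days=to_days(match.value, match.unit), value=match.value,
                   unit=match.unit, kind="interval", source_span=raw_span)
    if fam == "range":
        low, high = match.range_low, match.range_high
        if low > high:
            return None  # inconsistent bounds
        if range_policy == "upper":
            v = high
        elif range_policy == "lower":
            v = low
        elif range_policy == "midpoint":
            v = (low + high) / 2
        else:
            raise ValueError(f"unknown range policy: {range_policy!r}")
        if v <= 0:
            return None
        return NTI(days=to_days(v, match.unit), value=v, unit=match.unit,
                   kind="range", source_span=raw_span)
    if fam in ("precise_date", "month_year"):
        if referral_date is None:
            return None
        day = match.day if match.day is not None else 1  # completion: 1st of month
        year = _resolve_year(match.year, two_digit_year_window)
        try:
            target = date(year, match.month, day)
        except ValueError:
            return None  # impossible calendar date -> deleted as inconsistent
        days = (target - referral_date).days
        if days <= 0:
            return None  # past-event mention
        return NTI(days=days, value=float(days), unit="date", kind="precise_date",
                   source_span=raw_span, anchor_date=referral_date)
    raise ValueError(f"unknown family: {fam!r}")


def select_indication(
    matches: list[TemporalMatch],
    processed_text: str,
    keywords: Optional[Iterable[str]] = None,
) -> Optional[TemporalMatch]:
    """Pick one match when a text carries several temporal indications.

    The match nearest (in tokens) to a follow-up keyword wins; ties go to the
    leftmost match.  With no keyword in the text all distances are infinite
    and the leftmost match wins.
    """
    if not matches:
        return None
    if len(matches) == 1:
        return matches[0]
    if keywords is None:
        keywords = default_lexicon()["followup_keywords"]

    tokens = [(m.start(), m.end()) for m in re.finditer(r"\S+", processed_text)]

    def token_range(span: tuple[int, int]) -> tuple[int, int]:
        idx = [i for i, (s, e) in enumerate(tokens) if s < span[1] and span[0] < e]
        return (min(idx), max(idx)) if idx else (0, 0)

    kw_positions: list[tuple[int, int]] = []
    for kw in keywords:
        for m in re.finditer(r"(?<!\w)" + re.escape(kw) + r"(?!\w)", processed_text):
            kw_positions.append(token_range((m.start(), m.end())))

    def distance(span: tuple[int, int]) -> float:
        lo, hi = token_range(span)
        best = float("inf")
        for klo, khi in kw_positions:
            if khi < lo:
                d = lo - khi
            elif hi < klo:
                d = klo - hi
            else:
                d = 0
            best = min(best, d)
        return best

    return min(matches, key=lambda m: (distance(m.span), m.span[0]))


def validate_nti(nti: Optional[NTI], max_horizon: int = DEFAULT_MAX_HORIZON) -> Optional[NTI]:
    """Delete inconsistent values: non-positive or beyond the horizon."""
    if nti is None:
        return None
    if nti.days <= 0 or nti.days > max_horizon:
        return None
    return nti


class Pipeline:
    """End-to-end extractor: preprocess -> scan -> select -> resolve -> validate."""

    def __init__(self, grammar: Optional[Grammar] = None, config: Optional[dict[str, Any]] = None):
        self.grammar = grammar or compile_grammar()
        cfg = dict(self.grammar.normalizer_config)
        if config:
            cfg.update(config)
        self.max_horizon = int(cfg.get("max_horizon_days", DEFAULT_MAX_HORIZON))
        self.range_policy = str(cfg.get("range_policy", DEFAULT_RANGE_POLICY))
        self.two_digit_year_window = int(cfg.get("two_digit_year_window", 2000))
        self.followup_keywords = list(
            cfg.get("followup_keywords", default_lexicon()["followup_keywords"])
        )

    def preprocess(self, text: str) -> PreprocessedText:
        return preprocess(text)

    def extract(self, raw_text: str, referral_date: Optional[date] = None) -> Optional[NTI]:
        """Extract the NTI from one raw clinical question (None = no indication)."""
        pre = self.preprocess(raw_text)
        matches = scan(self.grammar, pre.processed)
        picked = select_indication(matches, pre.processed, self.followup_keywords)
        if picked is None:
            return None
        raw_span = pre.span_to_raw(*picked.span)
        nti = resolve_match(picked, referral_date, raw_span,
                            range_policy=self.range_policy,
                            two_digit_year_window=self.two_digit_year_window)
        return validate_nti(nti, self.max_horizon)


def extract_nti(raw_text: str, referral_date: Optional[date] = None,
                pipeline: Optional[Pipeline] = None) -> Optional[NTI]:
    """Convenience wrapper around :class:`Pipeline` with the default grammar."""
    return (pipeline or _default_pipeline()).extract(raw_text, referral_date)


_PIPELINE: Optional[Pipeline] = None


def _default_pipeline() -> Pipeline:
    global _PIPELINE
    if _PIPELINE is None:
        _PIPELINE = Pipeline()
    return _PIPELINE
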