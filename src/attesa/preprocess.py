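"""Text simplification for Italian referral clinical questions.

The clinical question is free text written in a hurry: uppercase, abbreviated,
misspelt, and full of numbers that are not waiting times (ICD codes, gestational
weeks, past exam dates).  Before parsing, the text is simplified by six steps,
applied in this order:

1. ``lowercase``
2. ``words_to_digits`` — Italian cardinal words (and a few temporal ordinals)
   become digits, so "tra tre mesi" and "tra 3 mesi" parse identically;
3. ``remove_pregnancy_context`` — gestational-week spans near a pregnancy
   trigger word are deleted ("alla 32 settimana di gravidanza" is an age, not a
   waiting time);
4. ``prune_punctuation`` — punctuation becomes whitespace, except ``/ - .``
   between digits, which date expressions need;
5. ``lemmatize_units`` — plural time units map to their lemma (mesi -> mese);
   the backend is pluggable, the default is a closed dictionary over the
   temporal lexicon;
6. ``correct_typos`` — tokens of length >= 4 at edit distance 1 from exactly
   one temporal-lexicon entry are replaced ("mesii" -> "mesi"); ambiguous or
   short tokens are left alone, so abbreviations survive.

Stop words (tra, fra, entro, in, a, ...) are deliberately retained: they are
the triggers that distinguish a waiting time from any other number.

Every step is tracked through a character offset map, so a span found on the
processed text can be projected back onto the raw text.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import edlib

from ._resources import default_lexicon, default_numbers

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[a-zà-ÿ]+")
_TOKEN_RE = re.compile(r"\S+")
_NUM_TOKEN_RE = re.compile(r"\d{1,3}$")

#: tokens that introduce a prospective duration; a number they introduce is
#: never treated as a gestational week
_PROSPECTIVE_TRIGGERS = frozenset({"tra", "fra", "entro", "dopo", "ogni"})

#: clause-ending characters: the pregnancy window never crosses them
_CLAUSE_END = ";.!?,"

DEFAULT_STEPS = (
    "lowercase",
    "words_to_digits",
    "remove_pregnancy_context",
    "prune_punctuation",
    "lemmatize_units",
    "correct_typos",
)


@dataclass
class PreprocessedText:
    """Processed text plus the bookkeeping to get back to the raw string."""

    raw: str
    processed: str
    #: offset_map[i] = index into ``raw`` of processed character i (monotone)
    offset_map: list[int]
    applied_steps: list[str]
    #: (raw_span, replacement) for every lexical substitution performed
    corrections: list[tuple[tuple[int, int], str]] = field(default_factory=list)

    def span_to_raw(self, start: int, end: int) -> tuple[int, int]:
        """Project a [start, end) span on the processed text onto the raw text."""
        if not self.offset_map or start >= end:
            i = self.offset_map[start] if start < len(self.offset_map) else len(self.raw)
            return (i, i)
        s = self.offset_map[start]
        last = self.offset_map[end - 1]
        return (s, min(last + 1, len(self.raw)))


# ---------------------------------------------------------------------------
# edit machinery: every step is expressed as a list of (start, end, repl)
# edits on the current text, which keeps the offset map consistent
# ---------------------------------------------------------------------------

Edit = tuple[int, int, str]


def _apply_edits(text: str, omap: list[int], edits: list[Edit]) -> tuple[str, list[int]]:
    if not edits:
        return text, omap
    edits = sorted(edits)
    out: list[str] = []
    new_map: list[int] = []
    prev = 0
    for s, e, rep in edits:
        if s < prev:
            raise ValueError("overlapping edits")
        out.append(text[prev:s])
        new_map.extend(omap[prev:s])
        if rep:
            start_anchor = omap[s] if s < len(omap) else (omap[-1] + 1 if omap else 0)
            end_anchor = omap[e - 1] if e > s and e - 1 < len(omap) else start_anchor
            out.append(rep)
            # spread replacement chars over the raw span so projected spans
            # cover the whole replaced region
            new_map.extend(min(start_anchor + k, end_anchor) for k in range(len(rep)))
        prev = e
    out.append(text[prev:])
    new_map.extend(omap[prev:])
    return "".join(out), new_map


def _identity_map(text: str) -> list[int]:
    return list(range(len(text)))


# ---------------------------------------------------------------------------
# step 1: lowercase
# ---------------------------------------------------------------------------

def lowercase(text: str) -> str:
    """Length-preserving Unicode lowercase (chars that would expand are kept)."""
    return "".join(c.lower() if len(c.lower()) == 1 else c for c in text)


# ---------------------------------------------------------------------------
# step 2: literal numbers -> digits
# ---------------------------------------------------------------------------

def _number_lexicons():
    numbers = default_numbers()
    return numbers["number_words"], numbers["ordinal_words"]


#: homographs of common function words: replaced only when a time unit follows
_AMBIGUOUS_NUMBER_WORDS = frozenset({"un", "una", "sei"})

_ORDINAL_SUFFIXES = ("esima", "esimo", "esime", "esimi")


def _ordinal_value(token: str, number_words: dict[str, int]) -> Optional[int]:
    for suf in _ORDINAL_SUFFIXES:
        if token.endswith(suf) and len(token) > len(suf):
            stem = token[: -len(suf)]
            for cand in (stem, stem + "a", stem + "e", stem + "i", stem + "o", stem + "u"):
                if cand in number_words:
                    return number_words[cand]
    return None


def _unit_like_tokens() -> frozenset[str]:
    lex = default_lexicon()
    return frozenset(lex["unit_tokens"])


def _words_to_digits_edits(text: str) -> list[Edit]:
    number_words, ordinal_words = _number_lexicons()
    units = _unit_like_tokens()
    edits: list[Edit] = []
    for m in _WORD_RE.finditer(text):
        tok = m.group()
        value: Optional[int] = None
        if tok in number_words:
            value = number_words[tok]
        elif tok in ordinal_words:
            value = ordinal_words[tok]
        else:
            value = _ordinal_value(tok, number_words)
        if value is None:
            continue
        if tok in _AMBIGUOUS_NUMBER_WORDS:
            nxt = _WORD_RE.search(text, m.end())
            if nxt is None or nxt.group() not in units:
                continue
        edits.append((m.start(), m.end(), str(value)))
    return edits


def words_to_digits(text: str) -> str:
    """Replace Italian cardinal/ordinal number words with digits."""
    out, _ = _apply_edits(text, _identity_map(text), _words_to_digits_edits(text))
    return out


# ---------------------------------------------------------------------------
# step 3: pregnancy context removal
# ---------------------------------------------------------------------------

def _tokenize(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _norm_token(tok: str) -> str:
    return tok.strip(".,;:!?()[]\"'")


def _pregnancy_edits(text: str, window: int = 4) -> list[Edit]:
    lex = default_lexicon()
    triggers = set(lex["pregnancy_triggers"])
    week_units = set(lex["pregnancy_week_units"])
    attachers = set(lex["pregnancy_attachers"])

    toks = _tokenize(text)
    norm = [_norm_token(t) for t, _, _ in toks]
    # clause segmentation: a token ending with clause punctuation closes a segment
    seg = []
    cur = 0
    for t, _, _ in toks:
        seg.append(cur)
        if t and t[-1] in _CLAUSE_END:
            cur += 1

    trigger_idx = [i for i, n in enumerate(norm) if n in triggers]
    if not trigger_idx:
        return []

    edits: list[Edit] = []
    for i in range(len(toks) - 1):
        if not _NUM_TOKEN_RE.fullmatch(norm[i]):
            continue
        if norm[i + 1] not in week_units:
            continue
        if i > 0 and norm[i - 1] in _PROSPECTIVE_TRIGGERS:
            continue  # "tra 2 settimane" is a waiting time, never gestational
        near = [t for t in trigger_idx
                if seg[t] == seg[i] and (abs(t - i) <= window or abs(t - (i + 1)) <= window)]
        if not near:
            continue
        lo = min([i] + near)
        hi = max([i + 1] + near)
        if lo == i and i > 0 and norm[i - 1] in attachers and seg[i - 1] == seg[i]:
            lo = i - 1
        start = toks[lo][1]
        end = toks[hi][2]
        # absorb the preceding whitespace run so no double space is left behind
        while start > 0 and text[start - 1].isspace():
            start -= 1
        if start == 0:
            while end < len(text) and text[end].isspace():
                end += 1
        edits.append((start, end, ""))
    # merge overlapping deletions
    edits.sort()
    merged: list[Edit] = []
    for s, e, _ in edits:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]), "")
        else:
            merged.append((s, e, ""))
    return merged


def remove_pregnancy_context(text: str, window: int = 4) -> str:
    """Delete gestational number+week spans near a pregnancy trigger.

    The window is ±``window`` tokens and never crosses clause punctuation;
    the trigger word and a glued preposition are deleted with the span.
    Applied to fixpoint so that nothing gestational survives.
    """
    out = text
    for _ in range(5):
        edits = _pregnancy_edits(out, window)
        if not edits:
            break
        out, _ = _apply_edits(out, _identity_map(out), edits)
    return out


# ---------------------------------------------------------------------------
# step 4: punctuation pruning
# ---------------------------------------------------------------------------

def _punct_edits(text: str) -> list[Edit]:
    edits: list[Edit] = []
    for i, c in enumerate(text):
        if c.isalnum() or c.isspace():
            continue
        if c in "/-." and 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
            continue  # date separator
        edits.append((i, i + 1, " "))
    return edits


def _whitespace_edits(text: str) -> list[Edit]:
    edits: list[Edit] = []
    for m in re.finditer(r"\s+", text):
        if m.start() == 0 or m.end() == len(text):
            edits.append((m.start(), m.end(), ""))
        elif len(m.group()) > 1 or m.group() != " ":
            edits.append((m.start(), m.end(), " "))
    return edits


def prune_punctuation(text: str) -> str:
    """Replace punctuation with spaces, keeping ``/ - .`` between digits."""
    out, omap = _apply_edits(text, _identity_map(text), _punct_edits(text))
    out, _ = _apply_edits(out, omap, _whitespace_edits(out))
    return out


# ---------------------------------------------------------------------------
# step 5: unit lemmatization (pluggable)
# ---------------------------------------------------------------------------

Lemmatizer = Callable[[str], Optional[str]]


def dictionary_lemmatizer(token: str) -> Optional[str]:
    """Closed-dictionary lemmatizer over the temporal lexicon."""
    return default_lexicon()["unit_lemmas"].get(token)


def get_lemmatizer(backend: str = "dict") -> Lemmatizer:
    """Return a lemmatizer backend; unknown/unavailable backends fall back
    to the dictionary with a logged warning."""
    if backend == "dict":
        return dictionary_lemmatizer
    if backend == "spacy":
        try:  # pragma: no cover - spaCy is optional
            import spacy

            nlp = spacy.load("it_core_news_sm", disable=["parser", "ner"])

            def _spacy_lemma(token: str) -> Optional[str]:
                doc = nlp(token)
                return doc[0].lemma_ if len(doc) else None

            return _spacy_lemma
        except Exception:
            logger.warning("spaCy backend unavailable; falling back to dictionary lemmatizer")
            return dictionary_lemmatizer
    logger.warning("unknown lemmatizer backend %r; falling back to dictionary", backend)
    return dictionary_lemmatizer


def _lemmatize_edits(text: str, lemmatizer: Lemmatizer) -> list[Edit]:
    edits: list[Edit] = []
    for m in _WORD_RE.finditer(text):
        lemma = lemmatizer(m.group())
        if lemma is not None and lemma != m.group():
            edits.append((m.start(), m.end(), lemma))
    return edits


def lemmatize_units(text: str, lemmatizer: Optional[Lemmatizer] = None) -> str:
    """Map temporal tokens to their lemma (mesi -> mese, ...)."""
    lemmatizer = lemmatizer or dictionary_lemmatizer
    out, _ = _apply_edits(text, _identity_map(text), _lemmatize_edits(text, lemmatizer))
    return out


# ---------------------------------------------------------------------------
# step 6: partial typo correction
# ---------------------------------------------------------------------------

def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _typo_edits(
    text: str, lexicon: Iterable[str], max_edit_distance: int = 1, min_len: int = 4
) -> list[Edit]:
    lex = list(lexicon)
    lexset = set(lex)
    edits: list[Edit] = []
    for m in _WORD_RE.finditer(text):
        tok = m.group()
        if len(tok) < min_len or tok in lexset:
            continue
        best: list[str] = []
        best_d = max_edit_distance + 1
        for w in lex:
            if abs(len(w) - len(tok)) > max_edit_distance:
                continue
            d = _edit_distance(tok, w)
            if d < best_d:
                best, best_d = [w], d
            elif d == best_d:
                best.append(w)
        if best_d <= max_edit_distance and len(best) == 1:
            edits.append((m.start(), m.end(), best[0]))
    return edits


def correct_typos(
    text: str,
    lexicon: Optional[Iterable[str]] = None,
    max_edit_distance: int = 1,
) -> str:
    """Replace near-miss spellings of temporal keywords (unique candidate only)."""
    if lexicon is None:
        lexicon = default_lexicon()["typo_lexicon"]
    out, _ = _apply_edits(
        text, _identity_map(text), _typo_edits(text, lexicon, max_edit_distance)
    )
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def preprocess(
    text: str,
    lemmatizer: Optional[Lemmatizer] = None,
    typo_lexicon: Optional[Iterable[str]] = None,
    max_edit_distance: int = 1,
    pregnancy_window: int = 4,
) -> PreprocessedText:
    """Run the six simplification steps, tracking offsets back to ``text``."""
    lemmatizer = lemmatizer or dictionary_lemmatizer
    if typo_lexicon is None:
        typo_lexicon = default_lexicon()["typo_lexicon"]

    omap = _identity_map(text)
    corrections: list[tuple[tuple[int, int], str]] = []

    def record(edits: list[Edit]) -> None:
        for s, e, rep in edits:
            if not rep:
                continue
            raw_s = omap[s] if s < len(omap) else len(text)
            raw_e = (omap[e - 1] + 1) if e > s and e - 1 < len(omap) else raw_s
            corrections.append(((raw_s, raw_e), rep))

    cur = lowercase(text)

    edits = _words_to_digits_edits(cur)
    record(edits)
    cur, omap = _apply_edits(cur, omap, edits)

    for _ in range(5):
        edits = _pregnancy_edits(cur, pregnancy_window)
        if not edits:
            break
        cur, omap = _apply_edits(cur, omap, edits)

    cur, omap = _apply_edits(cur, omap, _punct_edits(cur))
    cur, omap = _apply_edits(cur, omap, _whitespace_edits(cur))

    cur, omap = _apply_edits(cur, omap, _lemmatize_edits(cur, lemmatizer))

    edits = _typo_edits(cur, typo_lexicon, max_edit_distance)
    record(edits)
    cur, omap = _apply_edits(cur, omap, edits)

    return PreprocessedText(
        raw=text,
        processed=cur,
        offset_map=omap,
        applied_steps=list(DEFAULT_STEPS),
        corrections=corrections,
    )
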