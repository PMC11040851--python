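"""Grammar compilation and scanning, including the all-substrings oracle."""

import re

import pytest

from attesa import GeneratorConfig, GrammarError, compile_grammar, generate_corpus, scan
from attesa.nti_normalizer import Pipeline
from attesa.temporal_parser import passes_guards
from attesa._resources import default_grammar_config


def test_default_grammar_has_five_families(grammar):
    assert set(grammar.families) == {
        "interval", "range", "precise_date", "month_year", "bare_duration"
    }


def test_undefined_subpattern_is_fatal_and_names_family():
    cfg = {
        "subpatterns": {"NUM": r"\d+"},
        "families": {"broken": {"priority": 1, "patterns": ["{{UNITT}}"]}},
    }
    with pytest.raises(GrammarError, match="broken"):
        compile_grammar(cfg)


def test_new_family_composes_from_existing_subpatterns():
    cfg = {k: dict(v) for k, v in default_grammar_config().items()
           if k in ("subpatterns", "families")}
    cfg["families"] = dict(cfg["families"])
    cfg["families"]["slash_duration"] = {
        "priority": 10,
        "patterns": ["(?P<value>{{NUM}})\\s*/\\s*(?P<unit>{{UNIT}})"],
    }
    g = compile_grammar(cfg)
    assert "slash_duration" in g.families
    # existing families unchanged
    assert [m.family for m in scan(g, "controllo tra 3 mese")] == ["interval"]


@pytest.mark.parametrize(
    "text, families, captures",
    [
        ("controllo tra 3 mese", ["interval"], dict(value=3.0, unit="month")),
        ("dermatite", [], {}),
        ("rivalutazione tra 3 e 6 mese", ["range"],
         dict(range_low=3.0, range_high=6.0, unit="month")),
        ("entro il 15/03/2022", ["precise_date"], dict(day=15, month=3, year=2022)),
        ("controllo 3-6 mese", ["bare_duration", "range"], {}),
        ("controllo a ottobre 2022", ["month_year"], dict(month=10, year=2022)),
        ("fup entro 30 gg", ["interval"], dict(value=30.0, unit="day")),
        ("controllo 6 mese", ["bare_duration"], dict(value=6.0, unit="month")),
        ("fra circa 2 settimana", ["interval"], dict(value=2.0, unit="week")),
        ("rm il 12.01.22", ["precise_date"], dict(day=12, month=1, year=22)),
    ],
)
def test_scan_families_and_captures(grammar, text, families, captures):
    matches = scan(grammar, text)
    got = [m.family for m in matches]
    if len(families) > 1:  # any of the listed families is acceptable
        assert len(matches) == 1 and got[0] in families
    else:
        assert got == families
    for k, v in captures.items():
        if matches and not (len(families) > 1):
            assert getattr(matches[0], k) == v


@pytest.mark.parametrize(
    "text",
    [
        "01282 altre forme di tubercolosi",   # ICD code: digits never split
        "scan osseo 07 20 neg",               # past exam shorthand, no unit
        "intervento 2 mese fa",               # "ago" guard
        "eseguito tra 3 mese fa",             # "ago" guard on interval
        "emoglobina 12 grammi",               # unit never inside a longer word
        "regolarizzazione 4 dito mano dx",
    ],
)
def test_scan_rejects_confounders(grammar, text):
    assert scan(grammar, text) == []


def test_scan_is_deterministic(grammar):
    text = "controllo tra 3 mese e rx 12/01/2022 e fup 2 settimana"
    runs = [tuple((m.span, m.family) for m in scan(grammar, text)) for _ in range(3)]
    assert len(set(runs)) == 1


def test_scan_matches_are_nonoverlapping_and_ordered(grammar):
    text = "controllo tra 3 mese poi rivalutazione tra 2 e 4 settimana"
    matches = scan(grammar, text)
    assert len(matches) >= 2
    for a, b in zip(matches, matches[1:]):
        assert a.span[1] <= b.span[0]


def oracle_scan(grammar, text):
    """Brute force: test every substring against every family independently,
    keep spans maximal per family, then the same priority resolution."""
    cands = []
    for fam in grammar.families.values():
        raw = []
        for rx in fam.regexes:
            for i in range(len(text)):
                for j in range(i + 1, len(text) + 1):
                    if rx.fullmatch(text, i, j) and passes_guards(text, i, j):
                        raw.append((i, j))
        keep = [s for s in set(raw)
                if not any(o[0] <= s[0] and s[1] <= o[1] and o != s for o in raw)]
        for s in keep:
            cands.append((-fam.priority, -(s[1] - s[0]), s[0], fam.name, s))
    cands.sort()
    chosen, occupied = [], []
    for _, _, _, name, s in cands:
        if any(s[0] < e and b < s[1] for b, e in occupied):
            continue
        occupied.append(s)
        chosen.append((s, name))
    return sorted(chosen)


def test_scanner_equals_oracle_on_generated_texts(grammar):
    cfg = GeneratorConfig(n_texts=300, seed=17, prevalence=0.5,
                          distractor_rate=0.5, typo_rate=0.05)
    texts, _ = generate_corpus(cfg)
    pipe = Pipeline(grammar)
    for t in texts:
        processed = pipe.preprocess(t).processed
        got = sorted((m.span, m.family) for m in scan(grammar, processed))
        assert got == oracle_scan(grammar, processed), processed
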