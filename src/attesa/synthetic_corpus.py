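"""Synthetic annotated referral corpora and referral tables.

The regional referral data are private; this module generates corpora with
the statistical structure the analysis assumes, so every other module is
testable without any download:

- ~2% of follow-up texts carry a waiting-time indication, phrased the way
  Italian physicians write them (triggers, abbreviations, number words,
  uppercase bursts);
- negatives are diagnosis stubs, a configurable fraction of which carry
  *distractor* temporal material — past month+year mentions, gestational
  weeks, ICD codes, "07 20"-style past exam dates, "N mesi fa" — that a
  correct extractor must not turn into waiting times;
- typos are injected on temporal tokens of positive phrases as single
  character edits, at a configurable rate;
- referral tables get coherent dates (referral <= booking <= first proposed
  <= accepted) with the gap between booking and first proposed drawn from a
  delay model targeting a configurable fraction of delayed exams.

Generation is a pure function of (config, seed): the same config yields
byte-identical corpora.

A held-out "unseen phrasing" template subset (``include_unseen``) produces
positive phrasings deliberately outside the default grammar, for studying
recall limits; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional

import numpy as np

from .nti_normalizer import to_days
from .referral_io import GoldAnnotation, ReferralRecord

# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

#: diagnosis stubs in the style of real clinical questions; none of their
#: tokens is within edit distance 1 of the typo-correction lexicon
DIAGNOSIS_STUBS = [
    "dermatite",
    "diabete mellito scompensato",
    "f.a. cronica",
    "scompenso cardiaco",
    "ipertensione arteriosa",
    "tiroidite di hashimoto",
    "gonartrosi dx",
    "lombalgia cronica",
    "psoriasi diffusa",
    "asma bronchiale",
    "fibrillazione atriale parossistica",
    "esiti frattura polso",
    "neoplasia prostatica",
    "calcolosi renale",
    "epatopatia cronica",
    "anemia sideropenica",
    "glaucoma cronico",
    "cataratta senile",
    "dislipidemia",
    "bpco riacutizzata",
    "cefalea muscolotensiva",
    "sindrome del tunnel carpale",
    "artrite reumatoide",
    "morbo di crohn",
    "colite ulcerosa",
    "ernia discale l4 l5",
    "regolarizzazione 4 dito mano dx",
    "ca mammario in follow up",
    "sarcoma di ewing emibacino sx",
]

FOLLOWUP_KEYWORDS = ["controllo", "visita di controllo", "rivalutazione", "follow up", "fup"]
TRIGGERS = ["tra", "fra", "entro", "dopo", "a", "ogni"]
UNIT_WORDS = {
    "day": ("giorno", "giorni"),
    "week": ("settimana", "settimane"),
    "month": ("mese", "mesi"),
    "year": ("anno", "anni"),
}
UNIT_ABBREV = {"day": ["gg"], "week": ["sett"], "month": [], "year": ["aa"]}
NUMBER_WORDS = {1: "un", 2: "due", 3: "tre", 4: "quattro", 6: "sei", 8: "otto", 12: "dodici"}
MONTH_NAMES = ["gennaio", "febbraio", "marzo", "aprile", "maggio", "giugno", "luglio",
               "agosto", "settembre", "ottobre", "novembre", "dicembre"]

#: plausible value ranges per unit, within the 730-day horizon
VALUE_RANGES = {"day": (5, 30), "week": (1, 8), "month": (1, 24), "year": (1, 2)}

ATS_IDS = [f"ATS{i}" for i in range(1, 9)]
SPECIALIST_TYPES = ["cardiologia", "ortopedia", "diabetologia", "oncologia",
                    "nefrologia", "pneumologia", "dermatologia", "neurologia",
                    "oculistica", "endocrinologia"]
RADIOLOGY_TYPES = ["rm", "tc", "rx", "ecografia", "mammografia"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the setting the analysis targets: 2% prevalence of
    waiting-time indications among follow-up texts, 16% of indicated exams
    delayed, delayed delays with median ~6 and mean ~19 days.
    """

    n_texts: int = 10_000
    prevalence: float = 0.02
    distractor_rate: float = 0.2
    typo_rate: float = 0.0
    abbreviation_rate: float = 0.3
    uppercase_rate: float = 0.2
    seed: int = 0
    anchor_date: date = date(2021, 6, 15)
    referral_period: tuple[date, date] = (date(2021, 1, 1), date(2021, 12, 31))
    max_booking_lag: int = 30
    pct_delayed: float = 0.16
    delay_lognorm_mu: float = 1.79    # median exp(mu) ~ 6 days
    delay_lognorm_sigma: float = 1.52  # mean ~ 19 days
    timely_mean_days: float = 45.0
    postponement_rate: float = 0.2
    max_postponement: int = 30
    include_unseen: bool = False

    def validate(self) -> None:
        if self.n_texts <= 0:
            raise ValueError("n_texts must be positive")
        for name in ("prevalence", "distractor_rate", "typo_rate",
                     "abbreviation_rate", "uppercase_rate", "pct_delayed",
                     "postponement_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class _Positive:
    text: str
    value: float
    unit: str
    days: int


# ---------------------------------------------------------------------------
# positive phrases
# ---------------------------------------------------------------------------

def _unit_surface(rng: np.random.Generator, unit: str, value: int,
                  abbreviation_rate: float, allow_word_number: bool) -> str:
    abbrevs = UNIT_ABBREV[unit]
    if abbrevs and not allow_word_number and rng.random() < abbreviation_rate:
        return rng.choice(abbrevs)
    sing, plur = UNIT_WORDS[unit]
    return sing if value == 1 else plur


def _duration_phrase(rng: np.random.Generator, cfg: GeneratorConfig) -> _Positive:
    unit = rng.choice(["day", "week", "month", "year"], p=[0.15, 0.25, 0.5, 0.1])
    lo, hi = VALUE_RANGES[unit]
    value = int(rng.integers(lo, hi + 1))
    as_word = value in NUMBER_WORDS and rng.random() < 0.25
    unit_txt = _unit_surface(rng, unit, value, cfg.abbreviation_rate, as_word)
    num_txt = NUMBER_WORDS[value] if as_word else str(value)

    style = rng.choice(["trigger", "kw_trigger", "bare"], p=[0.3, 0.5, 0.2])
    trg = rng.choice(TRIGGERS)
    kw = rng.choice(FOLLOWUP_KEYWORDS)
    if style == "trigger":
        phrase = f"{trg} {num_txt} {unit_txt}"
    elif style == "kw_trigger":
        phrase = f"{kw} {trg} {num_txt} {unit_txt}"
    else:
        phrase = f"{kw} {num_txt} {unit_txt}"
    return _Positive(text=phrase, value=float(value), unit=unit,
                     days=to_days(value, unit))


def _range_phrase(rng: np.random.Generator, cfg: GeneratorConfig) -> _Positive:
    unit = rng.choice(["week", "month"], p=[0.3, 0.7])
    lo_b, hi_b = VALUE_RANGES[unit]
    low = int(rng.integers(lo_b, hi_b))
    high = int(rng.integers(low + 1, hi_b + 1))
    unit_txt = _unit_surface(rng, unit, high, cfg.abbreviation_rate, False)
    kw = rng.choice(FOLLOWUP_KEYWORDS)
    if rng.random() < 0.5:
        phrase = f"{kw} tra {low} e {high} {unit_txt}"
    else:
        phrase = f"{kw} {low}-{high} {unit_txt}"
    # range policy "upper": gold is the upper bound
    return _Positive(text=phrase, value=float(high), unit=unit,
                     days=to_days(high, unit))


def _precise_date_phrase(rng: np.random.Generator, cfg: GeneratorConfig,
                         referral_date: date) -> _Positive:
    k = int(rng.integers(7, 366))
    target = referral_date + timedelta(days=k)
    sep = rng.choice(["/", "-", "."])
    year_txt = f"{target.year:04d}" if rng.random() < 0.8 else f"{target.year % 100:02d}"
    date_txt = f"{target.day:02d}{sep}{target.month:02d}{sep}{year_txt}"
    prefix = rng.choice(["entro il ", "entro ", "il ", ""])
    return _Positive(text=f"{prefix}{date_txt}", value=float(k), unit="date", days=k)


def _month_year_phrase(rng: np.random.Generator, cfg: GeneratorConfig,
                       referral_date: date) -> Optional[_Positive]:
    # a future month within the horizon, strictly after the referral month
    months_ahead = int(rng.integers(1, 13))
    m = referral_date.month + months_ahead
    year = referral_date.year + (m - 1) // 12
    month = (m - 1) % 12 + 1
    target = date(year, month, 1)
    k = (target - referral_date).days
    if k <= 0:
        return None
    prefix = rng.choice(["entro ", "a ", "controllo a ", ""])
    return _Positive(text=f"{prefix}{MONTH_NAMES[month - 1]} {year}",
                     value=float(k), unit="date", days=k)


#: phrasings outside the default grammar (recall-limit study set)
UNSEEN_TEMPLATES = ["richiamo al prossimo trimestre", "da rivedere a breve",
                    "controllo post ciclo"]


def _positive_phrase(rng: np.random.Generator, cfg: GeneratorConfig,
                     referral_date: date) -> _Positive:
    while True:
        kind = rng.choice(["duration", "range", "precise_date", "month_year"],
                          p=[0.6, 0.15, 0.15, 0.1])
        if kind == "duration":
            return _duration_phrase(rng, cfg)
        if kind == "range":
            return _range_phrase(rng, cfg)
        if kind == "precise_date":
            return _precise_date_phrase(rng, cfg, referral_date)
        out = _month_year_phrase(rng, cfg, referral_date)
        if out is not None:
            return out


# ---------------------------------------------------------------------------
# distractors and typos
# ---------------------------------------------------------------------------

def _distractor(rng: np.random.Generator, cfg: GeneratorConfig,
                referral_date: date, stub: str) -> str:
    kind = rng.choice(["past_month_year", "gestational", "icd_code",
                       "past_exam_date", "ago"])
    if kind == "past_month_year":
        months_back = int(rng.integers(1, 18))
        m = referral_date.month - months_back
        year = referral_date.year + (m - 1) // 12
        month = (m - 1) % 12 + 1
        return f"{stub} {MONTH_NAMES[month - 1]} {year}"
    if kind == "gestational":
        w = int(rng.integers(20, 41))
        unit = rng.choice(["settimana", "sg"])
        return f"controllo eco alla {w} {unit} di gravidanza"
    if kind == "icd_code":
        code = f"{rng.integers(0, 99999):05d}"
        return f"{code} - {stub}"
    if kind == "past_exam_date":
        mm = int(rng.integers(1, 13))
        yy = int(rng.integers(15, 21))
        return f"{stub}; scan osseo {mm:02d} {yy:02d} neg"
    n = int(rng.integers(2, 12))
    return f"{stub}; intervento {n} mesi fa"


def _inject_typo(rng: np.random.Generator, phrase: str) -> str:
    """One single-character edit on a temporal token of length >= 4."""
    tokens = phrase.split(" ")
    editable = [i for i, t in enumerate(tokens) if len(t) >= 4 and t.isalpha()]
    if not editable:
        return phrase
    i = int(rng.choice(editable))
    tok = tokens[i]
    pos = int(rng.integers(0, len(tok)))
    op = rng.choice(["sub", "ins", "del"])
    alphabet = "abcdefghilmnoprstuv"
    if op == "sub":
        c = rng.choice(list(alphabet.replace(tok[pos], "")))
        tok = tok[:pos] + c + tok[pos + 1:]
    elif op == "ins":
        c = rng.choice(list(alphabet))
        tok = tok[:pos] + c + tok[pos:]
    else:
        tok = tok[:pos] + tok[pos + 1:]
    tokens[i] = tok
    return " ".join(tokens)


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _make_text(rng: np.random.Generator, cfg: GeneratorConfig, referral_date: date,
               text_id: str) -> tuple[str, GoldAnnotation, Optional[_Positive]]:
    stub = str(rng.choice(DIAGNOSIS_STUBS))
    if rng.random() < cfg.prevalence:
        if cfg.include_unseen and rng.random() < 0.1:
            phrase_txt = str(rng.choice(UNSEEN_TEMPLATES))
            text = f"{stub}, {phrase_txt}"
            gold = GoldAnnotation(text_id=text_id, has_indication=True,
                                  indication_kind="followup_waiting_time",
                                  gold_value=90.0, gold_unit="day", gold_days=90)
            return text, gold, None
        pos = _positive_phrase(rng, cfg, referral_date)
        phrase = pos.text
        if rng.random() < cfg.typo_rate:
            phrase = _inject_typo(rng, phrase)
        sep = str(rng.choice([", ", "; ", " "]))
        text = f"{stub}{sep}{phrase}" if rng.random() < 0.8 else phrase
        if rng.random() < cfg.uppercase_rate:
            text = text.upper()
        gold = GoldAnnotation(text_id=text_id, has_indication=True,
                              indication_kind="followup_waiting_time",
                              gold_value=pos.value, gold_unit=pos.unit,
                              gold_days=pos.days)
        return text, gold, pos
    if rng.random() < cfg.distractor_rate:
        text = _distractor(rng, cfg, referral_date, stub)
        if rng.random() < cfg.uppercase_rate:
            text = text.upper()
        gold = GoldAnnotation(text_id=text_id, has_indication=False,
                              indication_kind="other_temporal")
        return text, gold, None
    text = stub
    if rng.random() < cfg.uppercase_rate:
        text = text.upper()
    gold = GoldAnnotation(text_id=text_id, has_indication=False,
                          indication_kind="none")
    return text, gold, None


def generate_corpus(config: GeneratorConfig) -> tuple[list[str], list[GoldAnnotation]]:
    """Annotated texts with the configured prevalence and confounder mix.

    All date expressions are generated relative to ``config.anchor_date``;
    downstream extraction should use the same anchor as referral date.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    texts: list[str] = []
    golds: list[GoldAnnotation] = []
    for i in range(config.n_texts):
        text_id = f"t{i:06d}"
        text, gold, _ = _make_text(rng, config, config.anchor_date, text_id)
        texts.append(text)
        golds.append(gold)
    return texts, golds


# ---------------------------------------------------------------------------
# referral table generation
# ---------------------------------------------------------------------------

def _draw_delay(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    """elapsed - NTI for one indicated exam: >0 with probability pct_delayed."""
    if rng.random() < cfg.pct_delayed:
        d = int(round(float(rng.lognormal(cfg.delay_lognorm_mu, cfg.delay_lognorm_sigma))))
        return max(1, d)
    return -int(rng.exponential(cfg.timely_mean_days))


def generate_referral_table(
    config: GeneratorConfig,
) -> tuple[list[ReferralRecord], list[GoldAnnotation]]:
    """Referral records with coherent dates and texts from the corpus model.

    The follow-up subset (specialist follow-up codes, radiology Z flags)
    receives texts at the configured prevalence; for indicated exams the
    booking-to-first-proposed gap equals NTI + delay with the delay drawn
    from the delay model, so the cohort's true delayed fraction is known.
    Gold annotations (text_id = "referral:exam") carry the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start, end = config.referral_period
    horizon_days = (end - start).days

    records: list[ReferralRecord] = []
    golds: list[GoldAnnotation] = []
    for i in range(config.n_texts):
        referral_id = f"R{i:07d}"
        exam_index = 1
        referral_date = start + timedelta(days=int(rng.integers(0, horizon_days + 1)))
        booking_date = referral_date + timedelta(days=int(rng.integers(0, config.max_booking_lag + 1)))

        cat = str(rng.choice(["specialist", "radiology", "lab", "other"],
                             p=[0.5, 0.3, 0.1, 0.1]))
        if cat == "specialist":
            exam_type = str(rng.choice(SPECIALIST_TYPES))
            is_followup = bool(rng.random() < 0.6)
            oz = str(rng.choice(["O", "Z"], p=[0.7, 0.3]))
        elif cat == "radiology":
            exam_type = str(rng.choice(RADIOLOGY_TYPES))
            is_followup = False
            oz = str(rng.choice(["O", "Z"], p=[0.4, 0.6]))
        else:
            exam_type = "lab" if cat == "lab" else "altro"
            is_followup = False
            oz = "O"

        is_screening = bool(rng.random() < 0.03)
        is_er = bool(rng.random() < 0.03)
        priority = str(rng.choice(["U", "B", "D", "P"], p=[0.05, 0.1, 0.25, 0.6]))
        prescriber = str(rng.choice(["specialist", "GP"], p=[0.71, 0.29]))

        in_cohort = (
            not is_screening and not is_er and priority != "U" and cat != "lab"
            and ((cat == "specialist" and is_followup) or (cat == "radiology" and oz == "Z"))
        )

        text_id = f"{referral_id}:{exam_index}"
        if in_cohort:
            text, gold, pos = _make_text(rng, config, referral_date, text_id)
        else:
            text = str(rng.choice(DIAGNOSIS_STUBS))
            gold = GoldAnnotation(text_id=text_id, has_indication=False,
                                  indication_kind="none")
            pos = None

        if pos is not None:
            elapsed = max(0, pos.days + _draw_delay(rng, config))
        else:
            elapsed = int(rng.integers(1, 61))
        first_proposed = booking_date + timedelta(days=elapsed)
        postpone = int(rng.integers(1, config.max_postponement + 1)) \
            if rng.random() < config.postponement_rate else 0
        accepted = first_proposed + timedelta(days=postpone)

        records.append(ReferralRecord(
            doctor_id=f"D{int(rng.integers(0, 2000)):05d}",
            referral_id=referral_id,
            exam_index=exam_index,
            referral_date=referral_date,
            booking_date=booking_date,
            first_proposed_date=first_proposed,
            accepted_date=accepted,
            exam_type_code=exam_type,
            exam_category=cat,
            is_followup_code=is_followup,
            oz_flag=oz,
            priority_class=priority,
            is_screening=is_screening,
            is_er=is_er,
            facility_id=f"F{int(rng.integers(0, 200)):04d}",
            ats_id=str(rng.choice(ATS_IDS)),
            prescriber_type=prescriber,
            clinical_question=text,
        ))
        golds.append(gold)
    return records, golds
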