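"""Scoring against gold annotations.

Two levels, mirroring how a rule-based extractor is audited in practice:

- a binary classification problem — does the text carry a follow-up
  waiting-time indication? — scored with accuracy/precision/recall over a
  confusion matrix;
- correctness of the normalized value (NTI days), scored as an accuracy on
  three populations: all texts, texts with any temporal indication, and
  texts with a follow-up waiting-time indication.  The population split
  exists because at ~2% prevalence an accuracy over everything is dominated
  by easy negatives.

Only ``followup_waiting_time`` gold items count as positives; a text with an
unrelated temporal mention (a past date, a gestational age) is a *negative*
for the waiting-time task, and the correct prediction for it is null.

Error listings (false negatives, false positives, wrong values) feed the
manual-review loop through which the grammar is extended — the
"semi-automatic" part of the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .nti_normalizer import NTI
from .referral_io import GoldAnnotation


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ErrorBreakdown:
    fn_ids: list[str] = field(default_factory=list)
    fp_ids: list[str] = field(default_factory=list)
    wrong_value_ids: list[str] = field(default_factory=list)
    details: dict[str, dict] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    counts: ConfusionCounts
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    nti_accuracy_all: Optional[float]
    nti_accuracy_any_indication: Optional[float]
    nti_accuracy_followup_indication: Optional[float]
    errors: ErrorBreakdown

    def rounded(self, ndigits: int = 3) -> dict[str, Optional[float]]:
        """Report-time rounding (3 decimals by default)."""
        def r(x: Optional[float]) -> Optional[float]:
            return None if x is None else round(x, ndigits)

        return {
            "accuracy": r(self.accuracy),
            "precision": r(self.precision),
            "recall": r(self.recall),
            "nti_accuracy_all": r(self.nti_accuracy_all),
            "nti_accuracy_any_indication": r(self.nti_accuracy_any_indication),
            "nti_accuracy_followup_indication": r(self.nti_accuracy_followup_indication),
        }


def _is_gold_positive(g: GoldAnnotation) -> bool:
    return g.indication_kind == "followup_waiting_time"


def confusion(
    predictions: Mapping[str, Optional[NTI]],
    gold: Sequence[GoldAnnotation],
) -> ConfusionCounts:
    """Confusion counts for the presence/absence problem.

    Every gold id must have a prediction (an explicit null counts); missing
    ids are fatal.
    """
    missing = [g.text_id for g in gold if g.text_id not in predictions]
    if missing:
        raise KeyError(f"predictions missing for ids: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    tp = fp = fn = tn = 0
    for g in gold:
        pred_pos = predictions[g.text_id] is not None
        if _is_gold_positive(g):
            if pred_pos:
                tp += 1
            else:
                fn += 1
        else:
            if pred_pos:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def binary_metrics(
    counts: ConfusionCounts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(accuracy, precision, recall); undefined ratios are None, never 0 or 1."""
    n = counts.total
    accuracy = (counts.tp + counts.tn) / n if n else None
    precision = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else None
    recall = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else None
    return accuracy, precision, recall


def _nti_correct(pred: Optional[NTI], g: GoldAnnotation) -> bool:
    if _is_gold_positive(g) and g.gold_days is not None:
        return pred is not None and pred.days == g.gold_days
    return pred is None


def nti_accuracy(
    predictions: Mapping[str, Optional[NTI]],
    gold: Sequence[GoldAnnotation],
    population: str = "all",
) -> Optional[float]:
    """Fraction of correct NTIs on a population; None on an empty population.

    Populations: ``all`` (every text), ``any_indication`` (gold kind is not
    none, including other temporal mentions), ``followup_indication`` (gold
    kind is followup_waiting_time).  A prediction is correct when the gold
    waiting time is absent and the prediction is null, or when both are
    present and the day counts agree exactly.
    """
    if population == "all":
        pop = list(gold)
    elif population == "any_indication":
        pop = [g for g in gold if g.indication_kind != "none"]
    elif population == "followup_indication":
        pop = [g for g in gold if _is_gold_positive(g)]
    else:
        raise ValueError(f"unknown population: {population!r}")
    if not pop:
        return None
    correct = sum(1 for g in pop if _nti_correct(predictions.get(g.text_id), g))
    return correct / len(pop)


def counts_from_error_analysis(
    n: int, fp: int, fn: int, reported_recall: float, ndigits: int = 3
) -> ConfusionCounts:
    """Reconstruct full confusion counts from a published error analysis.

    Audit reports often print only the corpus size, the FP/FN counts and a
    rounded recall.  The true-positive count is then the unique integer tp
    with round(tp/(tp+fn), ndigits) equal to the printed recall; tn follows
    by difference.  Raises if no or several tp values are consistent.
    """
    candidates = [
        tp for tp in range(0, n - fp - fn + 1)
        if (tp + fn) > 0 and round(tp / (tp + fn), ndigits) == round(reported_recall, ndigits)
    ]
    if not candidates:
        raise ValueError("no tp consistent with the reported recall")
    lo, hi = min(candidates), max(candidates)
    if hi - lo + 1 != len(candidates):
        raise ValueError("tp candidates are not contiguous")
    # a run of consistent values can occur at coarse rounding; require a
    # unique value at the printed precision
    if len(candidates) > 1:
        # choose is ambiguous only if the implied precision differs
        precs = {round(tp / (tp + fp), ndigits) for tp in candidates}
        if len(precs) > 1:
            raise ValueError(f"ambiguous tp in [{lo}, {hi}]")
    tp = candidates[0]
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn)


def error_report(
    predictions: Mapping[str, Optional[NTI]],
    gold: Sequence[GoldAnnotation],
    texts: Optional[Mapping[str, str]] = None,
) -> ErrorBreakdown:
    """FN / FP / wrong-value listings with snippets for manual review."""
    out = ErrorBreakdown()
    texts = texts or {}
    for g in gold:
        pred = predictions.get(g.text_id)
        detail: dict[str, object] = {}
        if _is_gold_positive(g):
            if pred is None:
                out.fn_ids.append(g.text_id)
                detail = {"kind": "fn", "gold_days": g.gold_days}
            elif g.gold_days is not None and pred.days != g.gold_days:
                out.wrong_value_ids.append(g.text_id)
                detail = {"kind": "wrong_value", "gold_days": g.gold_days,
                          "predicted_days": pred.days, "span": pred.source_span}
        else:
            if pred is not None:
                out.fp_ids.append(g.text_id)
                detail = {"kind": "fp", "predicted_days": pred.days,
                          "span": pred.source_span}
        if detail:
            if g.text_id in texts:
                detail["text"] = texts[g.text_id]
            out.details[g.text_id] = detail
    return out


def evaluate(
    predictions: Mapping[str, Optional[NTI]],
    gold: Sequence[GoldAnnotation],
    texts: Optional[Mapping[str, str]] = None,
) -> EvaluationReport:
    """Full report: confusion, binary metrics, NTI accuracies, error lists."""
    counts = confusion(predictions, gold)
    accuracy, precision, recall = binary_metrics(counts)
    return EvaluationReport(
        counts=counts,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        nti_accuracy_all=nti_accuracy(predictions, gold, "all"),
        nti_accuracy_any_indication=nti_accuracy(predictions, gold, "any_indication"),
        nti_accuracy_followup_indication=nti_accuracy(predictions, gold,
                                                      "followup_indication"),
        errors=error_report(predictions, gold, texts),
    )
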