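"""Cohort selection, delay computation and aggregation.

The delay clock starts at booking (the NHS is not responsible for late
booking) and stops at the first slot the booking system proposes (the NHS is
not responsible for a patient choosing a later slot).  With an extracted
waiting time of ``nti_days``::

    elapsed = first_proposed_date - booking_date      [days]
    delay   = elapsed - nti_days                      (positive = late)

Postponement — the days between the first proposed slot and the slot the
patient accepted — is patient-attributable and reported separately.

Cohort rules: screenings, ER visits, urgent (priority U) referrals and lab
tests are excluded; follow-ups are specialist records with a follow-up exam
code plus radiology records with the Z flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .referral_io import ReferralRecord

logger = logging.getLogger(__name__)

GROUP_KEYS = ("exam_type", "radiology_type", "ats", "prescriber")


@dataclass
class DelayResult:
    referral_id: str
    exam_index: int
    elapsed_days: int
    nti_days: int
    delay_days: int
    is_delayed: bool
    postponement_days: int


@dataclass
class GroupSummary:
    group: str
    n_records: int
    n_with_indication: int
    pct_with_indication: float
    n_delayed: int
    pct_delayed: Optional[float]          # over records with an indication
    delay_mean: Optional[float] = None    # stats over delayed records only
    delay_sd: Optional[float] = None
    delay_median: Optional[float] = None
    delay_q1: Optional[float] = None
    delay_q3: Optional[float] = None
    delay_iqr: Optional[float] = None
    n_postponed: int = 0
    postponement_mean: Optional[float] = None
    postponement_median: Optional[float] = None


def apply_exclusions(records: Iterable[ReferralRecord]) -> list[ReferralRecord]:
    """Drop screenings, ER visits, urgent (U) referrals and lab tests."""
    return [
        r for r in records
        if not r.is_screening
        and not r.is_er
        and r.priority_class != "U"
        and r.exam_category != "lab"
    ]


def select_followups(records: Iterable[ReferralRecord]) -> list[ReferralRecord]:
    """Keep specialist follow-up-code records and radiology Z-flag records."""
    return [
        r for r in records
        if (r.exam_category == "specialist" and r.is_followup_code)
        or (r.exam_category == "radiology" and r.oz_flag == "Z")
    ]


def compute_postponement(record: ReferralRecord) -> int:
    """max(0, accepted - first proposed); an earlier accepted date is a data
    error, logged and treated as 0."""
    if record.accepted_date is None or record.first_proposed_date is None:
        return 0
    diff = (record.accepted_date - record.first_proposed_date).days
    if diff < 0:
        logger.warning(
            "referral %s/%s: accepted date precedes first proposed date; "
            "postponement treated as 0", record.referral_id, record.exam_index,
        )
        return 0
    return diff


def compute_delay(record: ReferralRecord, nti_days: int) -> Optional[DelayResult]:
    """Delay of one record against its extracted waiting time.

    Returns None (logged) when booking or first-proposed dates are missing.
    """
    if record.booking_date is None or record.first_proposed_date is None:
        logger.warning(
            "referral %s/%s: missing booking or first-proposed date; skipped",
            record.referral_id, record.exam_index,
        )
        return None
    elapsed = (record.first_proposed_date - record.booking_date).days
    delay = elapsed - nti_days
    return DelayResult(
        referral_id=record.referral_id,
        exam_index=record.exam_index,
        elapsed_days=elapsed,
        nti_days=nti_days,
        delay_days=delay,
        is_delayed=delay > 0,
        postponement_days=compute_postponement(record),
    )


def _group_value(record: ReferralRecord, group_by: str) -> Optional[str]:
    if group_by == "exam_type":
        return record.exam_type_code
    if group_by == "radiology_type":
        return record.exam_type_code if record.exam_category == "radiology" else None
    if group_by == "ats":
        return record.ats_id
    if group_by == "prescriber":
        return record.prescriber_type
    raise ValueError(f"unknown group_by key: {group_by!r} (use one of {GROUP_KEYS})")


def aggregate(
    records: list[ReferralRecord],
    nti_results: dict[tuple[str, int], Optional[int]],
    delay_results: dict[tuple[str, int], DelayResult],
    group_by: str,
    min_group: int = 1000,
    order: str = "n_delayed",
) -> list[GroupSummary]:
    """One summary per group with more than ``min_group`` records.

    Delay statistics are computed over delayed records only; quartiles use
    linear interpolation.  ``order`` is "n_delayed" (descending absolute
    number of delayed exams, for bar reports) or "median_delay" (descending
    median delay, for boxplot reports); ties break on the group key.
    """
    rows = []
    for r in records:
        g = _group_value(r, group_by)
        if g is None:
            continue
        key = r.key
        nti = nti_results.get(key)
        dres = delay_results.get(key)
        rows.append({
            "group": g,
            "has_indication": nti is not None,
            "delay": dres.delay_days if dres is not None else np.nan,
            "is_delayed": bool(dres.is_delayed) if dres is not None else False,
            "postponement": dres.postponement_days if dres is not None else np.nan,
        })
    if not rows:
        return []
    df = pd.DataFrame(rows)

    summaries: list[GroupSummary] = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        if n <= min_group:
            continue
        n_ind = int(sub["has_indication"].sum())
        delayed = sub.loc[sub["is_delayed"], "delay"].to_numpy(dtype=float)
        n_del = len(delayed)
        s = GroupSummary(
            group=str(g),
            n_records=n,
            n_with_indication=n_ind,
            pct_with_indication=100.0 * n_ind / n,
            n_delayed=n_del,
            pct_delayed=(100.0 * n_del / n_ind) if n_ind else None,
        )
        if n_del:
            q1, med, q3 = np.percentile(delayed, [25, 50, 75])
            s.delay_mean = float(np.mean(delayed))
            s.delay_sd = float(np.std(delayed))
            s.delay_median = float(med)
            s.delay_q1 = float(q1)
            s.delay_q3 = float(q3)
            s.delay_iqr = float(q3 - q1)
        post = sub["postponement"].dropna().to_numpy(dtype=float)
        postponed = post[post > 0]
        s.n_postponed = int(len(postponed))
        if len(postponed):
            s.postponement_mean = float(np.mean(postponed))
            s.postponement_median = float(np.median(postponed))
        summaries.append(s)

    if order == "median_delay":
        summaries.sort(key=lambda s: (-(s.delay_median if s.delay_median is not None
                                        else float("-inf")), s.group))
    elif order == "n_delayed":
        summaries.sort(key=lambda s: (-s.n_delayed, s.group))
    else:
        raise ValueError(f"unknown order: {order!r}")
    return summaries


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Tabular form of the group summaries (for CSV output)."""
    return pd.DataFrame([s.__dict__ for s in summaries])
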