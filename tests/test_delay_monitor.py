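"""Cohort rules, delay arithmetic and aggregation."""

from datetime import date

import pytest

from attesa import (
    GeneratorConfig,
    ReferralRecord,
    aggregate,
    apply_exclusions,
    compute_delay,
    compute_postponement,
    generate_referral_table,
    select_followups,
)


def _record(**kw) -> ReferralRecord:
    base = dict(
        doctor_id="D1", referral_id="R1", exam_index=1,
        referral_date=date(2021, 3, 1), booking_date=date(2021, 3, 1),
        first_proposed_date=date(2021, 4, 15), accepted_date=date(2021, 4, 15),
        exam_type_code="cardiologia", exam_category="specialist",
        is_followup_code=True, oz_flag="O", priority_class="P",
        is_screening=False, is_er=False, facility_id="F1", ats_id="ATS1",
        prescriber_type="GP", clinical_question="",
    )
    base.update(kw)
    return ReferralRecord(**base)


@pytest.mark.parametrize("kw, excluded", [
    (dict(priority_class="U"), True),
    (dict(exam_category="lab"), True),
    (dict(is_screening=True), True),
    (dict(is_er=True), True),
    (dict(priority_class="P"), False),
    (dict(priority_class="B"), False),
])
def test_apply_exclusions(kw, excluded):
    records = [_record(**kw)]
    assert (apply_exclusions(records) == []) is excluded


def test_apply_exclusions_preserves_order():
    records = [_record(referral_id=f"R{i}") for i in range(5)]
    records[2] = _record(referral_id="R2", priority_class="U")
    kept = apply_exclusions(records)
    assert [r.referral_id for r in kept] == ["R0", "R1", "R3", "R4"]


@pytest.mark.parametrize("kw, kept", [
    (dict(exam_category="specialist", is_followup_code=True, oz_flag="O"), True),
    (dict(exam_category="radiology", is_followup_code=False, oz_flag="Z"), True),
    (dict(exam_category="radiology", is_followup_code=False, oz_flag="O"), False),
    (dict(exam_category="specialist", is_followup_code=False, oz_flag="Z"), False),
    (dict(exam_category="other", is_followup_code=True, oz_flag="Z"), False),
])
def test_select_followups(kw, kept):
    assert (select_followups([_record(**kw)]) != []) is kept


def test_compute_delay_late():
    r = _record(booking_date=date(2021, 3, 1), first_proposed_date=date(2021, 4, 15))
    d = compute_delay(r, 30)
    assert (d.elapsed_days, d.delay_days, d.is_delayed) == (45, 15, True)


def test_compute_delay_boundary_not_delayed():
    r = _record(booking_date=date(2021, 3, 1), first_proposed_date=date(2021, 3, 31))
    d = compute_delay(r, 30)
    assert d.delay_days == 0 and not d.is_delayed


def test_compute_delay_timely_negative():
    r = _record(booking_date=date(2021, 3, 1), first_proposed_date=date(2021, 4, 15))
    d = compute_delay(r, 90)
    assert d.delay_days == -45 and not d.is_delayed


def test_compute_delay_identity():
    r = _record()
    d = compute_delay(r, 19)
    assert d.delay_days + d.nti_days == d.elapsed_days


def test_compute_delay_missing_dates_skipped():
    assert compute_delay(_record(booking_date=None), 30) is None


@pytest.mark.parametrize("accepted, expected", [
    (date(2021, 4, 15), 0),          # same day
    (date(2021, 4, 25), 10),
    (None, 0),                        # absent
    (date(2021, 4, 10), 0),           # earlier than proposed: data error -> 0
])
def test_compute_postponement(accepted, expected):
    assert compute_postponement(_record(accepted_date=accepted)) == expected


def _cohort(n_per_group, delays_by_group):
    records, ntis, delayres = [], {}, {}
    i = 0
    for group, delays in delays_by_group.items():
        for j in range(n_per_group[group]):
            r = _record(referral_id=f"R{i}", exam_type_code=group)
            records.append(r)
            if j < len(delays):
                # elapsed is fixed at 45 d, so nti = 45 - delay forces the delay
                nti_days = 45 - delays[j]
                ntis[r.key] = nti_days
                delayres[r.key] = compute_delay(r, nti_days)
            else:
                ntis[r.key] = None
            i += 1
    return records, ntis, delayres


def test_aggregate_min_group_filter():
    n = {"a": 1001, "b": 999}
    records, ntis, delayres = _cohort(n, {"a": [19], "b": [5]})
    out = aggregate(records, ntis, delayres, "exam_type", min_group=1000)
    assert [s.group for s in out] == ["a"]


def test_aggregate_singleton_delay_stats():
    records, ntis, delayres = _cohort({"a": 1200}, {"a": [19]})
    (s,) = aggregate(records, ntis, delayres, "exam_type", min_group=1000)
    assert s.n_delayed == 1
    assert s.delay_mean == s.delay_median == 19
    assert s.delay_sd == 0 and s.delay_iqr == 0


def test_aggregate_all_null_group():
    records, ntis, delayres = _cohort({"a": 1100}, {"a": []})
    (s,) = aggregate(records, ntis, delayres, "exam_type", min_group=1000)
    assert s.n_with_indication == 0 and s.pct_with_indication == 0
    assert s.delay_mean is None and s.pct_delayed is None


def test_aggregate_conservation_before_filter():
    cfg = GeneratorConfig(n_texts=2000, seed=4)
    records, _ = generate_referral_table(cfg)
    ntis = {r.key: None for r in records}
    out = aggregate(records, ntis, {}, "ats", min_group=0)
    assert sum(s.n_records for s in out) == len(records)


def test_aggregate_unknown_key_fatal():
    with pytest.raises(ValueError, match="group_by"):
        aggregate([_record()], {("R1", 1): None}, {}, "nonsense", min_group=0)


def test_aggregate_ordering_modes():
    n = {"a": 1100, "b": 1100, "c": 1100}
    delays = {"a": [5, 5, 5], "b": [40, 2], "c": [10]}
    records, ntis, delayres = _cohort(n, delays)
    by_count = aggregate(records, ntis, delayres, "exam_type", min_group=1000,
                         order="n_delayed")
    assert [s.group for s in by_count] == ["a", "b", "c"]
    by_median = aggregate(records, ntis, delayres, "exam_type", min_group=1000,
                          order="median_delay")
    assert [s.group for s in by_median] == ["b", "c", "a"]


def test_nti_shift_monotonicity():
    """Adding k days to every NTI never increases any group's delayed count."""
    cfg = GeneratorConfig(n_texts=1500, seed=8, prevalence=0.2)
    records, golds = generate_referral_table(cfg)
    gold_days = {g.text_id: g.gold_days for g in golds}
    for k in (0, 7, 30):
        counts = []
        for shift in (0, k):
            n_del = 0
            for r in records:
                gd = gold_days.get(f"{r.referral_id}:{r.exam_index}")
                if gd is None:
                    continue
                d = compute_delay(r, gd + shift)
                if d and d.is_delayed:
                    n_del += 1
            counts.append(n_del)
        assert counts[1] <= counts[0]
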