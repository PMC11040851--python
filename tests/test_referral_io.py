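"""On-disk contracts: referral tables, gold annotations, extraction files."""

import json
from datetime import date

import pytest

from attesa import (
    GeneratorConfig,
    GoldAnnotation,
    TableDialect,
    generate_referral_table,
    read_extractions,
    read_gold,
    read_referrals,
    write_extractions,
    write_gold,
    write_referrals,
)
from attesa.nti_normalizer import NTI
from attesa.referral_io import ReferralIOError, parse_date


HEADER = ("doctor_id,referral_id,exam_index,referral_date,booking_date,"
          "first_proposed_date,accepted_date,exam_type_code,exam_category,"
          "is_followup_code,oz_flag,priority_class,is_screening,is_er,"
          "facility_id,ats_id,prescriber_type,clinical_question")


def _write(tmp_path, rows, header=HEADER):
    path = tmp_path / "referrals.csv"
    path.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
    return path


def test_read_referrals_basic_row(tmp_path):
    path = _write(tmp_path, [
        'D1,R1,1,2021-03-01,2021-03-05,2021-04-01,2021-04-01,rm,radiology,'
        '0,Z,P,0,0,F1,ATS1,GP,Dermatite'
    ])
    recs = list(read_referrals(path))
    assert len(recs) == 1
    r = recs[0]
    assert r.clinical_question == "Dermatite"
    assert r.oz_flag == "Z" and r.exam_category == "radiology"
    assert r.referral_date == date(2021, 3, 1)


def test_read_referrals_empty_text_and_missing_dates(tmp_path):
    path = _write(tmp_path, [
        'D1,R1,1,2021-03-01,,,,visita,specialist,1,,P,0,0,F1,ATS1,GP,'
    ])
    r = next(read_referrals(path))
    assert r.clinical_question == ""
    assert r.booking_date is None and r.accepted_date is None
    assert r.oz_flag is None


def test_read_referrals_skips_invalid_calendar_date(tmp_path):
    path = _write(tmp_path, [
        'D1,R1,1,31/02/2021,,,,visita,specialist,1,,P,0,0,F1,ATS1,GP,x',
        'D1,R2,1,01/03/2021,,,,visita,specialist,1,,P,0,0,F1,ATS1,GP,y',
    ])
    errors = []
    recs = list(read_referrals(path, errors=errors))
    assert [r.referral_id for r in recs] == ["R2"]
    assert len(errors) == 1 and errors[0][0] == 2


def test_record_count_is_rows_minus_skips(tmp_path):
    rows = [
        'D1,R1,1,2021-01-01,,,,v,specialist,1,,P,0,0,F,ATS1,GP,a',
        'D1,R2,1,bad-date,,,,v,specialist,1,,P,0,0,F,ATS1,GP,b',
        'D1,R3,1,2021-01-03,,,,v,specialist,1,,X,0,0,F,ATS1,GP,c',  # bad priority
        'D1,R4,1,2021-01-04,,,,v,specialist,1,,P,0,0,F,ATS1,GP,d',
    ]
    errors = []
    recs = list(read_referrals(_write(tmp_path, rows), errors=errors))
    assert len(recs) == len(rows) - len(errors) == 2


def test_missing_mandatory_column_is_fatal(tmp_path):
    path = _write(tmp_path, ["D1,R1"], header="doctor_id,referral_id")
    with pytest.raises(ReferralIOError, match="mandatory column"):
        list(read_referrals(path))


def test_column_mapping_and_dmy_dialect(tmp_path):
    dialect = TableDialect(delimiter=";", date_format="dmy",
                           columns={"clinical_question": "QUESITO",
                                    "referral_date": "DATA"})
    header = HEADER.replace(",", ";").replace("clinical_question", "QUESITO") \
                   .replace("referral_date", "DATA")
    path = _write(tmp_path, [
        'D1;R1;1;15/03/2021;;;;v;specialist;1;;P;0;0;F;ATS1;GP;Controllo tra 3 mesi'
    ], header=header)
    r = next(read_referrals(path, dialect))
    assert r.referral_date == date(2021, 3, 15)
    assert r.clinical_question == "Controllo tra 3 mesi"


def test_referral_roundtrip_identity(tmp_path):
    cfg = GeneratorConfig(n_texts=200, seed=1)
    records, _ = generate_referral_table(cfg)
    path = tmp_path / "out.csv"
    write_referrals(records, path)
    back = list(read_referrals(path))
    assert back == records


@pytest.mark.parametrize("cell, expected", [
    ("2021-03-01", date(2021, 3, 1)),
    ("01/03/2021", date(2021, 3, 1)),
    ("", None),
])
def test_parse_date_dialects(cell, expected):
    assert parse_date(cell, "auto") == expected


def test_read_gold_valid_lines(tmp_path):
    path = tmp_path / "gold.jsonl"
    path.write_text(
        '{"text_id":"a1","has_indication":false,"indication_kind":"none"}\n'
        '{"text_id":"a2","has_indication":true,'
        '"indication_kind":"followup_waiting_time",'
        '"gold_value":3,"gold_unit":"month","gold_days":90}\n',
        encoding="utf-8",
    )
    gold = read_gold(path)
    assert len(gold) == 2
    assert gold[1].gold_days == 90


def test_read_gold_invariant_violation_is_fatal_with_line(tmp_path):
    path = tmp_path / "gold.jsonl"
    path.write_text(
        '{"text_id":"a1","has_indication":false,"indication_kind":"none"}\n'
        '{"text_id":"a2","has_indication":true,'
        '"indication_kind":"followup_waiting_time","gold_value":3}\n',
        encoding="utf-8",
    )
    with pytest.raises(ReferralIOError, match="line 2"):
        read_gold(path)


def test_gold_roundtrip(tmp_path):
    anns = [
        GoldAnnotation("a", False, "none"),
        GoldAnnotation("b", True, "followup_waiting_time", 2.0, "week", 14),
        GoldAnnotation("c", False, "other_temporal"),
    ]
    path = tmp_path / "g.jsonl"
    write_gold(anns, path)
    assert read_gold(path) == anns


def test_extractions_roundtrip_and_explicit_null(tmp_path):
    results = [
        ("t1", NTI(days=90, value=3.0, unit="month", kind="interval",
                   source_span=(10, 22))),
        ("t2", None),
        ("t3", NTI(days=59, value=59.0, unit="date", kind="precise_date",
                   source_span=(0, 19), anchor_date=date(2021, 1, 15))),
    ]
    path = tmp_path / "ex.jsonl"
    write_extractions(results, path)
    lines = path.read_text(encoding="utf-8").strip().split("\n")
    assert json.loads(lines[1])["nti"] is None  # null written explicitly
    assert read_extractions(path) == results


def test_write_extractions_empty(tmp_path):
    path = tmp_path / "ex.jsonl"
    write_extractions([], path)
    assert path.read_text(encoding="utf-8") == ""
    assert read_extractions(path) == []
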