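import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cma.evaluation import (
    AcceptanceClass,
    FollowupEvent,
    acceptance_report,
    average_pairwise_kappa,
    classify_acceptance,
    cohen_kappa,
    pct_one_decimal,
    quantitative_report,
    render_pct,
    top_k_summary,
)
from cma.surveillance import ActionRecord

T0 = dt.datetime(2026, 3, 1, 12, 0)


def _action(action_id="a1"):
    return ActionRecord(
        action_id=action_id, alert_id="al1", disposition="note",
        note_text="please review", timestamp=T0,
    )


def _ev(kind, hours):
    return FollowupEvent(kind=kind, timestamp=T0 + dt.timedelta(hours=hours))


# --------------------------------------------------------------------------
# percentage rendering


@pytest.mark.parametrize(
    "count, total, precision, expected",
    [
        (444, 9381, 1, 4.7),
        (81, 9381, 1, 0.9),
        (608, 4223, 0, 14),
        (448, 5276, 0, 9),     # 8.49% -> 8.5 -> 9 under two-stage half-up
        (2439, 37782, 0, 7),   # 6.455% -> 6.5 -> 7
        (2568, 39481, 0, 7),
        (637, 39481, 1, 1.6),
        (189, 229, 0, 83),     # 82.53%
        (1, 3, 0, 33),
    ],
)
def test_two_stage_half_up_rendering(count, total, precision, expected):
    assert render_pct(count, total, precision) == expected


def test_render_pct_auto_precision():
    assert render_pct(637, 39481) == 1.6   # < 2% keeps one decimal
    assert render_pct(2568, 39481) == 7    # >= 2% renders integer
    with pytest.raises(ZeroDivisionError):
        pct_one_decimal(1, 0)


# --------------------------------------------------------------------------
# acceptance classification


def test_dose_correction_within_window_accepted():
    out = classify_acceptance(_action(), [_ev("dose_correction", 10)])
    assert out.classification is AcceptanceClass.accepted_dose_correction


def test_no_event_within_window_not_accepted():
    assert classify_acceptance(_action(), []).classification is AcceptanceClass.not_accepted
    late = classify_acceptance(_action(), [_ev("dose_correction", 80)])
    assert late.classification is AcceptanceClass.not_accepted


def test_boundary_exactly_72h_counts_as_within():
    out = classify_acceptance(_action(), [_ev("stop", 72)])
    assert out.classification is AcceptanceClass.accepted_stop


def test_discharge_before_event_is_unverifiable():
    out = classify_acceptance(_action(), [_ev("discharge", 4), _ev("dose_correction", 10)])
    assert out.classification is AcceptanceClass.excluded_unverifiable


def test_event_before_discharge_still_accepted():
    out = classify_acceptance(_action(), [_ev("followup_measurement", 2), _ev("discharge", 4)])
    assert out.classification is AcceptanceClass.accepted_followup


def test_duplicate_excluded_first():
    out = classify_acceptance(_action(), [_ev("stop", 1)], is_duplicate=True)
    assert out.classification is AcceptanceClass.excluded_duplicate


def test_events_at_or_before_action_ignored():
    out = classify_acceptance(_action(), [_ev("stop", 0), _ev("stop", -5)])
    assert out.classification is AcceptanceClass.not_accepted


# --------------------------------------------------------------------------
# acceptance report


def test_acceptance_report_conservation_and_rates():
    rows = (
        [{"channel": "note", "classification": "accepted_stop"}] * 5
        + [{"channel": "note", "classification": "not_accepted"}] * 3
        + [{"channel": "note", "classification": "excluded_duplicate"}] * 2
    )
    rep = acceptance_report(pd.DataFrame(rows), group_by=["channel"])
    row = rep.iloc[0]
    assert row["sampled"] == 10 and row["actions"] == 8
    assert row["accepted"] + (row["actions"] - row["accepted"]) + row["duplicates"] + row["unverifiable"] == 10
    assert row["accepted_pct"] == 63  # 5/8 = 62.5 -> 63


def test_all_accepted_is_100_and_all_excluded_is_undefined():
    rep = acceptance_report(pd.DataFrame([{"classification": "accepted_modification"}] * 4))
    assert rep.iloc[0]["accepted_pct"] == 100
    rep2 = acceptance_report(pd.DataFrame([{"classification": "excluded_duplicate"}] * 4))
    assert rep2.iloc[0]["accepted_pct"] is None


# --------------------------------------------------------------------------
# quantitative report


def test_quantitative_report_empty_run():
    rep = quantitative_report(0, 0, 0)
    assert rep["alerts_checked"] == 0
    assert "notes_pct" not in rep


def test_quantitative_report_category_sums():
    per_cat = pd.DataFrame(
        {
            "category": ["a", "b"],
            "checked": [100, 300],
            "notes": [10, 30],
            "notes_plus_phone": [2, 6],
        }
    )
    rep = quantitative_report(500, 45, 9, per_cat)
    assert rep["category_checked_total"] == 400
    assert rep["category_share_pct"] == 80
    assert rep["per_category"][0]["notes_pct"] == 10


# --------------------------------------------------------------------------
# top-k summaries


def test_top_k_ranking_share_and_truncation():
    rows = [{"ward": "ED"}] * 33 + [{"ward": "Nephrology"}] * 9 + [{"ward": w} for w in
            ["Vascular sg"] * 8 + ["Cardiac sg"] * 6 + ["Pneumology"] * 5 + ["Urology"] * 39]
    top = top_k_summary(pd.DataFrame(rows), "ward", k=5)
    assert len(top) == 5
    assert top.iloc[1]["ward"] == "ED" and top.iloc[1]["share_pct"] == 33
    assert top.iloc[0]["ward"] == "Urology"


def test_top_k_tie_break_alphabetical():
    rows = [{"drug": d} for d in ["b", "a", "c"] * 4]
    top = top_k_summary(pd.DataFrame(rows), "drug", k=5)
    assert list(top["drug"]) == ["a", "b", "c"]
    assert set(top["share_pct"]) == {33}


def test_top_k_single_action_and_missing_annotation():
    single = top_k_summary(pd.DataFrame([{"drug": "enoxaparin"}]), "drug")
    assert single.iloc[0]["share_pct"] == 100
    with pytest.raises(ValueError):
        top_k_summary(pd.DataFrame([{"drug": ""}]), "drug")


# --------------------------------------------------------------------------
# Cohen's kappa


def test_kappa_perfect_agreement():
    assert cohen_kappa(["a", "b", "a", "b"], ["a", "b", "a", "b"]) == 1.0


def test_kappa_complete_disagreement_balanced():
    # 2x2 counts a=0, b=5, c=5, d=0
    x = ["pos"] * 5 + ["neg"] * 5
    y = ["neg"] * 5 + ["pos"] * 5
    assert cohen_kappa(x, y) == pytest.approx(-1.0, abs=1e-12)


def test_kappa_hand_computed_2x2():
    # counts: both-pos 20, x-pos/y-neg 5, x-neg/y-pos 10, both-neg 15
    # p_o = 35/50 = 0.7; p_e = (25/50)(30/50) + (25/50)(20/50) = 0.5
    # kappa = (0.7 - 0.5) / 0.5 = 0.4
    x = ["p"] * 20 + ["p"] * 5 + ["n"] * 10 + ["n"] * 15
    y = ["p"] * 20 + ["n"] * 5 + ["p"] * 10 + ["n"] * 15
    assert cohen_kappa(x, y) == pytest.approx(0.4, abs=1e-12)


def test_kappa_matches_sklearn_on_random_tables():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        x = rng.integers(0, 3, n)
        y = rng.integers(0, 3, n)
        if len(set(x) | set(y)) < 2 or (x == y).all():
            continue
        assert cohen_kappa(x.tolist(), y.tolist()) == pytest.approx(
            sklearn_metrics.cohen_kappa_score(x, y), abs=1e-12
        )


def test_kappa_constant_identical_raters_defined_as_one():
    assert cohen_kappa(["a", "a", "a"], ["a", "a", "a"]) == 1.0


@given(
    pairs=st.lists(
        st.tuples(st.sampled_from("abc"), st.sampled_from("abc")), min_size=2, max_size=30
    )
)
def test_kappa_symmetric_and_label_invariant(pairs):
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    assert cohen_kappa(x, y) == pytest.approx(cohen_kappa(y, x), abs=1e-12)
    rename = {"a": "z", "b": "q", "c": "m"}
    assert cohen_kappa([rename[v] for v in x], [rename[v] for v in y]) == pytest.approx(
        cohen_kappa(x, y), abs=1e-12
    )
    assert -1.0 - 1e-12 <= cohen_kappa(x, y) <= 1.0 + 1e-12


def test_average_pairwise_kappa():
    a = ["x", "y", "x", "y"]
    b = ["x", "y", "x", "x"]
    c = ["y", "y", "x", "y"]
    expected = np.mean([cohen_kappa(a, b), cohen_kappa(a, c), cohen_kappa(b, c)])
    assert average_pairwise_kappa([a, b, c]) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        average_pairwise_kappa([a])
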