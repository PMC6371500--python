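"""Evaluation statistics for a surveillance run.

Covers the quantitative flow (alert and action counts with percentages per
pharmacotherapeutic category), qualitative top-k ward/drug summaries, the
72-hour acceptance classification of pharmacist actions, and Cohen's kappa
for interrater reliability of the triage step.

Percentage rendering
--------------------
Published clinical-service reports round percentages in two stages: the raw
fraction is rounded half-up to one decimal, and integer-precision figures are
then rounded half-up again (so 6.455% renders as 6.5% -> 7%, and 8.49% as
8.5% -> 9%).  ``render_pct`` reproduces that convention; reports also carry
the raw fraction so nothing is lost to formatting.
"""

from __future__ import annotations

import datetime as dt
import enum
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .surveillance import ActionRecord


def pct_one_decimal(count: float, total: float) -> float:
    """Percentage rounded half-up to one decimal place."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    d = Decimal(100) * Decimal(str(count)) / Decimal(str(total))
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def render_pct(count: float, total: float, precision: Optional[int] = None) -> float:
    """Render count/total as a percentage at the report's precision.

    precision 1 -> one decimal; precision 0 -> integer (second-stage half-up
    from the one-decimal figure); None -> one decimal below 2%, integer
    otherwise.
    """
    one_dec = pct_one_decimal(count, total)
    if precision is None:
        precision = 1 if one_dec < 2.0 else 0
    if precision == 1:
        return one_dec
    return float(Decimal(str(one_dec)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# quantitative flow


def quantitative_report(
    n_checked: int,
    n_notes: int,
    n_phone: int,
    per_category: Optional[pd.DataFrame] = None,
    n_alerts_with_sequential: Optional[int] = None,
    n_notes_with_sequential: Optional[int] = None,
) -> dict:
    """Counts and percentages of the screening flow.

    ``n_checked`` counts the pharmacist-checked alerts (sequential-therapy
    auto-notes excluded); the optional ``*_with_sequential`` totals describe
    the flow including the automatic notes.  ``per_category`` rows: category,
    checked, notes, notes_plus_phone.
    """
    report: dict = {
        "alerts_checked": n_checked,
        "notes": n_notes,
        "notes_plus_phone": n_phone,
    }
    if n_alerts_with_sequential:
        report["alerts_with_sequential"] = n_alerts_with_sequential
        if n_notes_with_sequential is not None:
            report["notes_with_sequential"] = n_notes_with_sequential
            report["notes_pct_with_sequential"] = render_pct(
                n_notes_with_sequential, n_alerts_with_sequential
            )
        report["phone_pct_with_sequential"] = render_pct(n_phone, n_alerts_with_sequential)
    if n_checked:
        report["notes_pct"] = render_pct(n_notes, n_checked)
        report["phone_pct"] = render_pct(n_phone, n_checked)
    if per_category is not None and len(per_category):
        cat_checked = int(per_category["checked"].sum())
        rows = []
        for _, r in per_category.iterrows():
            rows.append(
                {
                    "category": r["category"],
                    "checked": int(r["checked"]),
                    "notes": int(r["notes"]),
                    "notes_pct": render_pct(r["notes"], r["checked"]) if r["checked"] else None,
                    "notes_plus_phone": int(r["notes_plus_phone"]),
                    "phone_pct": render_pct(r["notes_plus_phone"], r["checked"]) if r["checked"] else None,
                }
            )
        report["per_category"] = rows
        report["category_checked_total"] = cat_checked
        if n_checked:
            report["category_share_pct"] = render_pct(cat_checked, n_checked)
        report["category_notes_total"] = int(per_category["notes"].sum())
        report["category_phone_total"] = int(per_category["notes_plus_phone"].sum())
        report["category_notes_pct"] = render_pct(report["category_notes_total"], cat_checked)
        report["category_phone_pct"] = render_pct(report["category_phone_total"], cat_checked)
    return report


def run_quantitative_report(
    alerts: pd.DataFrame, auto_notes: pd.DataFrame, actions: pd.DataFrame
) -> dict:
    """Quantitative report from run artifacts (alerts/auto-notes/actions
    tables as written by the screening and triage stages)."""
    new_alerts = alerts[alerts["status"] == "new"] if "status" in alerts else alerts
    n_auto = len(auto_notes)
    n_checked = len(new_alerts)
    n_notes = int((actions["disposition"] == "note").sum()) if len(actions) else 0
    n_phone = int((actions["disposition"] == "note_plus_phone").sum()) if len(actions) else 0
    per_cat = None
    if len(new_alerts):
        checked = new_alerts.groupby("category").size().rename("checked")
        if len(actions):
            notes = (
                actions[actions["disposition"] == "note"].groupby("category").size()
            )
            phone = (
                actions[actions["disposition"] == "note_plus_phone"].groupby("category").size()
            )
        else:
            notes = phone = pd.Series(dtype=int)
        per_cat = (
            pd.DataFrame({"checked": checked})
            .assign(
                notes=lambda df: notes.reindex(df.index).fillna(0).astype(int),
                notes_plus_phone=lambda df: phone.reindex(df.index).fillna(0).astype(int),
            )
            .reset_index()
            .rename(columns={"index": "category"})
            .sort_values("category")
        )
    return quantitative_report(
        n_checked,
        n_notes,
        n_phone,
        per_cat,
        n_alerts_with_sequential=n_checked + n_auto,
        n_notes_with_sequential=n_notes + n_auto,
    )


# --------------------------------------------------------------------------
# acceptance


class AcceptanceClass(str, enum.Enum):
    accepted_modification = "accepted_modification"
    accepted_stop = "accepted_stop"
    accepted_dose_correction = "accepted_dose_correction"
    accepted_followup = "accepted_followup"
    not_accepted = "not_accepted"
    excluded_duplicate = "excluded_duplicate"
    excluded_unverifiable = "excluded_unverifiable"

    @property
    def accepted(self) -> bool:
        return self.value.startswith("accepted")

    @property
    def excluded(self) -> bool:
        return self.value.startswith("excluded")


class FollowupEvent(BaseModel):
    """Something that happened to the patient after a pharmacist action:
    a prescription stop or dose correction, a new measurement of a monitored
    parameter, or a discharge/transfer that makes acceptance unverifiable."""

    kind: str  # stop | dose_correction | modification | followup_measurement | discharge | transfer
    timestamp: dt.datetime
    detail: str = ""


class AcceptanceOutcome(BaseModel):
    action_id: str
    classification: AcceptanceClass
    qualifying_event: Optional[str] = None


_QUALIFYING = {
    "stop": AcceptanceClass.accepted_stop,
    "dose_correction": AcceptanceClass.accepted_dose_correction,
    "modification": AcceptanceClass.accepted_modification,
    "followup_measurement": AcceptanceClass.accepted_followup,
}


def classify_acceptance(
    action: ActionRecord,
    subsequent_events: Sequence[FollowupEvent],
    window_hours: float = 72.0,
    is_duplicate: bool = False,
) -> AcceptanceOutcome:
    """Classify one pharmacist action against the patient's subsequent record.

    Acceptance = a prescription modification (stop or dose correction) or a
    further follow-up of the monitored clinical/laboratory parameter within
    ``window_hours`` of the action.  Duplicates are excluded first; a
    discharge or transfer before any qualifying event makes the action
    unverifiable and excluded; otherwise the first qualifying event inside
    the window sets the accepted subtype, and none means not accepted.
    """
    if is_duplicate:
        return AcceptanceOutcome(
            action_id=action.action_id, classification=AcceptanceClass.excluded_duplicate
        )
    deadline = action.timestamp + dt.timedelta(hours=window_hours)
    for event in sorted(subsequent_events, key=lambda e: e.timestamp):
        if event.timestamp <= action.timestamp:
            continue
        if event.kind in ("discharge", "transfer"):
            return AcceptanceOutcome(
                action_id=action.action_id,
                classification=AcceptanceClass.excluded_unverifiable,
            )
        if event.kind in _QUALIFYING and event.timestamp <= deadline:
            return AcceptanceOutcome(
                action_id=action.action_id,
                classification=_QUALIFYING[event.kind],
                qualifying_event=event.kind,
            )
    return AcceptanceOutcome(
        action_id=action.action_id, classification=AcceptanceClass.not_accepted
    )


def acceptance_report(
    outcomes: pd.DataFrame,
    group_by: Optional[Sequence[str]] = None,
    precision: int = 0,
) -> pd.DataFrame:
    """Acceptance-rate table from a frame with a ``classification`` column
    (plus any grouping columns, e.g. category / channel).

    Per stratum: sampled actions, duplicate and unverifiable exclusions,
    evaluable actions, accepted count, and the acceptance percentage
    (accepted / evaluable).  A stratum whose actions are all excluded gets a
    null rate (undefined), never 0.
    """
    df = outcomes.copy()
    cls = df["classification"].map(lambda c: AcceptanceClass(c))
    df["_accepted"] = cls.map(lambda c: c.accepted)
    df["_dup"] = cls == AcceptanceClass.excluded_duplicate
    df["_unver"] = cls == AcceptanceClass.excluded_unverifiable
    groups = list(group_by) if group_by else []
    if groups:
        g = df.groupby(groups, sort=True)
        agg = g.agg(
            sampled=("classification", "size"),
            duplicates=("_dup", "sum"),
            unverifiable=("_unver", "sum"),
            accepted=("_accepted", "sum"),
        ).reset_index()
    else:
        agg = pd.DataFrame(
            [
                {
                    "sampled": len(df),
                    "duplicates": int(df["_dup"].sum()),
                    "unverifiable": int(df["_unver"].sum()),
                    "accepted": int(df["_accepted"].sum()),
                }
            ]
        )
    agg["actions"] = agg["sampled"] - agg["duplicates"] - agg["unverifiable"]
    agg["accepted_pct"] = pd.Series(
        [
            render_pct(a, n, precision) if n > 0 else None
            for a, n in zip(agg["accepted"], agg["actions"])
        ],
        index=agg.index,
        dtype=object,  # an all-excluded stratum has an undefined rate, not 0
    )
    return agg


# --------------------------------------------------------------------------
# qualitative top-k


def top_k_summary(actions: pd.DataFrame, key: str, k: int = 5) -> pd.DataFrame:
    """Top-k labels by share of actions: descending share, ties alphabetical.
    Fewer than k distinct labels returns them all."""
    if key not in actions.columns:
        raise KeyError(f"actions are not annotated with {key!r}")
    if actions[key].isna().any() or (actions[key] == "").any():
        raise ValueError(f"every action must be annotated with {key!r}")
    total = len(actions)
    counts = actions.groupby(key).size().reset_index(name="n")
    counts = counts.sort_values(["n", key], ascending=[False, True], kind="mergesort")
    counts["share_pct"] = [render_pct(n, total, 0) for n in counts["n"]]
    return counts.head(k).reset_index(drop=True)


# --------------------------------------------------------------------------
# interrater reliability


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
    agreement p_e from the raters' marginal label frequencies.  Range -1
    (complete disagreement with balanced marginals) to +1 (perfect
    agreement).  Two identical constant raters (p_e = 1) agree perfectly, so
    kappa is defined as 1.0 there.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two rated items")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    labels = sorted(set(a) | set(b), key=str)
    p_e = sum(
        (a.count(lab) / n) * (b.count(lab) / n) for lab in labels
    )
    if p_e >= 1.0 - 1e-15:
        import logging
        logging.getLogger("cma").info(
            "both raters constant and identical: chance agreement is 1, kappa defined as 1.0"
        )
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def average_pairwise_kappa(ratings: Sequence[Sequence]) -> float:
    """Unweighted mean of pairwise Cohen's kappa over >= 2 raters."""
    raters = list(ratings)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    kappas = [
        cohen_kappa(raters[i], raters[j])
        for i in range(len(raters))
        for j in range(i + 1, len(raters))
    ]
    return float(np.mean(kappas))
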