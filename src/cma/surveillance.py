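"""Worklist construction, duplicate suppression, and flowchart-driven triage.

Alerts from the four non-sequential categories land on a structured worklist
that a pharmacist reviews daily.  Each rule ships a flowchart — a small
decision tree of yes/no questions over the alert evidence and the current
snapshot — whose leaves carry the disposition: no action, an electronic note
in the record, or a note plus a phone call to the prescriber.  The human step
is modelled as a pluggable decision source so triage can also run fully
automatically (deterministic flowchart descent) for testing and simulation.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Callable, Optional, Union

from pydantic import BaseModel, Field, model_validator

from .model import DrugSet, PatientSnapshot
from .rules import Alert, RuleCategory, RuleDefinition, evaluate_rule

logger = logging.getLogger("cma")

CATEGORY_ORDER = [c.value for c in RuleCategory]


class Worklist(BaseModel):
    """The day's reviewable alerts, grouped by category, rule, patient.
    Sequential-therapy auto-notes never appear here."""

    date: dt.date
    entries: list[Alert]

    @model_validator(mode="after")
    def _only_new(self) -> "Worklist":
        for a in self.entries:
            if a.status != "new":
                raise ValueError(f"worklist may contain only new alerts, got {a.status}")
            if a.category is RuleCategory.sequential_therapy:
                raise ValueError("sequential-therapy notes bypass the worklist")
        return self

    @classmethod
    def build(cls, date: dt.date, alerts: list[Alert]) -> "Worklist":
        entries = [
            a
            for a in alerts
            if a.status == "new" and a.category is not RuleCategory.sequential_therapy
        ]
        entries.sort(
            key=lambda a: (CATEGORY_ORDER.index(a.category.value), a.rule_id, a.patient_id)
        )
        return cls(date=date, entries=entries)


def suppress_duplicates(
    alerts: list[Alert],
    history: list[Alert],
    horizon_days: int = 7,
) -> list[Alert]:
    """Mark repeat alerts so the pharmacist is not shown unchanged repeats.

    An alert is a duplicate iff a prior alert within the horizon exists for
    the same (patient, rule, triggering drug set) AND no criterion's observed
    evidence has changed since.  A relevant change in any criterion value
    makes the alert reappear as new.  First occurrences are never suppressed.
    Returns new Alert objects with status set; input lists are not mutated.
    """
    def key(a: Alert) -> tuple:
        return (a.patient_id, a.rule_id, tuple(sorted(a.triggering_drugs)))

    out: list[Alert] = []
    for alert in alerts:
        prior_match: Optional[Alert] = None
        for prior in history:
            if prior.snapshot_date >= alert.snapshot_date:
                continue
            if (alert.snapshot_date - prior.snapshot_date).days > horizon_days:
                continue
            if key(prior) == key(alert) and prior.evidence == alert.evidence:
                prior_match = prior
                break
        if prior_match is not None:
            out.append(
                alert.model_copy(
                    update={"status": "suppressed_duplicate", "duplicate_of": prior_match.alert_id}
                )
            )
        else:
            out.append(alert.model_copy(update={"status": "new", "duplicate_of": None}))
    return out


# --------------------------------------------------------------------------
# flowcharts


class FlowchartLeaf(BaseModel):
    disposition: str  # no_action | note | note_plus_phone
    message: str = ""

    @model_validator(mode="after")
    def _check(self) -> "FlowchartLeaf":
        if self.disposition not in ("no_action", "note", "note_plus_phone"):
            raise ValueError(f"unknown disposition {self.disposition!r}")
        if self.disposition != "no_action" and not self.message.strip():
            raise ValueError("note leaves require a non-empty message")
        return self


class FlowchartNode(BaseModel):
    """A yes/no question; ``on_missing`` names the conservative branch taken
    when the question cannot be answered from the available data."""

    question: str  # criteria_still_met | triggering_drug_active
    if_yes: Union["FlowchartNode", FlowchartLeaf]
    if_no: Union["FlowchartNode", FlowchartLeaf]
    on_missing: str = "if_yes"


FlowchartNode.model_rebuild()


class Flowchart(BaseModel):
    rule_id: str
    root: FlowchartNode


def default_flowchart(rule: RuleDefinition) -> Flowchart:
    """The standard two-question tree: if the criteria no longer hold (value
    reverted / drug stopped) do nothing; otherwise act through the rule's
    escalation channel with the predefined advice text."""
    disposition = "note_plus_phone" if rule.escalation == "note_plus_phone" else "note"
    leaf = FlowchartLeaf(disposition=disposition, message=rule.advice_template or rule.description)
    no_action = FlowchartLeaf(disposition="no_action")
    root = FlowchartNode(
        question="criteria_still_met",
        if_yes=FlowchartNode(
            question="triggering_drug_active", if_yes=leaf, if_no=no_action
        ),
        if_no=no_action,
    )
    return Flowchart(rule_id=rule.rule_id, root=root)


def _answer(
    question: str,
    alert: Alert,
    snapshot: Optional[PatientSnapshot],
    rule: Optional[RuleDefinition],
    drug_sets: Optional[dict[str, DrugSet]],
) -> Optional[bool]:
    if question == "criteria_still_met":
        if snapshot is None or rule is None or drug_sets is None:
            return None
        return evaluate_rule(rule, snapshot, drug_sets) is not None
    if question == "triggering_drug_active":
        if snapshot is None:
            return None
        active_ids = {o.order_id for o in snapshot.active_orders()}
        return bool(set(alert.triggering_orders) & active_ids) or not alert.triggering_orders
    logger.warning("unknown flowchart question %r", question)
    return None


def render_message(template: str, evidence: dict[str, object]) -> str:
    class _Missing(dict):
        def __missing__(self, k):  # leave unresolvable placeholders visible
            return "{" + k + "}"

    try:
        return template.format_map(_Missing(evidence))
    except (ValueError, TypeError):
        return template


def apply_flowchart(
    alert: Alert,
    flowchart: Flowchart,
    snapshot: Optional[PatientSnapshot],
    rule: Optional[RuleDefinition] = None,
    drug_sets: Optional[dict[str, DrugSet]] = None,
) -> tuple[str, str]:
    """Descend the flowchart for one alert; returns (disposition, note text).

    Deterministic: identical inputs give identical dispositions.  A question
    that cannot be answered routes to the node's conservative branch with a
    logged message.
    """
    if flowchart.rule_id != alert.rule_id:
        raise ValueError(
            f"flowchart {flowchart.rule_id!r} applied to alert for rule {alert.rule_id!r}"
        )
    node: Union[FlowchartNode, FlowchartLeaf] = flowchart.root
    while isinstance(node, FlowchartNode):
        answer = _answer(node.question, alert, snapshot, rule, drug_sets)
        if answer is None:
            logger.info(
                "alert %s: question %r unanswerable, taking %s branch",
                alert.alert_id, node.question, node.on_missing,
            )
            node = node.if_yes if node.on_missing == "if_yes" else node.if_no
        else:
            node = node.if_yes if answer else node.if_no
    text = render_message(node.message, alert.evidence) if node.message else ""
    return node.disposition, text


class ActionRecord(BaseModel):
    """A pharmacist action on one alert: an electronic note, optionally
    escalated with a phone call (the call is always *next to* a note, so a
    note text is required for both channels)."""

    action_id: str
    alert_id: str
    rule_id: str = ""
    patient_id: str = ""
    category: str = ""
    ward: str = ""
    drug: str = ""
    disposition: str  # note | note_plus_phone
    note_text: str
    actor: str = "pharmacist"
    timestamp: dt.datetime

    @model_validator(mode="after")
    def _check(self) -> "ActionRecord":
        if self.disposition not in ("note", "note_plus_phone"):
            raise ValueError(f"invalid disposition {self.disposition!r}")
        if not self.note_text.strip():
            raise ValueError("every action carries a note text")
        return self


DecisionSource = Callable[[Alert, str, str], tuple[str, str]]


def triage_worklist(
    worklist: Worklist,
    snapshots: dict[str, PatientSnapshot],
    rules: dict[str, RuleDefinition],
    drug_sets: dict[str, DrugSet],
    flowcharts: Optional[dict[str, Flowchart]] = None,
    actor: str = "auto",
    decision_source: Optional[DecisionSource] = None,
) -> tuple[list[ActionRecord], list[Alert]]:
    """Triage every worklist entry through its flowchart.

    ``decision_source``, when given, may override the flowchart's proposed
    (disposition, text) — this is where an interactive reviewer plugs in.
    Returns (actions, no-action alerts).  Exactly one ActionRecord per
    acted-on alert.
    """
    flowcharts = flowcharts or {}
    actions: list[ActionRecord] = []
    untouched: list[Alert] = []
    for i, alert in enumerate(worklist.entries):
        rule = rules.get(alert.rule_id)
        chart = flowcharts.get(alert.rule_id)
        if chart is None:
            if rule is None:
                raise KeyError(f"no rule or flowchart for {alert.rule_id!r}")
            chart = default_flowchart(rule)
        snapshot = snapshots.get(alert.patient_id)
        disposition, text = apply_flowchart(alert, chart, snapshot, rule, drug_sets)
        if decision_source is not None:
            disposition, text = decision_source(alert, disposition, text)
        if disposition == "no_action":
            untouched.append(alert)
            continue
        actions.append(
            ActionRecord(
                action_id=f"{alert.alert_id}:a{i}",
                alert_id=alert.alert_id,
                rule_id=alert.rule_id,
                patient_id=alert.patient_id,
                category=alert.category.value,
                ward=alert.ward,
                drug=alert.triggering_drugs[0] if alert.triggering_drugs else "",
                disposition=disposition,
                note_text=text,
                actor=actor,
                timestamp=dt.datetime.combine(worklist.date, dt.time(12, 0)),
            )
        )
    return actions, untouched
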