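"""File formats and run-directory management.

Everything is flat text: header-bearing CSV for census tables and alerts,
JSON-lines for action logs, YAML for the rule-set configuration.  Malformed
census rows are collected into a rejects table with a reason per row — never
silently dropped.  A run directory carries a manifest (input hashes, seed,
stage flags) so evaluation can refuse to run on mismatched inputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import ValidationError

from .model import (
    ClinicalParameter,
    DDIOverrideEvent,
    DrugSet,
    LabResult,
    MedicationOrder,
    PatientSnapshot,
)
from .rules import (
    Alert,
    AutoNote,
    BioequivalenceTable,
    RuleConfigError,
    RuleDefinition,
    validate_ruleset,
)
from .surveillance import ActionRecord, Flowchart, FlowchartLeaf, FlowchartNode

logger = logging.getLogger("cma")

CENSUS_FILES = ("patients.csv", "orders.csv", "labs.csv", "params.csv", "overrides.csv")


@dataclasses.dataclass
class Ruleset:
    """A validated rule-set configuration: rules, named drug sets, the
    IV-to-oral bioequivalence table, and per-rule flowcharts."""

    rules: list[RuleDefinition]
    drug_sets: dict[str, DrugSet]
    bioequivalence: BioequivalenceTable
    flowcharts: dict[str, Flowchart]

    @property
    def rules_by_id(self) -> dict[str, RuleDefinition]:
        return {r.rule_id: r for r in self.rules}


def _parse_flowchart_node(obj: dict, path: str):
    if "disposition" in obj:
        return FlowchartLeaf(**obj)
    if "question" not in obj:
        raise RuleConfigError(f"{path}: flowchart node needs 'question' or 'disposition'")
    return FlowchartNode(
        question=obj["question"],
        if_yes=_parse_flowchart_node(obj["if_yes"], path + ".if_yes"),
        if_no=_parse_flowchart_node(obj["if_no"], path + ".if_no"),
        on_missing=obj.get("on_missing", "if_yes"),
    )


def load_ruleset(path: str | Path | None = None) -> Ruleset:
    """Load and validate a rule-set YAML; ``None`` loads the packaged
    exemplar rules.

    Every cross-reference must resolve (criterion drug_set_ref / pair_sets,
    flowchart rule ids); duplicate rule ids are rejected.  Errors name the
    offending field.
    """
    if path is None:
        text = resources.files("cma.data").joinpath("ruleset.yaml").read_text()
        source = "<packaged ruleset>"
    else:
        text = Path(path).read_text()
        source = str(path)
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RuleConfigError(f"{source}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise RuleConfigError(f"{source}: top level must be a mapping")

    drug_sets: dict[str, DrugSet] = {}
    for name, spec in (raw.get("drug_sets") or {}).items():
        try:
            drug_sets[name] = DrugSet(name=name, **(spec or {}))
        except (ValidationError, ValueError) as exc:
            raise RuleConfigError(f"{source}: drug_sets.{name}: {exc}") from exc

    try:
        bioeq = BioequivalenceTable(entries=raw.get("bioequivalence") or {})
    except (ValidationError, ValueError) as exc:
        raise RuleConfigError(f"{source}: bioequivalence: {exc}") from exc

    rules: list[RuleDefinition] = []
    for i, spec in enumerate(raw.get("rules") or []):
        try:
            rules.append(RuleDefinition(**spec))
        except (ValidationError, ValueError) as exc:
            rid = (spec or {}).get("rule_id", f"#{i}")
            raise RuleConfigError(f"{source}: rules[{rid}]: {exc}") from exc
    validate_ruleset(rules, drug_sets)
    if not rules:
        logger.warning("%s: no enabled rules", source)

    by_id = {r.rule_id for r in rules}
    flowcharts: dict[str, Flowchart] = {}
    for rid, spec in (raw.get("flowcharts") or {}).items():
        if rid not in by_id:
            raise RuleConfigError(f"{source}: flowcharts.{rid}: no such rule")
        try:
            flowcharts[rid] = Flowchart(rule_id=rid, root=_parse_flowchart_node(spec, f"flowcharts.{rid}"))
        except (ValidationError, ValueError) as exc:
            raise RuleConfigError(f"{source}: flowcharts.{rid}: {exc}") from exc

    return Ruleset(rules=rules, drug_sets=drug_sets, bioequivalence=bioeq, flowcharts=flowcharts)


# --------------------------------------------------------------------------
# census reading


def _parse_ts(value) -> dt.datetime:
    return dt.datetime.fromisoformat(str(value))


def read_census(datadir: str | Path) -> tuple[list[PatientSnapshot], pd.DataFrame]:
    """Read the five census tables into per-patient-day snapshots.

    Returns (snapshots, rejects): malformed rows land in ``rejects`` with the
    file, row index and reason, and the run proceeds without them.  A missing
    file is an error listing the expected files.
    """
    datadir = Path(datadir)
    missing = [f for f in CENSUS_FILES if not (datadir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"census directory {datadir} is missing {missing}; expected files: {list(CENSUS_FILES)}"
        )
    frames = {f.split(".")[0]: pd.read_csv(datadir / f, dtype=str).fillna("") for f in CENSUS_FILES}
    rejects: list[dict] = []

    def reject(table: str, idx, reason: str) -> None:
        rejects.append({"table": table, "row": int(idx), "reason": str(reason)})

    orders_by_pid: dict[str, list[MedicationOrder]] = {}
    for idx, row in frames["orders"].iterrows():
        try:
            orders_by_pid.setdefault(row["patient_id"], []).append(
                MedicationOrder(
                    order_id=row["order_id"],
                    drug_code=row["drug_code"],
                    drug_name=row.get("drug_name", ""),
                    dose_mg=float(row["dose_mg"]),
                    frequency_hours=float(row["frequency_hours"]),
                    route=row["route"],
                    start=_parse_ts(row["start"]),
                    stop=_parse_ts(row["stop"]) if row["stop"] else None,
                    crushable=str(row.get("crushable", "True")).lower() in ("true", "1", "yes"),
                    indication_code=row.get("indication_code") or None,
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            reject("orders", idx, exc)

    labs_by_pid: dict[str, list[LabResult]] = {}
    for idx, row in frames["labs"].iterrows():
        try:
            labs_by_pid.setdefault(row["patient_id"], []).append(
                LabResult.from_raw(
                    row["analyte"], float(row["value"]), row.get("unit", ""), _parse_ts(row["timestamp"])
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            reject("labs", idx, exc)

    params_by_pid: dict[str, list[ClinicalParameter]] = {}
    for idx, row in frames["params"].iterrows():
        try:
            params_by_pid.setdefault(row["patient_id"], []).append(
                ClinicalParameter(
                    kind=row["kind"], value=float(row["value"]), timestamp=_parse_ts(row["timestamp"])
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            reject("params", idx, exc)

    overrides_by_pid: dict[str, list[DDIOverrideEvent]] = {}
    for idx, row in frames["overrides"].iterrows():
        try:
            overrides_by_pid.setdefault(row["patient_id"], []).append(
                DDIOverrideEvent(
                    drug_a=row["drug_a"], drug_b=row["drug_b"], severity=row["severity"],
                    motivation=row.get("motivation", ""), physician_id=row.get("physician_id", ""),
                    timestamp=_parse_ts(row["timestamp"]),
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            reject("overrides", idx, exc)

    snapshots: list[PatientSnapshot] = []
    for idx, row in frames["patients"].iterrows():
        pid = row["patient_id"]
        try:
            snapshots.append(
                PatientSnapshot(
                    patient_id=pid,
                    snapshot_date=row["snapshot_date"],
                    age=int(row["age"]),
                    sex=row["sex"] or None,
                    weight_kg=float(row["weight_kg"]) if row.get("weight_kg") else None,
                    ward=row.get("ward", ""),
                    admission_class=row["admission_class"],
                    gi_absorption_intact=str(row.get("gi_absorption_intact", "False")).lower()
                    in ("true", "1", "yes"),
                    labs=labs_by_pid.get(pid, []),
                    clinical_params=params_by_pid.get(pid, []),
                    orders=orders_by_pid.get(pid, []),
                    overrides=overrides_by_pid.get(pid, []),
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            reject("patients", idx, exc)

    rejects_df = pd.DataFrame(rejects, columns=["table", "row", "reason"])
    if len(rejects_df):
        logger.warning("census %s: %d malformed rows rejected", datadir, len(rejects_df))
    return snapshots, rejects_df


def write_census(frames, datadir: str | Path) -> None:
    datadir = Path(datadir)
    datadir.mkdir(parents=True, exist_ok=True)
    for name, df in frames.as_dict().items():
        df.to_csv(datadir / f"{name}.csv", index=False)


# --------------------------------------------------------------------------
# alerts / actions round-trip


def alerts_to_frame(alerts: list[Alert]) -> pd.DataFrame:
    rows = []
    for a in alerts:
        rows.append(
            {
                "alert_id": a.alert_id, "rule_id": a.rule_id, "patient_id": a.patient_id,
                "snapshot_date": a.snapshot_date.isoformat(), "category": a.category.value,
                "ward": a.ward, "status": a.status, "duplicate_of": a.duplicate_of or "",
                "triggering_orders": ";".join(a.triggering_orders),
                "triggering_drugs": ";".join(a.triggering_drugs),
                "evidence": json.dumps(a.evidence, sort_keys=True, default=str),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "alert_id", "rule_id", "patient_id", "snapshot_date", "category", "ward",
            "status", "duplicate_of", "triggering_orders", "triggering_drugs", "evidence",
        ],
    )


def frame_to_alerts(df: pd.DataFrame) -> list[Alert]:
    out = []
    for _, r in df.fillna("").iterrows():
        out.append(
            Alert(
                alert_id=r["alert_id"], rule_id=r["rule_id"], patient_id=r["patient_id"],
                snapshot_date=dt.date.fromisoformat(str(r["snapshot_date"])),
                category=r["category"], ward=r["ward"], status=r["status"] or "new",
                duplicate_of=r["duplicate_of"] or None,
                triggering_orders=[x for x in str(r["triggering_orders"]).split(";") if x],
                triggering_drugs=[x for x in str(r["triggering_drugs"]).split(";") if x],
                evidence=json.loads(r["evidence"]) if r["evidence"] else {},
            )
        )
    return out


def write_jsonl(records: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def read_jsonl(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def actions_to_records(actions: list[ActionRecord]) -> list[dict]:
    return [a.model_dump(mode="json") for a in actions]


# --------------------------------------------------------------------------
# run directory


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class RunDirectory:
    """A screening run's working directory with a manifest tying outputs to
    their inputs (ruleset hash, census hash, seed, completed stages)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)

    @property
    def manifest_path(self) -> Path:
        return self.path / "manifest.json"

    def read_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {"stages": []}

    def update_manifest(self, **fields) -> None:
        manifest = self.read_manifest()
        stages = set(manifest.get("stages", []))
        if "stage" in fields:
            stages.add(fields.pop("stage"))
        manifest.update(fields)
        manifest["stages"] = sorted(stages)
        self.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def record_inputs(self, ruleset_path: Optional[Path], datadir: Path, seed: Optional[int] = None) -> None:
        fields: dict = {
            "census_hash": self.hash_census(datadir),
            "datadir": str(datadir),
        }
        if ruleset_path is not None:
            fields["ruleset_hash"] = _hash_file(Path(ruleset_path))
        if seed is not None:
            fields["seed"] = seed
        self.update_manifest(**fields)

    @staticmethod
    def hash_census(datadir: str | Path) -> str:
        h = hashlib.sha256()
        for name in CENSUS_FILES:
            f = Path(datadir) / name
            if f.exists():
                h.update(name.encode())
                h.update(f.read_bytes())
        return h.hexdigest()[:16]

    def check_inputs(self, datadir: str | Path) -> None:
        manifest = self.read_manifest()
        expected = manifest.get("census_hash")
        if expected and expected != self.hash_census(datadir):
            raise RuntimeError(
                f"run directory {self.path}: census at {datadir} does not match the "
                "manifest hash; refusing to evaluate stale outputs"
            )
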