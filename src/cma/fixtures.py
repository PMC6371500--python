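"""Reference count tables from the original service's published 18-month
evaluation, used as worked examples and regression anchors.

These are count-level data only (alerts checked, notes sent, phone calls,
acceptance-sample breakdowns per pharmacotherapeutic category); aggregating
them with :mod:`cma.evaluation` reproduces every published percentage.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluation import AcceptanceClass

#: overall screening flow over 18 months.
FLOW_COUNTS = {
    "alerts_with_sequential": 92050,
    "notes_with_sequential": 24943,
    "phone_calls": 637,
    "alerts_checked": 39481,  # sequential auto-notes excluded
    "notes": 2568,
    "four_category_checked": 37782,
}

_CATEGORIES = [
    "renal_insufficiency",
    "qtc_prolongation",
    "restricted_indication_dosing",
    "ddi_override",
]

#: per-category checks and actions (four preselected categories).
CATEGORY_COUNTS = pd.DataFrame(
    {
        "category": _CATEGORIES,
        "checked": [9381, 4223, 5276, 18902],
        "notes": [444, 608, 448, 939],
        "notes_plus_phone": [81, 139, 142, 259],
    }
)

#: acceptance samples: 300 patients per channel, with duplicate and
#: not-verifiable (discharge/transfer) exclusions, evaluable actions and the
#: number accepted within 72 h.
ACCEPTANCE_NOTE = pd.DataFrame(
    {
        "category": _CATEGORIES,
        "sampled": [61, 78, 51, 110],
        "duplicates": [10, 4, 3, 25],
        "unverifiable": [6, 11, 5, 7],
        "accepted": [31, 34, 21, 43],
    }
)

ACCEPTANCE_PHONE = pd.DataFrame(
    {
        "category": _CATEGORIES,
        "sampled": [27, 66, 66, 141],
        "duplicates": [0, 0, 0, 46],
        "unverifiable": [5, 3, 6, 11],
        "accepted": [16, 48, 44, 81],
    }
)

#: automatic sequential-therapy notes: 300 patients -> 341 advices.
SEQUENTIAL_COUNTS = {
    "actions": 341,
    "switched": 112,  # IV-to-oral switch performed
    "iv_stopped": 64,
    "not_accepted": 165,
}


def acceptance_outcomes_from_counts(counts: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Expand a per-category acceptance count table into one row per sampled
    action, so the standard aggregation path can be exercised on it."""
    rows = []
    for _, r in counts.iterrows():
        evaluable = int(r["sampled"] - r["duplicates"] - r["unverifiable"])
        not_accepted = evaluable - int(r["accepted"])
        if not_accepted < 0:
            raise ValueError(f"inconsistent counts in category {r['category']!r}")
        spec = [
            (AcceptanceClass.excluded_duplicate, int(r["duplicates"])),
            (AcceptanceClass.excluded_unverifiable, int(r["unverifiable"])),
            (AcceptanceClass.accepted_modification, int(r["accepted"])),
            (AcceptanceClass.not_accepted, not_accepted),
        ]
        for cls, n in spec:
            rows.extend(
                {"category": r["category"], "channel": channel, "classification": cls.value}
                for _ in range(n)
            )
    return pd.DataFrame(rows, columns=["category", "channel", "classification"])


def emit_fixtures(outdir: str | Path) -> list[Path]:
    """Write the count tables as CSV fixtures; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    flow = pd.DataFrame(sorted(FLOW_COUNTS.items()), columns=["quantity", "count"])
    seq = pd.DataFrame(sorted(SEQUENTIAL_COUNTS.items()), columns=["quantity", "count"])
    for name, df in [
        ("flow", flow),
        ("category_actions", CATEGORY_COUNTS),
        ("acceptance_note", ACCEPTANCE_NOTE),
        ("acceptance_phone", ACCEPTANCE_PHONE),
        ("sequential_acceptance", seq),
    ]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written
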