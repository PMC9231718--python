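"""Deterministic report rendering: CSV, aligned text, and structured JSON.

A report is a named collection of tables (pandas DataFrames) plus the
metadata needed to re-run the analysis exactly — the validated configuration,
the seed, and any study settings.  Rendering the same report twice produces
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .formatting import format_value
from .outcomes import OUTCOME_LABELS, CaseTriple

__all__ = [
    "Report",
    "FORMATS",
    "case_bounds_frame",
    "utilities_with_best",
    "render_report",
    "load_structured_report",
]

FORMATS = ("csv", "text", "structured")


@dataclass
class Report:
    """Named tables plus enough metadata to reproduce them."""

    tables: dict[str, pd.DataFrame]
    metadata: dict[str, Any] = field(default_factory=dict)


def case_bounds_frame(triple: CaseTriple, precision: int = 2) -> pd.DataFrame:
    """Tabulate a case-bound analysis: rows Expected / Worst Case / Best Case.

    Columns give the generating (P, Q), the implied clinical-benefit
    probability p(E1) = x1+x2+x3, and the six collapsed outcome categories.
    ``precision`` is carried in the frame's attrs for the text renderer.
    """
    pqs = {
        "Expected": triple.pq_expected,
        "Worst Case": triple.pq_worst,
        "Best Case": triple.pq_best,
    }
    rows = []
    for case, dist in triple.cases().items():
        p, q = pqs[case]
        pe1 = triple.pe1.get(case, dist.w[0] + dist.w[1] + dist.w[2])
        rows.append(
            {
                "case": case,
                "P": p,
                "Q": q,
                "p(E1)": pe1,
                **{label: w for label, w in zip(OUTCOME_LABELS, dist.w)},
            }
        )
    frame = pd.DataFrame(rows).set_index("case")
    frame.attrs["precision"] = precision
    return frame


def utilities_with_best(
    utilities: pd.DataFrame, best_actions: dict[str, dict[str, tuple[str, ...]]]
) -> pd.DataFrame:
    """Flatten a (value set, action) utility table, starring best actions."""
    out = pd.DataFrame(index=utilities.index)
    for ts, action in utilities.columns:
        marks = [
            "*" if action in best_actions.get(row, {}).get(ts, ()) else ""
            for row in utilities.index
        ]
        out[f"{ts} / {action}"] = [
            f"{v:.1f}{m}" for v, m in zip(utilities[(ts, action)], marks)
        ]
    return out


def _text_block(name: str, frame: pd.DataFrame) -> str:
    precision = frame.attrs.get("precision", 2)
    shown = frame.copy()
    for col in shown.columns:
        if pd.api.types.is_float_dtype(shown[col]):
            shown[col] = shown[col].map(lambda x: format_value(x, precision))
    title = name.replace("_", " ")
    return f"# {title}\n{shown.to_string()}\n"


def _frame_to_jsonable(frame: pd.DataFrame) -> dict[str, Any]:
    flat = frame.reset_index()
    flat.columns = [
        " / ".join(str(p) for p in c if str(p) != "") if isinstance(c, tuple) else str(c)
        for c in flat.columns
    ]
    return json.loads(flat.to_json(orient="split", index=False))


def render_report(
    report: Report, format: str, out_dir: str | Path, precision: int = 2
) -> list[Path]:
    """Write a report to ``out_dir`` in the requested format.

    ``csv`` writes one RFC-4180-style file per table, with the metadata in a
    ``# key=value`` comment header line; ``text`` writes one aligned-text
    file; ``structured`` writes a single JSON document with metadata and all
    tables, suitable for re-rendering later.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(FORMATS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    meta_line = "# " + " ".join(
        f"{k}={json.dumps(v, sort_keys=True)}" for k, v in sorted(report.metadata.items())
        if not isinstance(v, dict)
    )

    if format == "csv":
        for name, frame in report.tables.items():
            path = out_dir / f"{name}.csv"
            with open(path, "w", newline="") as fh:
                fh.write(meta_line + "\n")
                frame.to_csv(fh)
            written.append(path)
    elif format == "text":
        path = out_dir / "report.txt"
        blocks = [meta_line + "\n"] + [
            _text_block(name, frame) for name, frame in report.tables.items()
        ]
        path.write_text("\n".join(blocks))
        written.append(path)
    else:  # structured
        doc = {
            "metadata": report.metadata,
            "tables": {name: _frame_to_jsonable(f) for name, f in report.tables.items()},
        }
        path = out_dir / "results.json"
        path.write_text(json.dumps(doc, indent=2, sort_keys=True, allow_nan=True) + "\n")
        written.append(path)
    return written


def load_structured_report(path: str | Path) -> Report:
    """Re-load a structured JSON results document for re-rendering."""
    doc = json.loads(Path(path).read_text())
    tables = {}
    for name, payload in doc.get("tables", {}).items():
        frame = pd.DataFrame(payload["data"], columns=payload["columns"])
        if len(frame.columns):
            frame = frame.set_index(frame.columns[0])
        tables[name] = frame
    return Report(tables=tables, metadata=doc.get("metadata", {}))
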