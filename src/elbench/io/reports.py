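"""JSON serialisation of benchmark reports.

The JSON layout mirrors the published reporting convention: per-well
positives, true positives and recall, plus the balanced accuracy and the
standard deviation of recall, both in percent.
"""

from __future__ import annotations

import json

import numpy as np

from ..evaluation import BenchmarkReport, RecallTable

__all__ = ["write_report", "read_report", "report_to_dict"]


def report_to_dict(report: BenchmarkReport) -> dict:
    t = report.recall_table
    return {
        "wells": [
            {"well": int(w), "P": int(p), "TP": int(tp), "recall": float(r)}
            for w, p, tp, r in zip(t.well_ids, t.positives, t.true_positives, t.recall)
        ],
        "accuracy_percent": float(report.accuracy),
        "recall_std_percent": float(report.recall_std),
    }


def write_report(report: BenchmarkReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> BenchmarkReport:
    """Read and validate a benchmark report; rejects out-of-range values."""
    with open(path) as fh:
        d = json.load(fh)
    wells = d["wells"]
    ids = np.array([w["well"] for w in wells], dtype=int)
    p = np.array([w["P"] for w in wells], dtype=int)
    tp = np.array([w["TP"] for w in wells], dtype=int)
    for w in wells:
        if not (0.0 <= w["recall"] <= 1.0):
            raise ValueError(f"well {w['well']}: recall {w['recall']} outside [0, 1]")
    table = RecallTable(well_ids=ids, positives=p, true_positives=tp)
    acc = float(d["accuracy_percent"])
    if not (0.0 <= acc <= 100.0):
        raise ValueError(f"accuracy {acc} outside [0, 100]")
    return BenchmarkReport(recall_table=table, accuracy=acc, recall_std=float(d["recall_std_percent"]))
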