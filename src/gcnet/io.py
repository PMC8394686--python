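"""File formats: delimited panels, YAML models, TSV edge lists, JSON reports.

Panels are plain delimited text (comma or tab, auto-detected on read): a
header row of channel names, then one row per time point.  Models are YAML
documents with nested arrays so benchmark systems stay inspectable and
editable by hand.  Scan reports serialize to JSON with a schema version;
serialization is deterministic (sorted keys, sorted edge lists), so
identical inputs give byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .network import (
    CausalGraph,
    HiddenHubEvidence,
    ScanReport,
    ScanStep,
)
from .var import TimeSeriesPanel, VARModel

__all__ = [
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "read_model",
    "write_model",
    "write_edges",
    "write_dpc_table",
    "write_rpdc_table",
    "report_to_dict",
    "report_from_dict",
    "write_report",
]


class PanelFormatError(ValueError):
    """Malformed panel file; the message names the offending row/column."""


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_panel(path: str | Path) -> TimeSeriesPanel:
    """Read a delimited panel (header of channel names, rows = time points).

    Comma and tab delimiters are auto-detected.  Missing, non-numeric or
    ragged entries are rejected with the 1-based data row and the column
    label of the first offence.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise PanelFormatError(f"{path}: empty file")
    sep = _detect_delimiter(first)
    # check the raw header: pandas silently renames duplicate columns
    labels = [c.strip() for c in first.rstrip("\n").split(sep)]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise PanelFormatError(f"{path}: duplicate channel labels {dupes}")
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str,
                         skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise PanelFormatError(f"{path}: ragged rows ({exc})") from exc
    df.columns = labels
    values = np.empty(df.shape, dtype=float)
    for ci, col in enumerate(df.columns):
        # cell-wise float() keeps correctly rounded round-trip precision
        for ri, cell in enumerate(df[col]):
            if pd.isna(cell):
                raise PanelFormatError(
                    f"{path}: missing value at data row {ri + 1}, column {col!r}"
                )
            try:
                values[ri, ci] = float(cell)
            except ValueError:
                raise PanelFormatError(
                    f"{path}: non-numeric value {cell!r} at data row {ri + 1},"
                    f" column {col!r}"
                ) from None
    if values.shape[0] < 1:
        raise PanelFormatError(f"{path}: no data rows")
    return TimeSeriesPanel(values, tuple(labels))


def write_panel(panel: TimeSeriesPanel, path: str | Path, sep: str = ",") -> None:
    """Write a panel in the same dialect :func:`read_panel` accepts.

    Values are written with `repr` so a write-then-read round trip
    reproduces every float bit-for-bit.
    """
    with open(path, "w") as fh:
        fh.write(sep.join(panel.labels) + "\n")
        for row in panel.values:
            fh.write(sep.join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# model documents
# ---------------------------------------------------------------------------


def write_model(model: VARModel, path: str | Path) -> None:
    doc = {
        "n": int(model.n),
        "p": int(model.p),
        "A": [a.tolist() for a in model.A],
        "Sigma": model.Sigma.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_model(path: str | Path) -> VARModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    A = np.asarray(doc["A"], dtype=float)
    Sigma = np.asarray(doc["Sigma"], dtype=float)
    model = VARModel(A=A, Sigma=Sigma)
    if model.n != doc.get("n", model.n) or model.p != doc.get("p", model.p):
        raise ValueError(f"{path}: declared n/p disagree with array shapes")
    return model


# ---------------------------------------------------------------------------
# edge tables
# ---------------------------------------------------------------------------


def write_edges(graph: CausalGraph, path: str | Path) -> None:
    """TSV edge list: source, target, weight (header only when empty)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for (u, v) in sorted(graph.edges):
            w = graph.edges[(u, v)]
            fh.write(f"{u}\t{v}\t{'' if w is None else repr(w)}\n")


def write_dpc_table(result, ci, path: str | Path) -> None:
    """Per-cell DPC table: value, interval, and the significance call."""
    labels = result.labels
    with open(path, "w") as fh:
        fh.write("source\ttarget\tlag\tdpc_value\tci_lo\tci_hi\tsignificant\n")
        for i, tgt in enumerate(labels):
            for j, src in enumerate(labels):
                if i == j:
                    continue
                for h in range(1, result.p + 1):
                    val = result.pi[i, j, h - 1]
                    lo = ci.lo[i, j, h - 1]
                    hi = ci.hi[i, j, h - 1]
                    sig = int(val < lo or val > hi)
                    fh.write(
                        f"{src}\t{tgt}\t{h}\t{val!r}\t{lo!r}\t{hi!r}\t{sig}\n"
                    )


def write_rpdc_table(result, path: str | Path) -> None:
    """Per-frequency rPDC table with the pointwise critical value."""
    labels = result.labels
    with open(path, "w") as fh:
        fh.write("source\ttarget\tomega\trpdc_value\tcritical_value\tsignificant\n")
        for k, tgt in enumerate(labels):
            for j, src in enumerate(labels):
                if k == j:
                    continue
                for f, omega in enumerate(result.omegas):
                    val = result.lam[k, j, f]
                    sig = int(val > result.critical)
                    fh.write(
                        f"{src}\t{tgt}\t{omega!r}\t{val!r}\t"
                        f"{result.critical!r}\t{sig}\n"
                    )


# ---------------------------------------------------------------------------
# scan reports
# ---------------------------------------------------------------------------


def _graph_to_dict(graph: CausalGraph) -> dict:
    return {
        "nodes": list(graph.nodes),
        "edges": [
            [u, v, graph.edges[(u, v)]] for (u, v) in sorted(graph.edges)
        ],
    }


def _graph_from_dict(doc: dict) -> CausalGraph:
    return CausalGraph(
        nodes=tuple(doc["nodes"]),
        edges={(u, v): w for u, v, w in doc["edges"]},
    )


def report_to_dict(report: ScanReport) -> dict:
    ev = report.evidence
    return {
        "schema_version": __version__,
        "steps": [
            {
                "omitted": sorted(step.omitted),
                "graph": _graph_to_dict(step.graph),
                "important": sorted(step.important),
                "feedback_pairs": sorted(sorted(p) for p in step.feedback_pairs),
            }
            for step in report.steps
        ],
        "evidence": {
            "flag": ev.flag,
            "common_nodes": sorted(ev.common_nodes),
            "union_nodes": sorted(ev.union_nodes),
            "gained_out_links": [sorted(g) for g in ev.gained_out_links],
        },
        "failure": report.failure,
    }


def report_from_dict(doc: dict) -> ScanReport:
    steps = tuple(
        ScanStep(
            omitted=frozenset(s["omitted"]),
            graph=_graph_from_dict(s["graph"]),
            important=frozenset(s["important"]),
            feedback_pairs=frozenset(
                frozenset(p) for p in s["feedback_pairs"]
            ),
        )
        for s in doc["steps"]
    )
    ev = doc["evidence"]
    evidence = HiddenHubEvidence(
        flag=bool(ev["flag"]),
        common_nodes=frozenset(ev["common_nodes"]),
        union_nodes=frozenset(ev["union_nodes"]),
        gained_out_links=tuple(frozenset(g) for g in ev["gained_out_links"]),
    )
    return ScanReport(steps=steps, evidence=evidence, failure=doc.get("failure"))


def write_report(report: ScanReport, path: str | Path) -> None:
    """JSON scan report; deterministic byte-for-byte for identical inputs."""
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
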