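"""Reading and writing the pipeline's file formats.

All tabular artifacts are UTF-8 TSV with decimal points; graphs are
written as GraphML (node attributes: community, degree, z, P; edge
attribute r) or as a TSV edge list (region_a, region_b, r, p).
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from .data import (
    BehavioralTrial,
    GroupDesign,
    RegionActivityTable,
    ValidationError,
)

GRAPH_FORMATS = ("graphml", "edgelist")

#: Fixed float format so repeated runs are byte-identical.
FLOAT_FMT = "%.6f"


def read_activity_table(
    path: str | os.PathLike,
    design_path: str | os.PathLike,
) -> tuple[RegionActivityTable, GroupDesign, list[str]]:
    """Read a regions x subjects counts TSV and its companion design TSV.

    Returns (table, design, warnings); warnings flag any (genotype,
    condition) cell with fewer than 4 subjects, too small for a Pearson
    p-value.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        bad = pd.to_numeric(raw[col], errors="coerce")
        if bad.isna().any() and not raw[col].isna().any():
            row = raw.index[bad.isna().argmax()]
            raise ValidationError(
                f"non-numeric count at region {row!r}, subject {col!r} in {path}"
            )
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"duplicate region labels in {path}: {dupes}")
    table = RegionActivityTable.from_frame(raw.astype(float))

    design = GroupDesign(pd.read_csv(design_path, sep="\t", dtype=str))
    missing = [s for s in table.subject_ids if s not in design.subject_ids]
    if missing:
        raise ValidationError(
            f"subjects present in counts but missing from design: {missing}"
        )
    warnings = [
        f"group ({gen}, {cond}) has only {n} subjects (< 4): "
        "Pearson p-values unavailable"
        for gen, cond, n in design.small_groups()
    ]
    return table, design, warnings


def write_activity_table(
    table: RegionActivityTable,
    design: GroupDesign,
    counts_path: str | os.PathLike,
    design_path: str | os.PathLike,
) -> None:
    frame = table.to_frame()
    frame.index.name = "region"
    frame.to_csv(counts_path, sep="\t", float_format=FLOAT_FMT)
    design.table.to_csv(design_path, sep="\t", index=False)


def read_behavior_table(path: str | os.PathLike) -> list[BehavioralTrial]:
    """Read behavioral trials from TSV (columns: subject_id, Tc, To, Tm,
    Tnc, Tno, and optionally distance, latency, lit_time, session_length).
    """
    frame = pd.read_csv(path, sep="\t")
    trials = []
    for _, row in frame.iterrows():
        kwargs = dict(
            subject_id=str(row["subject_id"]),
            Tc=float(row["Tc"]),
            To=float(row["To"]),
            Tm=float(row["Tm"]),
            Tnc=float(row["Tnc"]),
            Tno=float(row["Tno"]),
        )
        for opt in ("distance", "latency"):
            if opt in frame.columns and not pd.isna(row[opt]):
                kwargs[opt] = float(row[opt])
        for opt in ("lit_time", "session_length"):
            if opt in frame.columns and not pd.isna(row[opt]):
                kwargs[opt] = float(row[opt])
        trials.append(BehavioralTrial(**kwargs))
    return trials


def write_behavior_table(
    trials: list[BehavioralTrial], path: str | os.PathLike
) -> None:
    rows = []
    for t in trials:
        rows.append(
            {
                "subject_id": t.subject_id,
                "Tc": t.Tc,
                "To": t.To,
                "Tm": t.Tm,
                "Tnc": t.Tnc,
                "Tno": t.Tno,
                "distance": t.distance,
                "latency": t.latency,
                "lit_time": "" if t.lit_time is None else t.lit_time,
                "session_length": ""
                if t.session_length is None
                else t.session_length,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_graph(
    graph: nx.Graph,
    partition: dict[str, int] | None,
    path: str | os.PathLike,
    format: str = "graphml",
) -> None:
    """Serialize a thresholded brain graph.

    GraphML carries per-node attributes (community, degree, and z / P when
    present on the graph) and per-edge r and p; the edge-list TSV has
    columns region_a, region_b, r, p. Isolated nodes are kept in GraphML
    (the edge list, by its nature, only records edges).
    """
    if format not in GRAPH_FORMATS:
        raise ValidationError(
            f"unknown graph format {format!r}; supported: {list(GRAPH_FORMATS)}"
        )
    if partition is not None:
        missing = [n for n in graph.nodes if n not in partition]
        if missing:
            raise ValidationError(f"partition does not cover nodes: {missing}")
    if format == "graphml":
        out = nx.Graph()
        for node in graph.nodes:
            attrs = {"degree": int(graph.degree(node))}
            if partition is not None:
                attrs["community"] = int(partition[node])
            for key in ("z", "P"):
                if key in graph.nodes[node]:
                    attrs[key] = float(graph.nodes[node][key])
            out.add_node(node, **attrs)
        for u, v, d in graph.edges(data=True):
            out.add_edge(u, v, r=float(d.get("r", np.nan)), p=float(d.get("p", np.nan)))
        nx.write_graphml(out, path)
    else:
        rows = [
            {
                "region_a": u,
                "region_b": v,
                "r": float(d.get("r", np.nan)),
                "p": float(d.get("p", np.nan)),
            }
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["region_a", "region_b", "r", "p"]).to_csv(
            path, sep="\t", index=False, float_format=FLOAT_FMT
        )


def read_graph(path: str | os.PathLike) -> nx.Graph:
    """Read back a GraphML file written by :func:`write_graph`."""
    return nx.read_graphml(path)
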