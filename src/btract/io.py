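"""Readers and writers: EMA/SIPS/metadata CSVs, labeled matrices, viewer JSON.

The viewer export is a single JSON document with ``nodes``, ``edges`` and
``paths`` arrays, the input format of 3D multilayer-network viewers; it
round-trips losslessly through :func:`read_network_export`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .items import BINARY_ITEM, EMA_ITEMS, SIPS_ITEMS, WELLBEING_REVERSE
from .panel import (
    INDEX_COLS,
    CohortMetadata,
    EMAPanel,
    SchemaError,
    SIPSTable,
    StudyDesign,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .tract import MLN3D, BehavioralPath

PathLike = Union[str, Path]


def _read_table(path: PathLike) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# EMA panel
# ---------------------------------------------------------------------------

def read_ema_table(
    path: PathLike,
    schema: Optional[Mapping[str, str]] = None,
    item_names: Optional[Sequence[str]] = None,
    design: Optional[StudyDesign] = None,
    reverse_code_wellbeing: bool = True,
) -> EMAPanel:
    """Read a long-format EMA CSV/TSV (one row per completed prompt).

    ``schema`` maps file column names to canonical names; columns carrying a
    positively-coded wellbeing item (e.g. ``Happiness``) are reverse-coded to
    their ``Lacking-`` counterpart (r' = 8 - r) when
    ``reverse_code_wellbeing`` is on.  When ``item_names`` is omitted the
    item set is the file's canonical item columns, in canonical order.
    Unknown item columns raise :class:`SchemaError`; out-of-range values
    raise :class:`ValidationError` naming the offending row.
    """
    df = _read_table(path)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in INDEX_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"EMA table lacks required columns {missing}")

    if item_names is None:
        present = set(df.columns) | {
            WELLBEING_REVERSE[c] for c in df.columns if c in WELLBEING_REVERSE
        }
        item_names = [it for it in EMA_ITEMS if it in present]
        if not item_names:
            raise SchemaError("EMA table has no recognized item columns")

    known = set(item_names) | set(WELLBEING_REVERSE) | set(INDEX_COLS) | {"timestamp"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown item columns {unknown}")

    if reverse_code_wellbeing:
        for pos, neg in WELLBEING_REVERSE.items():
            if pos in df.columns:
                if neg in df.columns:
                    raise SchemaError(
                        f"both {pos!r} and {neg!r} present; ambiguous coding"
                    )
                df[neg] = 8.0 - df[pos].astype(float)
                df = df.drop(columns=[pos])
    else:
        leftovers = [c for c in WELLBEING_REVERSE if c in df.columns]
        if leftovers:
            raise SchemaError(
                f"positively-coded columns {leftovers} present with reverse "
                "coding disabled; rename or enable reverse_code_wellbeing"
            )

    for col in item_names:
        if col not in df.columns:
            raise SchemaError(f"EMA table lacks item column {col!r}")
        df[col] = df[col].astype(float)

    cols = INDEX_COLS + (["timestamp"] if "timestamp" in df.columns else [])
    df = df[cols + list(item_names)]
    panel = EMAPanel(df, tuple(item_names), design or StudyDesign())
    return panel.sort()


def write_ema_table(panel: EMAPanel, path: PathLike) -> None:
    panel.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SIPS table and metadata
# ---------------------------------------------------------------------------

def read_sips_table(
    path: PathLike, item_names: Optional[Sequence[str]] = None
) -> SIPSTable:
    """Read a per-subject SIPS CSV (``subject_id`` column + 0-6 item scores)."""
    df = _read_table(path)
    if "subject_id" not in df.columns:
        raise SchemaError("SIPS table lacks a subject_id column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicated subject_id {dup.iloc[0]!r} in SIPS table")
    df = df.set_index("subject_id")
    if item_names is None:
        # canonical order first, then any extra columns in file order
        item_names = [c for c in SIPS_ITEMS if c in df.columns] + [
            c for c in df.columns if c not in SIPS_ITEMS
        ]
    missing = [c for c in item_names if c not in df.columns]
    if missing:
        raise SchemaError(f"SIPS table lacks item columns {missing}")
    return SIPSTable(df[list(item_names)].astype(float))


def write_sips_table(sips: SIPSTable, path: PathLike) -> None:
    sips.data.to_csv(path, index_label="subject_id")


def read_metadata(path: PathLike) -> CohortMetadata:
    df = _read_table(path)
    if "subject_id" not in df.columns:
        raise SchemaError("metadata table lacks a subject_id column")
    return CohortMetadata(df.set_index("subject_id"))


def write_metadata(meta: CohortMetadata, path: PathLike) -> None:
    meta.data.to_csv(path, index_label="subject_id")


# ---------------------------------------------------------------------------
# Labeled matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, labels: Sequence[str], path: PathLike) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path)


def read_matrix(path: PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# Viewer JSON export
# ---------------------------------------------------------------------------

class ExportError(ValueError):
    """Raised when a network cannot be exported (e.g. missing coordinates)."""


def write_network_export(
    mln: "MLN3D", paths: Sequence["BehavioralPath"], out: PathLike
) -> None:
    """Write the 3D multilayer network and its shortest paths as viewer JSON.

    Node ``size`` is the summed absolute weight of incident edges and
    ``centrality`` the number of shortest paths through the node; edge
    ``n_paths`` counts traversing shortest paths.
    """
    from .tract import longitudinal_betweenness, node_name

    node_counts, edge_counts = longitudinal_betweenness(mln, paths)
    strength: dict = {key: 0.0 for key in mln.node_keys()}
    for e in mln.edges:
        strength[e.u] += abs(e.weight)
        strength[e.v] += abs(e.weight)

    nodes_out = []
    for node in mln.nodes:
        if not (np.isfinite(node.x) and np.isfinite(node.y) and np.isfinite(node.z)):
            raise ExportError(f"node {node.item}@{node.layer} lacks finite coordinates")
        key = (node.item, node.layer)
        nodes_out.append(
            {
                "name": node.item,
                "layer": node.layer,
                "x": node.x,
                "y": node.y,
                "z": node.z,
                "size": strength[key],
                "centrality": int(node_counts.get(key, 0)),
            }
        )
    edges_out = [
        {
            "source": node_name(e.u),
            "target": node_name(e.v),
            "weight": e.weight,
            "length": e.length,
            "kind": e.kind,
            "n_paths": int(edge_counts.get((e.u, e.v), 0)),
        }
        for e in mln.edges
    ]
    paths_out = [
        {
            "start": p.start_item,
            "end": p.end_item,
            "nodes": [node_name(k) for k in p.node_sequence],
            "total_length": p.total_length,
        }
        for p in paths
    ]
    doc = {"nodes": nodes_out, "edges": edges_out, "paths": paths_out}
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_network_export(path: PathLike) -> tuple["MLN3D", list["BehavioralPath"]]:
    """Re-read a viewer JSON written by :func:`write_network_export`."""
    from .tract import MLN3D, BehavioralPath, Edge3D, Node3D, parse_node_name

    with open(path) as fh:
        doc = json.load(fh)
    nodes = [
        Node3D(n["name"], n["layer"], n["x"], n["y"], n["z"]) for n in doc["nodes"]
    ]
    edges = [
        Edge3D(
            parse_node_name(e["source"]),
            parse_node_name(e["target"]),
            e["weight"],
            e["length"],
            e["kind"],
        )
        for e in doc["edges"]
    ]
    mln = MLN3D(nodes=nodes, edges=edges)
    paths = []
    for p in doc["paths"]:
        seq = [parse_node_name(n) for n in p["nodes"]]
        paths.append(
            BehavioralPath(
                start_item=p["start"],
                end_item=p["end"],
                node_sequence=seq,
                coordinates=[mln.coordinates[k] for k in seq],
                total_length=p["total_length"],
            )
        )
    return mln, paths
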