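"""In-memory property graph for pathology records and their staging.

Schema: Patient -> Pathology_Report via HAS_REPORT; Pathology_Report ->
TNM_Stage (HAS_T_STAGE / HAS_N_STAGE / HAS_M_STAGE), Grade (HAS_GRADE),
PSA_Value (HAS_PSA), AJCC_Stage (CLASSIFIED_AS).  Staging-element nodes are
shared and deduplicated by a label-specific key (TNM nodes by the
(code, category) pair).  Exports: GraphML, a deterministic Cypher MERGE
script, and a JSON dump whose re-parse round-trips byte-identically.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .record_model import (
    MissingValue,
    PathologyRecord,
    TnmCode,
    is_missing,
    parameter_value,
)
from .staging_engine import StagingInput, StagingResult, assign_stage, impute_m, stage_record

__all__ = [
    "NODE_LABELS",
    "EDGE_TYPES",
    "GraphNode",
    "GraphEdge",
    "PropertyGraph",
    "build_graph",
    "stage_from_graph",
    "export_graph",
    "graph_from_json",
]

NODE_LABELS = (
    "Patient", "Pathology_Report", "TNM_Stage", "Grade", "PSA_Value", "AJCC_Stage",
)
EDGE_TYPES = (
    "HAS_REPORT", "HAS_T_STAGE", "HAS_N_STAGE", "HAS_M_STAGE",
    "HAS_GRADE", "HAS_PSA", "CLASSIFIED_AS",
)

_EDGE_ENDPOINTS = {
    "HAS_REPORT": ("Patient", "Pathology_Report"),
    "HAS_T_STAGE": ("Pathology_Report", "TNM_Stage"),
    "HAS_N_STAGE": ("Pathology_Report", "TNM_Stage"),
    "HAS_M_STAGE": ("Pathology_Report", "TNM_Stage"),
    "HAS_GRADE": ("Pathology_Report", "Grade"),
    "HAS_PSA": ("Pathology_Report", "PSA_Value"),
    "CLASSIFIED_AS": ("Pathology_Report", "AJCC_Stage"),
}

Key = Union[str, int, float, tuple]


@dataclass(frozen=True)
class GraphNode:
    label: str
    key: Key
    properties: tuple[tuple[str, Any], ...] = ()

    def props(self) -> dict:
        return dict(self.properties)


@dataclass(frozen=True)
class GraphEdge:
    type: str
    source: tuple[str, Key]  # (label, key)
    target: tuple[str, Key]


class DuplicateReportError(ValueError):
    pass


class PropertyGraph:
    """Labeled nodes (unique per (label, key)) and typed edges."""

    def __init__(self) -> None:
        self._nodes: dict[tuple[str, Key], GraphNode] = {}
        self._edges: list[GraphEdge] = []

    # -- construction -------------------------------------------------
    def merge_node(self, label: str, key: Key, properties: Mapping[str, Any] | None = None) -> GraphNode:
        if label not in NODE_LABELS:
            raise ValueError(f"unknown node label {label!r}")
        node_key = (label, key)
        existing = self._nodes.get(node_key)
        if existing is not None:
            if properties:
                merged = {**existing.props(), **dict(properties)}
                node = GraphNode(label, key, tuple(sorted(merged.items())))
                self._nodes[node_key] = node
                return node
            return existing
        node = GraphNode(label, key, tuple(sorted((properties or {}).items())))
        self._nodes[node_key] = node
        return node

    def add_edge(self, type_: str, source: tuple[str, Key], target: tuple[str, Key]) -> None:
        if type_ not in _EDGE_ENDPOINTS:
            raise ValueError(f"unknown edge type {type_!r}")
        want = _EDGE_ENDPOINTS[type_]
        if (source[0], target[0]) != want:
            raise ValueError(f"{type_} must connect {want[0]} -> {want[1]}")
        if source not in self._nodes or target not in self._nodes:
            raise ValueError("edge endpoints must exist before the edge is added")
        self._edges.append(GraphEdge(type_, source, target))

    # -- access -------------------------------------------------------
    @property
    def nodes(self) -> dict[tuple[str, Key], GraphNode]:
        return dict(self._nodes)

    @property
    def edges(self) -> list[GraphEdge]:
        return list(self._edges)

    def nodes_with_label(self, label: str) -> list[GraphNode]:
        return [n for (lbl, _), n in self._nodes.items() if lbl == label]

    def out_edges(self, source: tuple[str, Key], type_: str | None = None) -> list[GraphEdge]:
        return [
            e for e in self._edges
            if e.source == source and (type_ is None or e.type == type_)
        ]


def _clean_scalar(value: Any) -> Any:
    if isinstance(value, TnmCode):
        return value.render()
    return value


def _report_properties(record: PathologyRecord) -> dict[str, Any]:
    """Non-staging report fields stored as flat properties (missing omitted)."""
    names = (
        "Histologic Subtype", "Resection Margins",
        "Number of Lymph Nodes examined", "Lymph Nodes with Metastasis",
        "Primary Gleason Pattern", "Secondary Gleason Pattern",
        "Tertiary Gleason Pattern", "Percentage of Secondary Gleason Pattern",
        "EPE", "SVI", "Perineural Invasion",
    )
    props: dict[str, Any] = {}
    for name in names:
        v = parameter_value(record, name)
        if not is_missing(v):
            props[name] = _clean_scalar(v)
    return props


def _staging_grade_group(record: PathologyRecord):
    gg = record.gleason.reported_grade_group
    if is_missing(gg):
        gg = record.gleason.derived_grade_group()
    return gg


def build_graph(
    records: Sequence[PathologyRecord],
    stagings: Sequence[StagingResult] | None = None,
    *,
    pmx_blocks: bool = False,
) -> PropertyGraph:
    """Build the property graph from records and (optionally) precomputed stagings.

    Missing fields produce no edge; shared staging-element nodes are
    deduplicated by key.  Duplicate report ids are a construction error.
    """
    if stagings is None:
        stagings = [stage_record(r, pmx_blocks=pmx_blocks) for r in records]
    by_report = {s.report_id: s for s in stagings}
    graph = PropertyGraph()
    seen: set[str] = set()
    for record in records:
        if record.report_id in seen:
            raise DuplicateReportError(f"duplicate report_id {record.report_id!r}")
        seen.add(record.report_id)

        patient = ("Patient", record.patient_id)
        graph.merge_node("Patient", record.patient_id)
        report = ("Pathology_Report", record.report_id)
        graph.merge_node("Pathology_Report", record.report_id, _report_properties(record))
        graph.add_edge("HAS_REPORT", patient, report)

        for attr, edge_type in (
            ("t_stage", "HAS_T_STAGE"),
            ("n_stage", "HAS_N_STAGE"),
            ("m_stage", "HAS_M_STAGE"),
        ):
            value = getattr(record, attr)
            if isinstance(value, TnmCode):
                key = (value.code, value.category)
                graph.merge_node("TNM_Stage", key, {"code": value.code, "type": value.category})
                graph.add_edge(edge_type, report, ("TNM_Stage", key))

        gg = _staging_grade_group(record)
        if not is_missing(gg):
            graph.merge_node("Grade", int(gg), {"grade_group": int(gg)})
            graph.add_edge("HAS_GRADE", report, ("Grade", int(gg)))

        if not is_missing(record.psa_ng_ml):
            key = round(float(record.psa_ng_ml), 2)
            graph.merge_node("PSA_Value", key, {"value": key})
            graph.add_edge("HAS_PSA", report, ("PSA_Value", key))

        staging = by_report.get(record.report_id)
        if staging is not None:
            graph.merge_node("AJCC_Stage", staging.label, {"stage": staging.stage})
            graph.add_edge("CLASSIFIED_AS", report, ("AJCC_Stage", staging.label))
    return graph


def stage_from_graph(
    graph: PropertyGraph, report_id: str, *, pmx_blocks: bool = False
) -> str:
    """Re-derive a report's stage label from its graph neighborhood.

    Reads the HAS_* neighbors, reconstructs a staging input (absent edges
    become missing elements), imputes M and runs the rule engine.  For a
    graph built with the same policy this equals the stored CLASSIFIED_AS
    target.
    """
    report = ("Pathology_Report", report_id)
    if report not in graph.nodes:
        raise KeyError(f"unknown report_id {report_id!r}")

    from .record_model import NOT_MENTIONED

    def tnm_or_missing(edge_type: str, category: str):
        edges = graph.out_edges(report, edge_type)
        if not edges:
            return NOT_MENTIONED
        code, _ = edges[0].target[1]
        return TnmCode(prefix="", category=category, code=code)

    grade_edges = graph.out_edges(report, "HAS_GRADE")
    psa_edges = graph.out_edges(report, "HAS_PSA")
    inp = StagingInput(
        t=tnm_or_missing("HAS_T_STAGE", "T"),
        n=tnm_or_missing("HAS_N_STAGE", "N"),
        m=tnm_or_missing("HAS_M_STAGE", "M"),
        grade_group=grade_edges[0].target[1] if grade_edges else NOT_MENTIONED,
        psa=psa_edges[0].target[1] if psa_edges else NOT_MENTIONED,
    )
    inp, _ = impute_m(inp, pmx_blocks=pmx_blocks)
    return assign_stage(inp).label


# ---------------------------------------------------------------------------
# Export

def _key_to_json(key: Key) -> Any:
    return list(key) if isinstance(key, tuple) else key


def _key_from_json(raw: Any) -> Key:
    return tuple(raw) if isinstance(raw, list) else raw


def _sort_token(key: Key) -> str:
    return json.dumps(_key_to_json(key))


def _sorted_nodes(graph: PropertyGraph) -> list[GraphNode]:
    return sorted(graph.nodes.values(), key=lambda n: (n.label, _sort_token(n.key)))


def _sorted_edges(graph: PropertyGraph) -> list[GraphEdge]:
    return sorted(
        graph.edges,
        key=lambda e: (e.type, e.source[0], _sort_token(e.source[1]),
                       e.target[0], _sort_token(e.target[1])),
    )


def _cypher_literal(value: Any) -> str:
    if isinstance(value, str):
        escaped = value.replace("\\", "\\\\").replace("'", "\\'")
        return f"'{escaped}'"
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _cypher_props(props: Mapping[str, Any]) -> str:
    items = ", ".join(
        f"`{k}`: {_cypher_literal(v)}" for k, v in sorted(props.items())
    )
    return "{" + items + "}"


def _node_key_props(node: GraphNode) -> dict[str, Any]:
    if node.label == "TNM_Stage":
        code, category = node.key
        return {"code": code, "type": category}
    field_name = {
        "Patient": "patient_id",
        "Pathology_Report": "report_id",
        "Grade": "grade_group",
        "PSA_Value": "value",
        "AJCC_Stage": "label",
    }[node.label]
    return {field_name: node.key}


def export_graph(graph: PropertyGraph, format: str) -> bytes:
    """Serialize the graph: ``graphml``, ``cypher`` (MERGE script) or ``json``."""
    if format == "json":
        payload = {
            "nodes": [
                {"label": n.label, "key": _key_to_json(n.key), "properties": n.props()}
                for n in _sorted_nodes(graph)
            ],
            "edges": [
                {
                    "type": e.type,
                    "source": {"label": e.source[0], "key": _key_to_json(e.source[1])},
                    "target": {"label": e.target[0], "key": _key_to_json(e.target[1])},
                }
                for e in _sorted_edges(graph)
            ],
        }
        return (json.dumps(payload, indent=2, sort_keys=True) + "\n").encode("utf-8")

    if format == "cypher":
        lines: list[str] = []
        for node in _sorted_nodes(graph):
            key_props = _node_key_props(node)
            lines.append(f"MERGE (n:{node.label} {_cypher_props(key_props)})")
            extra = {k: v for k, v in node.props().items() if k not in key_props}
            if extra:
                sets = ", ".join(
                    f"n.`{k}` = {_cypher_literal(v)}" for k, v in sorted(extra.items())
                )
                lines[-1] += f" SET {sets}"
            lines[-1] += ";"
        for e in _sorted_edges(graph):
            src = _node_key_props(graph.nodes[e.source])
            tgt = _node_key_props(graph.nodes[e.target])
            lines.append(
                f"MATCH (a:{e.source[0]} {_cypher_props(src)}), "
                f"(b:{e.target[0]} {_cypher_props(tgt)}) "
                f"MERGE (a)-[:{e.type}]->(b);"
            )
        text = "\n".join(lines)
        return (text + "\n").encode("utf-8") if lines else b""

    if format == "graphml":
        g = nx.MultiDiGraph()
        for node in _sorted_nodes(graph):
            node_id = f"{node.label}::{_sort_token(node.key)}"
            attrs = {k: v for k, v in node.props().items()}
            g.add_node(node_id, label=node.label, **attrs)
        for e in _sorted_edges(graph):
            g.add_edge(
                f"{e.source[0]}::{_sort_token(e.source[1])}",
                f"{e.target[0]}::{_sort_token(e.target[1])}",
                type=e.type,
            )
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue()

    raise ValueError(f"unsupported export format {format!r}")


def graph_from_json(data: Union[bytes, str]) -> PropertyGraph:
    """Parse the JSON dump produced by :func:`export_graph`."""
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    payload = json.loads(data)
    graph = PropertyGraph()
    for n in payload["nodes"]:
        graph.merge_node(n["label"], _key_from_json(n["key"]), n.get("properties") or {})
    for e in payload["edges"]:
        graph.add_edge(
            e["type"],
            (e["source"]["label"], _key_from_json(e["source"]["key"])),
            (e["target"]["label"], _key_from_json(e["target"]["key"])),
        )
    return graph
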