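"""Persist trained decision trees as property graphs and reload them.

A tree becomes a :class:`GraphBucket`: one node record per tree node
(label ``DTDecision`` or ``DTLeaf``) and one relationship record per
parent-child edge (type ``TRUE_BRANCH`` or ``FALSE_BRANCH``), exactly the
shape a graph database stores.  Buckets round-trip through JSON, can be
emitted as a deterministic Cypher CREATE script for loading into a graph
database shell, and optionally as GraphML.

Decision nodes carry the split condition (feature, kind, threshold or
category, missing-value routing); leaves carry the class label and the
training class distribution as parallel ``class_labels``/``class_counts``
arrays, which keeps every property JSON-scalar or JSON-array valued.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .splitting import CATEGORICAL_EQUALITY, NUMERIC_THRESHOLD, ClassDistribution
from .tree import (
    FALSE_BRANCH,
    TRUE_BRANCH,
    DecisionNode,
    DecisionTree,
    LeafNode,
    TreeNode,
    node_depth,
)

NODE_DECISION = "DTDecision"
NODE_LEAF = "DTLeaf"
REL_TRUE = "TRUE_BRANCH"
REL_FALSE = "FALSE_BRANCH"


class GraphFormatError(ValueError):
    """Raised when a bucket violates the rooted-binary-tree invariants."""


@dataclass
class GraphNodeRecord:
    id: str
    node_label: str
    properties: dict

    def __post_init__(self) -> None:
        if self.node_label not in (NODE_DECISION, NODE_LEAF):
            raise GraphFormatError(f"unknown node label: {self.node_label!r}")


@dataclass
class GraphRelationshipRecord:
    source_id: str
    target_id: str
    rel_type: str
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rel_type not in (REL_TRUE, REL_FALSE):
            raise GraphFormatError(f"unknown relationship type: {self.rel_type!r}")


@dataclass
class GraphBucket:
    """Node and relationship records representing one persisted tree."""

    nodes: list[GraphNodeRecord]
    relationships: list[GraphRelationshipRecord]

    def validate(self) -> str:
        """Check the rooted-binary-tree invariants; return the root id."""
        ids = [n.id for n in self.nodes]
        if not ids:
            raise GraphFormatError("empty bucket: no root node")
        if len(ids) != len(set(ids)):
            raise GraphFormatError("duplicate node ids")
        id_set = set(ids)
        for rel in self.relationships:
            if rel.source_id not in id_set or rel.target_id not in id_set:
                raise GraphFormatError(
                    f"dangling relationship {rel.source_id!r}->{rel.target_id!r}"
                )
        if len(self.relationships) != len(self.nodes) - 1:
            raise GraphFormatError(
                "a tree needs exactly |nodes| - 1 relationships"
            )
        targets = [r.target_id for r in self.relationships]
        if len(targets) != len(set(targets)):
            raise GraphFormatError("a node has more than one parent")
        roots = id_set - set(targets)
        if len(roots) != 1:
            raise GraphFormatError(f"expected exactly one root, found {len(roots)}")
        by_label = {n.id: n.node_label for n in self.nodes}
        outgoing: dict[str, list[str]] = {i: [] for i in ids}
        for rel in self.relationships:
            outgoing[rel.source_id].append(rel.rel_type)
        for node_id, label in by_label.items():
            rels = sorted(outgoing[node_id])
            if label == NODE_DECISION and rels != sorted([REL_TRUE, REL_FALSE]):
                raise GraphFormatError(
                    f"decision node {node_id!r} must have exactly one "
                    "TRUE_BRANCH and one FALSE_BRANCH"
                )
            if label == NODE_LEAF and rels:
                raise GraphFormatError(f"leaf node {node_id!r} has children")
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        g.add_edges_from((r.source_id, r.target_id) for r in self.relationships)
        if len(self.nodes) > 1 and not nx.is_arborescence(g):
            raise GraphFormatError("relationships do not form a rooted tree")
        (root,) = roots
        return root


def tree_to_graph(tree: DecisionTree) -> GraphBucket:
    """Export a tree as node and relationship buckets (pre-order ids kept)."""
    nodes: list[GraphNodeRecord] = []
    relationships: list[GraphRelationshipRecord] = []

    def walk(node: TreeNode) -> None:
        if isinstance(node, LeafNode):
            labels = sorted(node.distribution.counts)
            nodes.append(
                GraphNodeRecord(
                    id=node.node_id,
                    node_label=NODE_LEAF,
                    properties={
                        "label": node.label,
                        "level": node.level,
                        "class_labels": labels,
                        "class_counts": [
                            node.distribution.counts[l] for l in labels
                        ],
                    },
                )
            )
            return
        properties = {
            "feature": node.feature,
            "kind": node.kind,
            "level": node.level,
            "missing_branch": node.missing_branch,
        }
        if node.kind == NUMERIC_THRESHOLD:
            properties["threshold"] = float(node.threshold)
        else:
            properties["category"] = node.category
        nodes.append(
            GraphNodeRecord(
                id=node.node_id, node_label=NODE_DECISION, properties=properties
            )
        )
        for rel_type, child in (
            (REL_TRUE, node.true_child),
            (REL_FALSE, node.false_child),
        ):
            routed = (rel_type == REL_TRUE) == (node.missing_branch == TRUE_BRANCH)
            relationships.append(
                GraphRelationshipRecord(
                    source_id=node.node_id,
                    target_id=child.node_id,
                    rel_type=rel_type,
                    properties={"missing_routed": routed},
                )
            )
            walk(child)

    walk(tree.root)
    return GraphBucket(nodes=nodes, relationships=relationships)


def graph_to_tree(bucket: GraphBucket) -> DecisionTree:
    """Reconstruct a tree from a bucket; predictions are preserved.

    Training metadata (criterion, max_depth) is not stored in the bucket,
    so the reloaded tree carries None there.
    """
    root_id = bucket.validate()
    by_id = {n.id: n for n in bucket.nodes}
    children: dict[str, dict[str, str]] = {}
    for rel in bucket.relationships:
        children.setdefault(rel.source_id, {})[rel.rel_type] = rel.target_id

    def build(node_id: str, level: int) -> TreeNode:
        record = by_id[node_id]
        props = record.properties
        if record.node_label == NODE_LEAF:
            try:
                dist = ClassDistribution(
                    dict(zip(props["class_labels"], props["class_counts"]))
                )
                return LeafNode(
                    node_id=node_id,
                    label=str(props["label"]),
                    distribution=dist,
                    level=int(props.get("level", level)),
                )
            except (KeyError, ValueError) as exc:
                raise GraphFormatError(f"bad leaf node {node_id!r}: {exc}") from exc
        try:
            kind = props["kind"]
            if kind == NUMERIC_THRESHOLD:
                threshold, category = float(props["threshold"]), None
            elif kind == CATEGORICAL_EQUALITY:
                threshold, category = None, str(props["category"])
            else:
                raise GraphFormatError(f"unknown condition kind {kind!r}")
            missing_branch = props.get("missing_branch", TRUE_BRANCH)
            if missing_branch not in (TRUE_BRANCH, FALSE_BRANCH):
                raise GraphFormatError(
                    f"bad missing_branch {missing_branch!r} on {node_id!r}"
                )
            return DecisionNode(
                node_id=node_id,
                feature=str(props["feature"]),
                kind=kind,
                level=int(props.get("level", level)),
                true_child=build(children[node_id][REL_TRUE], level + 1),
                false_child=build(children[node_id][REL_FALSE], level + 1),
                threshold=threshold,
                category=category,
                missing_branch=missing_branch,
            )
        except KeyError as exc:
            raise GraphFormatError(
                f"bad decision node {node_id!r}: missing {exc}"
            ) from exc

    root = build(root_id, 0)
    labels: set[str] = set()
    for record in bucket.nodes:
        if record.node_label == NODE_LEAF:
            labels.update(str(l) for l in record.properties["class_labels"])
            labels.add(str(record.properties["label"]))
    return DecisionTree(
        root=root,
        criterion=None,
        class_labels=tuple(sorted(labels)),
        max_depth=None,
        depth=node_depth(root),
    )


# -- Cypher emission ---------------------------------------------------------


def _cypher_value(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_cypher_value(v) for v in value) + "]"
    text = str(value).replace("\\", "\\\\").replace("'", "\\'")
    return f"'{text}'"


def _cypher_props(properties: dict) -> str:
    parts = [
        f"`{key}`: {_cypher_value(value)}"
        for key, value in properties.items()
        if value is not None
    ]
    return "{" + ", ".join(parts) + "}"


def _id_sort_key(node_id: str) -> tuple[int, str]:
    return (len(node_id), node_id)


def emit_cypher(bucket: GraphBucket) -> str:
    """A deterministic Cypher script recreating the bucket.

    One CREATE per node, then one MATCH...CREATE per relationship keyed on
    the ``id`` property.  Ordering is fixed (nodes by id, relationships by
    source id then TRUE before FALSE) so identical buckets emit
    byte-identical text.
    """
    bucket.validate()
    lines = []
    for node in sorted(bucket.nodes, key=lambda n: _id_sort_key(n.id)):
        props = {"id": node.id, **node.properties}
        lines.append(f"CREATE (:`{node.node_label}` {_cypher_props(props)});")
    rel_order = {REL_TRUE: 0, REL_FALSE: 1}
    for rel in sorted(
        bucket.relationships,
        key=lambda r: (_id_sort_key(r.source_id), rel_order[r.rel_type]),
    ):
        lines.append(
            f"MATCH (a {{`id`: {_cypher_value(rel.source_id)}}}), "
            f"(b {{`id`: {_cypher_value(rel.target_id)}}}) "
            f"CREATE (a)-[:`{rel.rel_type}` {_cypher_props(rel.properties)}]->(b);"
        )
    return "\n".join(lines) + "\n"


# -- JSON serialisation ------------------------------------------------------


def bucket_to_dict(bucket: GraphBucket) -> dict:
    return {
        "nodes": [
            {"id": n.id, "node_label": n.node_label, "properties": n.properties}
            for n in bucket.nodes
        ],
        "relationships": [
            {
                "source_id": r.source_id,
                "target_id": r.target_id,
                "rel_type": r.rel_type,
                "properties": r.properties,
            }
            for r in bucket.relationships
        ],
    }


def bucket_from_dict(payload: dict) -> GraphBucket:
    if not isinstance(payload, dict) or not {"nodes", "relationships"} <= set(
        payload
    ):
        raise GraphFormatError('bucket JSON needs "nodes" and "relationships"')
    try:
        bucket = GraphBucket(
            nodes=[
                GraphNodeRecord(
                    id=str(n["id"]),
                    node_label=n["node_label"],
                    properties=dict(n.get("properties", {})),
                )
                for n in payload["nodes"]
            ],
            relationships=[
                GraphRelationshipRecord(
                    source_id=str(r["source_id"]),
                    target_id=str(r["target_id"]),
                    rel_type=r["rel_type"],
                    properties=dict(r.get("properties", {})),
                )
                for r in payload["relationships"]
            ],
        )
    except (KeyError, TypeError) as exc:
        raise GraphFormatError(f"malformed bucket JSON: {exc}") from exc
    bucket.validate()
    return bucket


def bucket_to_json(bucket: GraphBucket, path: str | Path) -> None:
    """Write the bucket as JSON (round-trips through bucket_from_json)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bucket_to_dict(bucket), fh, indent=2)
        fh.write("\n")


def bucket_from_json(path: str | Path) -> GraphBucket:
    """Parse and validate a bucket JSON file."""
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GraphFormatError(f"malformed JSON: {exc}") from exc
    return bucket_from_dict(payload)


# -- GraphML (optional writer) ----------------------------------------------


def bucket_to_graphml(bucket: GraphBucket, path: str | Path) -> None:
    """Write the bucket as GraphML; list-valued properties are stored as
    JSON strings since GraphML attributes are scalar."""
    bucket.validate()
    g = nx.DiGraph()
    for node in bucket.nodes:
        attrs = {"node_label": node.node_label}
        for key, value in node.properties.items():
            if value is None:
                continue
            attrs[key] = (
                json.dumps(value) if isinstance(value, (list, tuple)) else value
            )
        g.add_node(node.id, **attrs)
    for rel in bucket.relationships:
        g.add_edge(
            rel.source_id,
            rel.target_id,
            rel_type=rel.rel_type,
            **{k: v for k, v in rel.properties.items() if v is not None},
        )
    nx.write_graphml(g, str(path))
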