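"""Directed causal graphs, hub importance, and sub-network scanning.

A node's importance is measured by out-degree: the count of directed links it
sends.  The scan repeatedly removes the currently most influential nodes and
re-infers the network on the remaining channels.  When a pair of reciprocal
links (a 2-cycle, "feedback structure") appears in a sub-network even though
the full system is feed-forward, the usual cause is a common driver that was
dropped from the analysis — marginalizing a shared input leaves correlated
innovations that Granger methods read as mutual influence.  The scan
therefore treats feedback pairs appearing after hub removal as evidence of
unobserved important components, and the channels participating in them as
the candidates for who that hidden component was driving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np

__all__ = [
    "CausalGraph",
    "ScanStep",
    "ScanReport",
    "HiddenHubEvidence",
    "out_degree",
    "important_nodes",
    "two_cycles",
    "subnetwork_scan",
    "hidden_hub_evidence",
]


@dataclass(frozen=True)
class CausalGraph:
    """Directed graph over channel labels with optional edge weights.

    ``edges`` maps ordered (source, target) pairs to a weight (or ``None``).
    Self-loops are rejected; every endpoint must be a known node.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = tuple(str(v) for v in self.nodes)
        node_set = set(nodes)
        if len(node_set) != len(nodes):
            raise ValueError("duplicate node labels")
        edges = {}
        for (u, v), w in self.edges.items():
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop {u}->{v} not allowed")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {u}->{v} references unknown node")
            edges[(u, v)] = None if w is None else float(w)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return (str(edge[0]), str(edge[1])) in self.edges

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, **({} if w is None else {"weight": w}))
        return g


def out_degree(graph: CausalGraph, node: str) -> int:
    """Number of directed links the node sends."""
    node = str(node)
    if node not in graph.nodes:
        raise KeyError(f"unknown node {node!r}")
    return sum(1 for (u, _v) in graph.edges if u == node)


def important_nodes(graph: CausalGraph) -> set[str]:
    """Nodes attaining the maximum out-degree (empty if the graph has no edges)."""
    if not graph.nodes:
        raise ValueError("graph has no nodes")
    if not graph.edges:
        return set()
    degs = {v: out_degree(graph, v) for v in graph.nodes}
    top = max(degs.values())
    return {v for v, d in degs.items() if d == top}


def two_cycles(graph: CausalGraph) -> set[frozenset[str]]:
    """Unordered pairs {u, v} with both u->v and v->u present."""
    return {
        frozenset((u, v))
        for (u, v) in graph.edges
        if (v, u) in graph.edges and u < v
    }


# ---------------------------------------------------------------------------
# sub-network scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanStep:
    """One scan stage: cumulative omitted set, inferred graph, its summary."""

    omitted: frozenset[str]
    graph: CausalGraph
    important: frozenset[str]
    feedback_pairs: frozenset[frozenset[str]]


@dataclass(frozen=True)
class HiddenHubEvidence:
    """Summary of whether the scan points at an unobserved important node.

    ``flag`` is raised when any step shows a feedback pair.  ``common_nodes``
    intersects the feedback participants across the steps that show feedback
    (the nodes a hidden hub would have driven at every stage); with a single
    such step it equals that step's pair.  ``union_nodes`` collects all
    feedback participants.  ``gained_out_links`` lists, per step after the
    first, the surviving nodes whose out-degree grew when the hubs above
    them were removed.
    """

    flag: bool
    common_nodes: frozenset[str]
    union_nodes: frozenset[str]
    gained_out_links: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class ScanReport:
    """Ordered record of a leave-important-nodes-out scan."""

    steps: tuple[ScanStep, ...]
    evidence: HiddenHubEvidence
    failure: str | None = None

    def __post_init__(self) -> None:
        omitted = [step.omitted for step in self.steps]
        for a, b in zip(omitted, omitted[1:]):
            if not (a < b):
                raise ValueError("omitted sets must strictly increase")

    @property
    def feedback_pairs(self) -> tuple[frozenset[frozenset[str]], ...]:
        return tuple(step.feedback_pairs for step in self.steps)


def hidden_hub_evidence(steps: Iterable[ScanStep]) -> HiddenHubEvidence:
    """Combine per-step feedback structures into a hidden-hub summary."""
    steps = list(steps)
    with_fb = [s for s in steps if s.feedback_pairs]
    union: set[str] = set()
    for s in with_fb:
        for pair in s.feedback_pairs:
            union |= set(pair)
    if len(with_fb) >= 2:
        per_step = [
            set().union(*(set(pair) for pair in s.feedback_pairs))
            for s in with_fb
        ]
        common = set.intersection(*per_step)
    else:
        common = set(union)
    gained: list[frozenset[str]] = []
    for prev, cur in zip(steps, steps[1:]):
        prev_deg = {v: out_degree(prev.graph, v) for v in prev.graph.nodes}
        cur_deg = {v: out_degree(cur.graph, v) for v in cur.graph.nodes}
        gained.append(frozenset(
            v for v, d in cur_deg.items() if d > prev_deg.get(v, 0)
        ))
    return HiddenHubEvidence(
        flag=bool(with_fb),
        common_nodes=frozenset(common),
        union_nodes=frozenset(union),
        gained_out_links=tuple(gained),
    )


def subnetwork_scan(
    panel,
    infer: "Callable[[object], CausalGraph] | str",
    max_depth: int = 3,
    min_channels: int = 3,
    config=None,
) -> ScanReport:
    """Leave-important-nodes-out scan.

    ``infer`` is either a method name (``"rpdc"`` or ``"dpc"``, configured
    by ``config``, a :class:`gcnet.config.RunConfig`) or a callback mapping
    a panel to a :class:`CausalGraph`.  Step 0 infers on all observed
    channels; each later step drops the channels of the current
    maximal-out-degree nodes (ties removed together), refits from scratch
    and records any feedback pairs.  The scan stops when no node is
    important, fewer than ``min_channels`` channels would remain, or
    ``max_depth`` removal steps have run.  An inference failure is recorded
    and stops the scan gracefully.
    """
    if isinstance(infer, str):
        from .config import RunConfig
        from .pipeline import make_inferrer
        cfg = (config if config is not None else RunConfig()).with_overrides(
            method=infer
        )
        max_depth = cfg.max_depth
        min_channels = cfg.min_channels
        infer = make_inferrer(cfg)
    if panel.n < min_channels:
        raise ValueError(
            f"scan needs at least {min_channels} channels, got {panel.n}"
        )
    steps: list[ScanStep] = []
    omitted: set[str] = set()
    current = panel
    failure = None
    for depth in range(max_depth + 1):
        try:
            graph = infer(current)
        except Exception as exc:  # recorded, scan stops gracefully
            failure = f"inference failed at step {depth}: {exc}"
            break
        imp = important_nodes(graph)
        steps.append(ScanStep(
            omitted=frozenset(omitted),
            graph=graph,
            important=frozenset(imp),
            feedback_pairs=frozenset(two_cycles(graph)),
        ))
        if not imp or depth == max_depth:
            break
        if current.n - len(imp) < min_channels:
            break
        omitted = omitted | imp
        current = current.drop(imp)
    return ScanReport(
        steps=tuple(steps),
        evidence=hidden_hub_evidence(steps),
        failure=failure,
    )
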