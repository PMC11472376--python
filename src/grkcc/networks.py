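"""Common-tendency conformational-change networks across subfamilies.

A pair (residue- or SSE-level) shows a *common tendency* when its CC score
is nonzero with the same sign in both subfamilies (GRK2/3 and GRK4/5/6):
opposing signs likely indicate subfamily bias rather than a global
movement, and are excluded.  Edges carry the summed CC of the two
subfamilies; residue-level networks additionally keep only edges whose
|sum| strictly exceeds a threshold (default 1), suppressing subtle changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .contacts import ScoreTable
from .labels import GCLLabel, SSEKey, parse_gcl_label

__all__ = [
    "NetworkPolicy",
    "CommonPair",
    "ChangeNetwork",
    "common_tendency_pairs",
    "build_change_network",
    "export_graph",
    "import_graph",
]


@dataclass
class NetworkPolicy:
    residue_threshold: float = 1.0  # strict > on |cc_a + cc_b|, residue level only
    require_same_sign: bool = True

    def __post_init__(self) -> None:
        if self.residue_threshold < 0:
            raise ValueError("residue_threshold must be >= 0")


@dataclass(frozen=True)
class CommonPair:
    pair: tuple  # (GCLLabel, GCLLabel) or (SSEKey, SSEKey), ordered
    cc_a: float
    cc_b: float

    @property
    def total(self) -> float:
        return self.cc_a + self.cc_b


def common_tendency_pairs(cc_a: ScoreTable, cc_b: ScoreTable) -> list[CommonPair]:
    """Pairs present in both tables with strictly same-signed nonzero CC.

    A CC of zero in either table excludes the pair (zero has no sign).
    Raises on a level mismatch.
    """
    if cc_a.level != cc_b.level:
        raise ValueError(f"level mismatch: {cc_a.level!r} vs {cc_b.level!r}")
    scores_b = cc_b.cc_scores()
    out = []
    for pair in cc_a.pairs:
        if pair not in scores_b:
            continue
        va, vb = cc_a.cc(pair), scores_b[pair]
        if va == 0.0 or vb == 0.0 or (va > 0) != (vb > 0):
            continue
        out.append(CommonPair(pair=pair, cc_a=va, cc_b=vb))
    return out


@dataclass
class ChangeNetwork:
    """Graph of common-tendency changes; nodes are exactly the edge endpoints."""

    level: str  # 'residue' | 'sse'
    graph: nx.Graph

    @property
    def edges(self) -> list[tuple]:
        return sorted(
            ((min(u, v), max(u, v)) for u, v in self.graph.edges), key=lambda e: e
        )

    def edge_weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def hub_ranking(self) -> list[tuple[str, int]]:
        """Nodes by descending degree (ties broken by name) — hub identification."""
        return sorted(self.graph.degree, key=lambda kv: (-kv[1], kv[0]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChangeNetwork):
            return NotImplemented
        if self.level != other.level:
            return False
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        def edge_set(g):
            return {
                (min(u, v), max(u, v)): (
                    round(d["cc_a"], 9),
                    round(d["cc_b"], 9),
                    round(d["weight"], 9),
                    d["direction"],
                )
                for u, v, d in g.edges(data=True)
            }
        return edge_set(self.graph) == edge_set(other.graph)


def build_change_network(
    common: Sequence[CommonPair],
    policy: NetworkPolicy | None = None,
    level: str = "residue",
) -> ChangeNetwork:
    """Assemble the change network from common-tendency pairs.

    Residue level: keep edges with ``|cc_a + cc_b| > residue_threshold``
    (strict).  SSE level: keep all common-tendency edges.  Node set is the
    endpoints of surviving edges only.
    """
    policy = policy or NetworkPolicy()
    g = nx.Graph(level=level)
    for cp in common:
        total = cp.total
        if level == "residue" and abs(total) <= policy.residue_threshold:
            continue
        u, v = str(cp.pair[0]), str(cp.pair[1])
        g.add_edge(
            u,
            v,
            cc_a=cp.cc_a,
            cc_b=cp.cc_b,
            weight=total,
            direction="closed-favoring" if total > 0 else "open-favoring",
        )
    return ChangeNetwork(level=level, graph=g)


def _edge_records(net: ChangeNetwork) -> list[dict]:
    records = []
    for u, v in net.edges:
        d = net.graph.edges[u, v]
        records.append(
            {
                "label_i": u,
                "label_j": v,
                "cc_grk23": d["cc_a"],
                "cc_grk456": d["cc_b"],
                "sum": d["weight"],
                "direction": d["direction"],
            }
        )
    return records


def export_graph(net: ChangeNetwork, path: str | Path, format: str = "graphml") -> Path:
    """Write a network as graphml, json-edges, or tsv (deterministic ordering).

    graphml and json-edges round-trip losslessly through
    :func:`import_graph`; tsv is a flat edge table.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph(level=net.level)
        for node in sorted(net.graph.nodes):
            g.add_node(node)
        for u, v in net.edges:
            g.add_edge(u, v, **net.graph.edges[u, v])
        nx.write_graphml(g, path)
    elif format == "json-edges":
        payload = {
            "level": net.level,
            "nodes": sorted(net.graph.nodes),
            "edges": _edge_records(net),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif format == "tsv":
        pd.DataFrame(
            _edge_records(net),
            columns=["label_i", "label_j", "cc_grk23", "cc_grk456", "sum", "direction"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def import_graph(path: str | Path, format: str = "graphml") -> ChangeNetwork:
    """Read a network written by :func:`export_graph` (graphml or json-edges)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        level = g.graph.get("level", "residue")
        out = nx.Graph(level=level)
        for node in g.nodes:
            out.add_node(node)
        for u, v, d in g.edges(data=True):
            out.add_edge(
                u,
                v,
                cc_a=float(d["cc_a"]),
                cc_b=float(d["cc_b"]),
                weight=float(d["weight"]),
                direction=d["direction"],
            )
        return ChangeNetwork(level=level, graph=out)
    if format == "json-edges":
        payload = json.loads(path.read_text())
        g = nx.Graph(level=payload["level"])
        for node in payload["nodes"]:
            g.add_node(node)
        for rec in payload["edges"]:
            g.add_edge(
                rec["label_i"],
                rec["label_j"],
                cc_a=rec["cc_grk23"],
                cc_b=rec["cc_grk456"],
                weight=rec["sum"],
                direction=rec["direction"],
            )
        return ChangeNetwork(level=payload["level"], graph=g)
    raise ValueError(f"unknown format {format!r}")
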