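"""Frame-to-frame nucleus linking into lineage forests with division detection.

Linking is deterministic greedy globally-shortest-first one-to-one matching
within a distance gate, followed by a division pass that lets an unmatched
next-frame nucleus attach as a second child of its nearest already-matched
parent. Trees always point forward in time regardless of scan direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

CENTROID_COLS = ["centroid_y_um", "centroid_x_um"]


@dataclass
class LineageForest:
    """Directed forest over (frame, label) nodes; out-degree-2 nodes are divisions."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        g = self.graph
        for node in g.nodes:
            if g.out_degree(node) > 2:
                raise ValueError(f"node {node} has out-degree > 2")
            if g.in_degree(node) > 1:
                raise ValueError(f"node {node} has in-degree > 1")
        for u, v in g.edges:
            if v[0] != u[0] + 1:
                raise ValueError(f"edge {u}->{v} does not connect consecutive frames")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("lineage forest contains a cycle")

    @property
    def roots(self) -> list[tuple[int, int]]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    @property
    def divisions(self) -> list[tuple[int, int]]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 2)

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "frame": int(f),
                    "label": int(l),
                    **{k: float(v) for k, v in self.graph.nodes[(f, l)].items()},
                }
                for f, l in sorted(self.graph.nodes)
            ],
            "edges": [
                {
                    "parent": [int(u[0]), int(u[1])],
                    "child": [int(v[0]), int(v[1])],
                }
                for u, v in sorted(self.graph.edges)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageForest":
        g = nx.DiGraph()
        for node in d["nodes"]:
            attrs = {k: v for k, v in node.items() if k not in ("frame", "label")}
            g.add_node((node["frame"], node["label"]), **attrs)
        for edge in d["edges"]:
            g.add_edge(tuple(edge["parent"]), tuple(edge["child"]))
        return cls(g)


def link_frames(a: pd.DataFrame, b: pd.DataFrame, gate_um: float) -> list[tuple[int, int]]:
    """Link nuclei of frame t (``a``) to frame t+1 (``b``).

    Greedy shortest-first one-to-one matching within ``gate_um`` (distance
    ties broken by (a-label, b-label)); then each remaining unmatched
    b-nucleus whose nearest a-nucleus within the gate has exactly one child
    becomes that nucleus's second child. Returns (a-label, b-label) edges.
    """
    if gate_um <= 0:
        raise ValueError("gate_um must be > 0")
    if len(a) == 0 or len(b) == 0:
        return []
    pa = a[CENTROID_COLS].to_numpy(dtype=float)
    pb = b[CENTROID_COLS].to_numpy(dtype=float)
    la = a["label"].to_numpy()
    lb = b["label"].to_numpy()
    d = cdist(pa, pb)
    cand = np.argwhere(d <= gate_um)
    keys = sorted(
        ((d[i, j], la[i], lb[j], i, j) for i, j in cand),
        key=lambda t: (t[0], t[1], t[2]),
    )
    children: dict[int, list[int]] = {}
    matched_b: set[int] = set()
    matched_a: set[int] = set()
    edges: list[tuple[int, int]] = []
    for _, lai, lbj, i, j in keys:
        if i in matched_a or j in matched_b:
            continue
        matched_a.add(i)
        matched_b.add(j)
        children.setdefault(i, []).append(j)
        edges.append((int(lai), int(lbj)))
    # division pass: attach leftover b-nuclei as second children
    for j in range(len(b)):
        if j in matched_b:
            continue
        within = np.flatnonzero(d[:, j] <= gate_um)
        if within.size == 0:
            continue
        order = sorted(within, key=lambda i: (d[i, j], la[i]))
        for i in order:
            if len(children.get(i, [])) == 1:
                children[i].append(j)
                matched_b.add(j)
                edges.append((int(la[i]), int(lb[j])))
                break
    return edges


def build_forest(
    frames: list[pd.DataFrame],
    gate_um: float,
    direction: str = "forward",
) -> LineageForest:
    """Apply pairwise linking over a frame sequence; edges point forward.

    ``direction`` controls the scan order over adjacent pairs; pairwise
    linking is order-independent, so both directions yield the same forest
    (the backward scan mirrors tracking a movie from its final frame).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to build a forest")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be forward or backward")
    g = nx.DiGraph()
    for t, table in enumerate(frames):
        for _, row in table.iterrows():
            g.add_node(
                (t, int(row["label"])),
                centroid_y_um=float(row["centroid_y_um"]),
                centroid_x_um=float(row["centroid_x_um"]),
            )
    pair_order = range(len(frames) - 1)
    if direction == "backward":
        pair_order = reversed(list(pair_order))
    for t in pair_order:
        for la, lb in link_frames(frames[t], frames[t + 1], gate_um):
            g.add_edge((t, la), (t + 1, lb))
    return LineageForest(g)


def summarize_forest(forest: LineageForest) -> dict:
    """Counts: trees rooted at frame 0, division events, final-frame leaves."""
    g = forest.graph
    if len(g) == 0:
        return {"lineages_frame0": 0, "divisions": 0, "terminal_tracks": 0}
    last = max(f for f, _ in g.nodes)
    return {
        "lineages_frame0": sum(1 for f, _ in forest.roots if f == 0),
        "divisions": len(forest.divisions),
        "terminal_tracks": sum(
            1 for n in g.nodes if n[0] == last and g.out_degree(n) == 0
        ),
    }


def brute_force_min_matching(
    pa: np.ndarray, pb: np.ndarray, gate_um: float
) -> tuple[float, list[tuple[int, int]]]:
    """Exhaustive optimal one-to-one matching (test oracle; tiny inputs only).

    Maximizes the number of matched pairs within the gate, then minimizes
    total distance among maximum matchings.
    """
    from itertools import combinations, permutations

    pa = np.atleast_2d(pa)
    pb = np.atleast_2d(pb)
    na, nb = len(pa), len(pb)
    if na * nb == 0:
        return 0.0, []
    d = cdist(pa, pb)
    idx_b = list(range(nb))
    for r in range(min(na, nb), 0, -1):
        best_total = np.inf
        best_pairs: list[tuple[int, int]] = []
        for a_sub in combinations(range(na), r):
            for b_perm in permutations(idx_b, r):
                if any(d[i, j] > gate_um for i, j in zip(a_sub, b_perm)):
                    continue
                total = sum(d[i, j] for i, j in zip(a_sub, b_perm))
                if total < best_total:
                    best_total = total
                    best_pairs = list(zip(a_sub, b_perm))
        if best_pairs:
            return float(best_total), best_pairs
    return 0.0, []
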