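"""Vessel centerline graphs.

A :class:`CenterlineGraph` represents an arterial tree as branches (polylines
in world mm) joined at nodes (root / bifurcation / endpoint).  It is produced
either analytically by the phantom generator or by skeletonizing a vessel mask
(:mod:`sirtdose.territories`), and consumed by the territory-labeling step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass
class Node:
    id: int
    position: np.ndarray  # (3,) world mm
    kind: str  # "root" | "bifurcation" | "endpoint"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Branch:
    id: int
    points: np.ndarray  # (N, 3) world mm, ordered start->end
    start_node: int
    end_node: int

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise InvalidInputError(f"branch {self.id}: polyline needs >= 2 points")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class CenterlineGraph:
    """A rooted tree of vessel branches."""

    nodes: dict[int, Node] = field(default_factory=dict)
    branches: dict[int, Branch] = field(default_factory=dict)
    root_node: int = 0

    # -- topology helpers ---------------------------------------------------

    def node_branches(self) -> dict[int, list[int]]:
        """node id -> ids of incident branches."""
        adj: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for b in self.branches.values():
            adj[b.start_node].append(b.id)
            adj[b.end_node].append(b.id)
        return adj

    def _bfs(self):
        """Breadth-first sweep from the root over branches.

        Returns (generations, parent, children) keyed by branch id; the
        generation of a branch incident to the root node is 1.
        """
        adj = self.node_branches()
        gens: dict[int, int] = {}
        parent: dict[int, int | None] = {}
        children: dict[int, list[int]] = {b: [] for b in self.branches}
        frontier = [(self.root_node, 0, None)]
        seen_nodes = {self.root_node}
        while frontier:
            nxt = []
            for node, g, parent_branch in frontier:
                for bid in sorted(adj.get(node, [])):
                    if bid in gens:
                        continue
                    gens[bid] = g + 1
                    parent[bid] = parent_branch
                    if parent_branch is not None:
                        children[parent_branch].append(bid)
                    b = self.branches[bid]
                    other = b.end_node if b.start_node == node else b.start_node
                    if other not in seen_nodes:
                        seen_nodes.add(other)
                        nxt.append((other, g + 1, bid))
            frontier = nxt
        if len(gens) != len(self.branches):
            raise InvalidInputError("centerline graph is not connected to its root")
        return gens, parent, children

    def branch_generations(self) -> dict[int, int]:
        return self._bfs()[0]

    def branch_children(self) -> dict[int, list[int]]:
        return self._bfs()[2]

    def leaf_branches(self) -> list[int]:
        children = self.branch_children()
        return sorted(b for b, ch in children.items() if not ch)

    def total_length_mm(self) -> float:
        return sum(b.length_mm for b in self.branches.values())

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "root_node": self.root_node,
            "nodes": [
                {"id": n.id, "position_mm": n.position.tolist(), "kind": n.kind}
                for n in self.nodes.values()
            ],
            "branches": [
                {
                    "id": b.id,
                    "points_mm": b.points.tolist(),
                    "start_node": b.start_node,
                    "end_node": b.end_node,
                }
                for b in self.branches.values()
            ],
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CenterlineGraph":
        obj = json.loads(text)
        nodes = {
            n["id"]: Node(n["id"], np.asarray(n["position_mm"]), n["kind"])
            for n in obj["nodes"]
        }
        branches = {
            b["id"]: Branch(
                b["id"], np.asarray(b["points_mm"]), b["start_node"], b["end_node"]
            )
            for b in obj["branches"]
        }
        return cls(nodes=nodes, branches=branches, root_node=obj["root_node"])


def canonicalize_branch_ids(graph: CenterlineGraph) -> dict[int, int]:
    """Renumber branches 1..B by polyline centroid (lexicographic on mm).

    Branch ids are used as the deterministic tie-break in nearest-branch
    labeling, so they must not depend on construction order: a ground-truth
    tree and its skeleton-based reconstruction get (near-)identical numbering
    when their geometry matches.  Returns the old->new id map.
    """

    def key(b: Branch):
        c = b.points.mean(axis=0)
        return (c[0], c[1], c[2], b.id)

    order = sorted(graph.branches.values(), key=key)
    remap = {b.id: i + 1 for i, b in enumerate(order)}
    graph.branches = {
        remap[b.id]: Branch(remap[b.id], b.points, b.start_node, b.end_node)
        for b in order
    }
    return remap


def smooth_polyline(points: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Endpoint-preserving (1/4, 1/2, 1/4) smoothing of a polyline.

    Damps the one-voxel zigzag of skeleton voxel chains toward the underlying
    smooth centerline; endpoints (shared junction positions) stay fixed.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    for _ in range(int(iterations)):
        if p.shape[0] < 3:
            break
        q = p.copy()
        q[1:-1] = 0.25 * p[:-2] + 0.5 * p[1:-1] + 0.25 * p[2:]
        p = q
    return p


def densify_polyline(points: np.ndarray, step_mm: float = 1.0) -> np.ndarray:
    """Resample a polyline so consecutive points are <= step_mm apart.

    Original vertices are always retained; each segment is subdivided
    uniformly. Used to bound the point-to-polyline distance error in
    nearest-branch labeling below the voxel size.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        return pts
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.linalg.norm(seg) / step_mm)))
        t = np.arange(1, n + 1)[:, None] / n
        out.append(a + t * seg)
    return np.concatenate(out, axis=0)


def group_branches(
    graph: CenterlineGraph,
    generation: int | None = None,
    mapping: dict[int, object] | None = None,
) -> tuple[dict[int, int], dict[int, str]]:
    """Group branches into territories.

    Either an explicit ``mapping`` (branch id -> arbitrary territory key) or a
    ``generation`` g is given.  With g, the territories are the branch
    subtrees rooted at generation g: every branch of generation >= g maps to
    its generation-g ancestor.  Branches shallower than g (the feeding stem)
    define no territory and are left out of the returned map -- they are not
    assignable, and the liver volume around them is divided among the nearest
    generation-g subtrees purely by distance.  If g exceeds the tree depth
    entirely, each leaf branch becomes one territory (with a warning).

    Returns ``(branch_to_territory, territory_names)``; territory ids are
    numbered 1..K by anchor-branch centroid (a geometric order, stable
    between a ground-truth tree and its skeleton-based reconstruction).
    """
    if (generation is None) == (mapping is None):
        raise InvalidInputError("give exactly one of generation or mapping")
    if not graph.branches:
        raise InvalidInputError("empty centerline graph")

    if mapping is not None:
        missing = set(graph.branches) - set(mapping)
        if missing:
            raise InvalidInputError(f"mapping misses branches {sorted(missing)}")
        keys = sorted({str(mapping[b]) for b in graph.branches}, key=str)
        tid_of_key = {k: i + 1 for i, k in enumerate(keys)}
        branch_to_tid = {b: tid_of_key[str(mapping[b])] for b in graph.branches}
        names = {tid: k for k, tid in tid_of_key.items()}
        return branch_to_tid, names

    g = int(generation)  # type: ignore[arg-type]
    if g < 1:
        raise InvalidInputError("generation must be >= 1")
    gens, parent, children = graph._bfs()
    max_gen = max(gens.values())

    anchors: dict[int, int] = {}
    if g > max_gen:
        warnings.warn(
            f"grouping generation {g} exceeds tree depth {max_gen}; "
            "using one territory per leaf branch",
            stacklevel=2,
        )
        for bid in graph.branches:
            anchors[bid] = bid if not children[bid] else lowest_descendant_at_leaf(
                graph, children, bid
            )
    else:
        for bid in graph.branches:
            if gens[bid] < g:
                continue  # feeding stem: defines no territory, not assignable
            cur = bid
            while gens[cur] > g:
                cur = parent[cur]  # type: ignore[assignment]
            anchors[bid] = cur
        if not anchors:
            raise InvalidInputError("no branch reaches the grouping generation")

    # number territories by anchor-branch centroid (geometric, hence stable
    # between a ground-truth graph and its skeleton-based reconstruction)
    def _centroid_key(a: int):
        c = graph.branches[a].points.mean(axis=0)
        return (round(c[0], 3), round(c[1], 3), round(c[2], 3), a)

    anchor_ids = sorted(set(anchors.values()), key=_centroid_key)
    tid_of_anchor = {a: i + 1 for i, a in enumerate(anchor_ids)}
    branch_to_tid = {b: tid_of_anchor[a] for b, a in anchors.items()}
    names = {tid: f"territory_{tid:02d}" for tid in tid_of_anchor.values()}
    return branch_to_tid, names


def lowest_descendant_at_leaf(graph, children, bid):
    """Lowest-id leaf branch in the subtree of ``bid``."""
    stack, best = [bid], None
    while stack:
        cur = stack.pop()
        if not children[cur]:
            if best is None or cur < best:
                best = cur
        else:
            stack.extend(children[cur])
    return best
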