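"""Rooted airway centerline trees.

A tree is a set of :class:`CenterlineNode` (3-D position in world mm, radius,
parent link) with a single root at the tracheal origin.  The module provides
validation, decomposition into branches with generation levels (trachea = 0,
main bronchi = 1, so segmental/tertiary bronchi sit at generation 3),
propagation of single-point segmental-bronchus annotations through downstream
subtrees, and SWC I/O.

Generation counting: a branch is a maximal chain between consecutive branch
points (or root/leaf); the trachea chain is generation 0 and every child
branch adds 1.  Trifurcations and higher are allowed — the right main
bronchus feeds three lobar bronchi — and each child branch still gets
generation + 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CenterlineNode",
    "AirwayTree",
    "Branch",
    "SegmentalAnnotation",
    "validate_tree",
    "branch_decomposition",
    "segmental_candidates",
    "propagate_labels",
    "count_bifurcations",
    "labeled_point_sets",
    "resample_edges",
    "read_swc",
    "write_swc",
    "read_annotations",
    "write_annotations",
]

logger = logging.getLogger(__name__)

# SWC "type" column: 100 + segment code marks a labeled node; 0/1 unlabeled.
_SWC_LABEL_OFFSET = 100


@dataclass(frozen=True)
class CenterlineNode:
    """One centerline point: id, world position (mm), radius (mm), parent link."""

    id: int
    position: tuple[float, float, float]
    radius: float = 1.0
    parent_id: int = -1
    segment_label: int | None = None

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"node id must be positive, got {self.id}")
        if self.radius < 0:
            raise ValueError(f"node {self.id}: radius must be >= 0")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))


class AirwayTree:
    """Rooted centerline tree with unique node ids.

    Construction does not validate tree-ness; run :func:`validate_tree` (or
    any operation that requires a valid tree) to check the invariants.
    """

    def __init__(self, nodes) -> None:
        self.nodes: dict[int, CenterlineNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise ValueError(f"duplicate node id {n.id}")
            self.nodes[n.id] = n
        roots = [n.id for n in self.nodes.values() if n.parent_id == -1]
        self.root_id: int | None = roots[0] if len(roots) == 1 else None

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        return isinstance(other, AirwayTree) and self.nodes == other.nodes

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id != -1 and n.parent_id in ch:
                ch[n.parent_id].append(n.id)
        for lst in ch.values():
            lst.sort()
        return ch

    def positions(self, node_ids=None) -> np.ndarray:
        ids = list(self.nodes) if node_ids is None else list(node_ids)
        return np.array([self.nodes[i].position for i in ids], dtype=float)

    def with_labels(self, labels: dict[int, int]) -> "AirwayTree":
        """Copy of the tree with ``segment_label`` replaced per ``labels``."""
        return AirwayTree(
            replace(n, segment_label=labels.get(n.id)) for n in self.nodes.values()
        )


@dataclass(frozen=True)
class Branch:
    """Maximal unbranched chain of node ids plus its generation level."""

    node_ids: tuple[int, ...]
    generation: int


@dataclass(frozen=True)
class SegmentalAnnotation:
    """One clicked centerline point per segmental bronchus: node id -> code."""

    entries: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = list(self.entries.values())
        dup = {c for c in codes if codes.count(c) > 1}
        if dup:
            raise ValueError(f"segment codes annotated more than once: {sorted(dup)}")


# -- validation ---------------------------------------------------------------


def validate_tree(tree: AirwayTree) -> list[str]:
    """Return a list of invariant violations (empty iff the tree is valid)."""
    report: list[str] = []
    if not tree.nodes:
        report.append("tree has no nodes")
        return report
    roots = [n.id for n in tree.nodes.values() if n.parent_id == -1]
    if len(roots) == 0:
        report.append("no root (no node with parent -1)")
    elif len(roots) > 1:
        report.append(f"multiple roots: nodes {sorted(roots)}")
    for n in tree.nodes.values():
        if n.parent_id == n.id:
            report.append(f"node {n.id} is its own parent")
        elif n.parent_id != -1 and n.parent_id not in tree.nodes:
            report.append(f"node {n.id} has dangling parent {n.parent_id}")
    # reachability from the root detects cycles and disconnected components
    if len(roots) == 1 and not report:
        ch = tree.children_map()
        seen: set[int] = set()
        stack = [roots[0]]
        while stack:
            nid = stack.pop()
            if nid in seen:
                report.append(f"cycle involving node {nid}")
                return report
            seen.add(nid)
            stack.extend(ch[nid])
        unreachable = set(tree.nodes) - seen
        if unreachable:
            report.append(
                f"cycle or disconnected nodes not reachable from root: "
                f"{sorted(unreachable)[:10]}"
            )
    return report


def _require_valid(tree: AirwayTree) -> None:
    report = validate_tree(tree)
    if report:
        raise ValueError("invalid airway tree: " + "; ".join(report))


# -- branch decomposition -----------------------------------------------------


def branch_decomposition(tree: AirwayTree) -> list[Branch]:
    """Split the tree into maximal chains between branch points.

    Every node belongs to exactly one branch.  The chain containing the root
    (the trachea) is generation 0; children of the first bifurcation — the
    left and right main bronchi — are generation 1.
    """
    _require_valid(tree)
    ch = tree.children_map()
    branches: list[Branch] = []
    # (first node of branch, generation)
    stack: list[tuple[int, int]] = [(tree.root_id, 0)]
    while stack:
        start, gen = stack.pop()
        chain = [start]
        while len(ch[chain[-1]]) == 1:
            chain.append(ch[chain[-1]][0])
        branches.append(Branch(tuple(chain), gen))
        for child in reversed(ch[chain[-1]]):
            stack.append((child, gen + 1))
    branches.sort(key=lambda b: b.node_ids[0])
    return branches


def segmental_candidates(tree: AirwayTree) -> list[Branch]:
    """Generation-3 branches (the segmental/tertiary bronchi), by first node id."""
    return [b for b in branch_decomposition(tree) if b.generation == 3]


def count_bifurcations(tree: AirwayTree, *, split_multifurcations: bool = True) -> int:
    """Number of bifurcations in the tree.

    With ``split_multifurcations`` (default) a node with ``c`` children counts
    as ``c - 1`` bifurcations, so the total equals (#leaves - 1) and is stable
    under a trifurcation being represented as two nearby bifurcations.
    Otherwise branch-point nodes (>= 2 children) are counted once each.
    """
    ch = tree.children_map()
    if split_multifurcations:
        return sum(max(0, len(c) - 1) for c in ch.values())
    return sum(1 for c in ch.values() if len(c) >= 2)


# -- label propagation --------------------------------------------------------


def propagate_labels(tree: AirwayTree, ann: SegmentalAnnotation) -> AirwayTree:
    """Propagate clicked segmental-bronchus labels downstream.

    For each annotation (node n, code k) the whole branch containing n and
    every node in that branch's downstream subtree receive label k.  Nodes
    upstream of the segmental level stay unlabeled.  Overlapping propagation
    regions are an error (each bronchus must have a unique, unambiguous
    label); annotating a branch whose generation is not 3 logs a warning but
    proceeds, since traced trees can miss a generation.
    """
    _require_valid(tree)
    branches = branch_decomposition(tree)
    branch_of: dict[int, Branch] = {}
    for b in branches:
        for nid in b.node_ids:
            branch_of[nid] = b
    ch = tree.children_map()

    labels: dict[int, int] = {}
    claimed_by: dict[int, int] = {}  # node id -> segment code that claimed it
    for node_id, code in sorted(ann.entries.items()):
        if node_id not in tree.nodes:
            raise ValueError(f"annotated node {node_id} not in tree")
        b = branch_of[node_id]
        if b.generation != 3:
            logger.warning(
                "annotation for segment %d sits on a generation-%d branch "
                "(expected 3); propagating anyway",
                code,
                b.generation,
            )
        region = list(b.node_ids)
        stack = [c for c in ch[b.node_ids[-1]]]
        while stack:
            nid = stack.pop()
            region.append(nid)
            stack.extend(ch[nid])
        for nid in region:
            prev = claimed_by.get(nid)
            if prev is not None and prev != code:
                raise ValueError(
                    f"conflicting annotation: segments {prev} and {code} both "
                    f"propagate to node {nid}"
                )
            claimed_by[nid] = code
            labels[nid] = code
    return tree.with_labels(labels)


# -- edge resampling and labeled point sets -----------------------------------


def resample_edges(tree: AirwayTree, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Densely sample every parent-child edge at <= ``step_mm``.

    Returns ``(points, labels)``: an (N, 3) array of world-mm points covering
    all node positions plus interior edge samples, and the per-point segment
    label (0 where unlabeled).  Interior samples of an edge carry the shared
    label of its endpoints, or 0 if the endpoints disagree (the junction edge
    entering a labeled subtree contributes only its labeled endpoint).
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    pts: list[np.ndarray] = []
    labs: list[np.ndarray] = []
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        pts.append(np.asarray(n.position, dtype=float)[None, :])
        labs.append(np.array([n.segment_label or 0]))
        if n.parent_id == -1 or n.parent_id not in tree.nodes:
            continue
        p = tree.nodes[n.parent_id]
        a = np.asarray(p.position, dtype=float)
        b = np.asarray(n.position, dtype=float)
        length = float(np.linalg.norm(b - a))
        nseg = int(np.ceil(length / step_mm))
        if nseg > 1:
            t = np.arange(1, nseg)[:, None] / nseg
            interior = a[None, :] * (1 - t) + b[None, :] * t
            pts.append(interior)
            la = p.segment_label or 0
            lb = n.segment_label or 0
            lab = la if la == lb else 0
            labs.append(np.full(len(interior), lab))
    return np.concatenate(pts, axis=0), np.concatenate(labs, axis=0).astype(int)


def labeled_point_sets(tree: AirwayTree, step_mm: float) -> dict[int, np.ndarray]:
    """Per-segment dense point sets (world mm) of the labeled centerline.

    The point set of segment k is every node labeled k plus edge samples whose
    two endpoints are both labeled k — i.e. the entire tertiary branch and its
    downstream sub-branches after :func:`propagate_labels`.
    """
    points, labels = resample_edges(tree, step_mm)
    return {
        int(k): points[labels == k]
        for k in np.unique(labels)
        if k != 0
    }


# -- SWC I/O ------------------------------------------------------------------


def read_swc(path) -> AirwayTree:
    """Read an SWC morphology file.

    Dialect: whitespace-separated columns ``id type x y z radius parent``,
    ``#`` comments, ids need not be contiguous, and a parent may be defined
    later in the file (two-pass read).  A type of 100 + code encodes a
    segment label; other types are treated as unlabeled.
    """
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed SWC line: {exc}") from exc
    ids = {r[0] for r in rows}
    nodes = []
    for nid, typ, x, y, z, radius, parent in rows:
        if parent != -1 and parent not in ids:
            raise ValueError(f"{path}: node {nid} references missing parent {parent}")
        label = typ - _SWC_LABEL_OFFSET if typ > _SWC_LABEL_OFFSET else None
        nodes.append(
            CenterlineNode(
                id=nid,
                position=(x, y, z),
                radius=radius,
                parent_id=parent,
                segment_label=label,
            )
        )
    tree = AirwayTree(nodes)
    report = validate_tree(tree)
    if report:
        raise ValueError(f"{path}: invalid tree: " + "; ".join(report))
    return tree


def write_swc(tree: AirwayTree, path) -> None:
    """Write SWC; segment labels go to the type column as 100 + code."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(tree.nodes):
            n = tree.nodes[nid]
            typ = _SWC_LABEL_OFFSET + n.segment_label if n.segment_label else 1
            x, y, z = n.position
            fh.write(
                f"{n.id} {typ} {x:.6f} {y:.6f} {z:.6f} {n.radius:.6f} {n.parent_id}\n"
            )


def read_annotations(path) -> SegmentalAnnotation:
    """Read annotation JSON: a list of ``{"node_id": int, "segment": int}``."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        entries = {int(e["node_id"]): int(e["segment"]) for e in data}
    except (KeyError, TypeError) as exc:
        raise ValueError(
            f"{path}: expected a list of objects with node_id and segment"
        ) from exc
    return SegmentalAnnotation(entries)


def write_annotations(ann: SegmentalAnnotation, path) -> None:
    data = [
        {"node_id": nid, "segment": code} for nid, code in sorted(ann.entries.items())
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
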