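"""Reading, validating and writing SWC morphology files.

SWC is the interchange format for 3D-traced cell skeletons: one sample per
line with seven whitespace-separated columns
``id type x y z radius parent_id`` (coordinates and radius in micrometres,
``parent_id == -1`` marking the root) and ``#`` comment lines.  Files are
exposed as :class:`RootedTree` objects — soma-rooted trees, the input of the
topological morphology descriptor.

Somata are frequently exported as a contour of several label-1 samples rather
than a single point.  Because the descriptor needs exactly one root, all
contiguous soma samples are collapsed into a single root placed at the first
soma sample's coordinates, and children of collapsed samples are re-parented
to that root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

SOMA_LABEL = 1

__all__ = [
    "SwcNode",
    "RootedTree",
    "SwcParseError",
    "SwcStructureError",
    "read_swc",
    "write_swc",
    "tree_summary",
]


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcStructureError(ValueError):
    """The samples do not form a single rooted tree."""


@dataclass(frozen=True)
class SwcNode:
    """One SWC sample point.

    Attributes
    ----------
    id : int
        Positive sample identifier, unique within a file.
    structure_label : int
        SWC structure code; ``1`` marks the soma.  Other codes are kept but
        carry no topological meaning here.
    x, y, z : float
        Position in micrometres.
    radius : float
        Local process radius in micrometres (non-negative).
    parent_id : int
        Identifier of the parent sample, ``-1`` for the root.
    """

    id: int
    structure_label: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class RootedTree:
    """A soma-rooted skeleton: nodes plus parent→children adjacency.

    Parameters
    ----------
    nodes : sequence of SwcNode
        Must contain exactly one root (``parent_id == -1``); every other
        node's parent must exist.  Node order is preserved.
    source_id : str
        Label identifying the provenance of the tree (file stem, generator
        tag, ...).
    """

    def __init__(self, nodes: Sequence[SwcNode], source_id: str = "") -> None:
        nodes = list(nodes)
        if not nodes:
            raise SwcStructureError("tree has zero nodes")
        ids = [n.id for n in nodes]
        if len(set(ids)) != len(ids):
            raise SwcStructureError("duplicate node ids")
        by_id = {n.id: n for n in nodes}
        roots = [n for n in nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SwcStructureError(
                f"expected exactly one root, found {len(roots)}"
            )
        children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent_id == -1:
                continue
            if n.parent_id not in by_id:
                raise SwcStructureError(
                    f"node {n.id} has dangling parent {n.parent_id}"
                )
            children[n.parent_id].append(n.id)
        # connectivity + acyclicity: walk from the root, every node must be
        # reached exactly once
        root = roots[0]
        seen: set[int] = set()
        stack = [root.id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise SwcStructureError("cycle detected")
            seen.add(nid)
            stack.extend(children[nid])
        if len(seen) != len(nodes):
            raise SwcStructureError("tree is not connected")
        for n in nodes:
            if not all(map(math.isfinite, (n.x, n.y, n.z, n.radius))):
                raise SwcStructureError(f"non-finite coordinate in node {n.id}")
            if n.radius < 0:
                raise SwcStructureError(f"negative radius in node {n.id}")

        self.nodes: list[SwcNode] = nodes
        self.root: SwcNode = root
        self.children: dict[int, list[int]] = children
        self.by_id: dict[int, SwcNode] = by_id
        self.source_id = source_id

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[SwcNode]:
        return iter(self.nodes)

    @property
    def leaves(self) -> list[SwcNode]:
        return [n for n in self.nodes if not self.children[n.id]]

    def coords(self) -> np.ndarray:
        """(n, 3) array of node positions in file order."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def radial_distance(self, node: SwcNode) -> float:
        """Euclidean distance from ``node`` to the root (µm)."""
        r = self.root
        return math.dist((node.x, node.y, node.z), (r.x, r.y, r.z))

    def radial_distances(self) -> dict[int, float]:
        """Radial distance of every node, keyed by node id."""
        return {n.id: self.radial_distance(n) for n in self.nodes}


@dataclass(frozen=True)
class TreeSummary:
    n_nodes: int
    n_leaves: int
    n_bifurcations: int
    total_length: float
    max_radial_distance: float


def _parse_line(line: str, lineno: int) -> SwcNode:
    parts = line.split()
    if len(parts) != 7:
        raise SwcParseError(
            f"line {lineno}: expected 7 columns, got {len(parts)}"
        )
    try:
        return SwcNode(
            id=int(parts[0]),
            structure_label=int(parts[1]),
            x=float(parts[2]),
            y=float(parts[3]),
            z=float(parts[4]),
            radius=float(parts[5]),
            parent_id=int(parts[6]),
        )
    except ValueError as exc:
        raise SwcParseError(f"line {lineno}: {exc}") from None


def _collapse_soma(nodes: list[SwcNode]) -> list[SwcNode]:
    """Collapse all label-1 samples into a single root node.

    The root keeps the first soma sample's id and coordinates; children of any
    collapsed soma sample are re-parented to it.  Leaf count and the geometry
    of non-soma segments are unchanged.
    """
    soma_ids = {n.id for n in nodes if n.structure_label == SOMA_LABEL}
    if len(soma_ids) <= 1:
        return nodes
    first = next(n for n in nodes if n.structure_label == SOMA_LABEL)
    out: list[SwcNode] = []
    for n in nodes:
        if n.structure_label == SOMA_LABEL:
            if n.id == first.id:
                out.append(
                    SwcNode(first.id, SOMA_LABEL, first.x, first.y, first.z,
                            first.radius, -1)
                )
            continue
        parent = first.id if n.parent_id in soma_ids else n.parent_id
        out.append(SwcNode(n.id, n.structure_label, n.x, n.y, n.z, n.radius,
                           parent))
    return out


def read_swc(path) -> RootedTree:
    """Parse an SWC file into a validated :class:`RootedTree`.

    ``#`` comment lines and blank lines are skipped.  Multi-sample somata are
    collapsed to a single root (see module docstring).

    Raises
    ------
    SwcParseError
        On a malformed line (with its line number).
    SwcStructureError
        If the samples contain a cycle, a dangling parent, several roots, or
        no nodes at all.
    """
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            nodes.append(_parse_line(line, lineno))
    if not nodes:
        raise SwcStructureError(f"{path}: no sample lines (empty input)")
    nodes = _collapse_soma(nodes)
    import os

    stem = os.path.splitext(os.path.basename(str(path)))[0]
    return RootedTree(nodes, source_id=stem)


def write_swc(tree: RootedTree, path) -> None:
    """Write a tree in standard 7-column SWC, space-delimited.

    Coordinates are written with ``repr``-style shortest round-trip floats so
    that ``read_swc(write_swc(t))`` reproduces them exactly.
    """
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in tree.nodes:
            fh.write(
                f"{n.id} {n.structure_label} {n.x!r} {n.y!r} {n.z!r} "
                f"{n.radius!r} {n.parent_id}\n"
            )


def tree_summary(tree: RootedTree) -> TreeSummary:
    """Basic geometric summary: node/leaf/bifurcation counts, total cable
    length (sum of parent–child segment lengths, µm) and maximal radial
    distance from the root (µm)."""
    total = 0.0
    for n in tree.nodes:
        if n.parent_id == -1:
            continue
        p = tree.by_id[n.parent_id]
        total += math.dist((n.x, n.y, n.z), (p.x, p.y, p.z))
    rmax = max(tree.radial_distance(n) for n in tree.nodes)
    n_leaves = len(tree.leaves)
    n_bifs = sum(
        1
        for n in tree.nodes
        if len(tree.children[n.id]) >= 2 and n.id != tree.root.id
    )
    return TreeSummary(
        n_nodes=len(tree.nodes),
        n_leaves=n_leaves,
        n_bifurcations=n_bifs,
        total_length=total,
        max_radial_distance=rmax,
    )
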