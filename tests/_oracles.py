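"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the barcode
oracle is a superlevel-set threshold sweep with union–find over the tree's
undirected adjacency, not the branch-point recursion of the package.
"""

from __future__ import annotations

import numpy as np

from morphomics.swc_io import RootedTree


class _DSU:
    def __init__(self):
        self.parent: dict[int, int] = {}
        self.info: dict[int, tuple[float, int]] = {}  # root -> (max_f, carrier)

    def make(self, x: int, f: float) -> None:
        self.parent[x] = x
        self.info[x] = (f, x)

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> tuple[tuple[float, int], tuple[float, int]]:
        """Merge the sets of a and b; returns (survivor, dying) info."""
        ra, rb = self.find(a), self.find(b)
        ia, ib = self.info[ra], self.info[rb]
        # elder rule: larger max f survives; ties -> smaller carrier id
        if (ia[0], -ia[1]) >= (ib[0], -ib[1]):
            surv, die, keep = ia, ib, ra
            self.parent[rb] = ra
        else:
            surv, die, keep = ib, ia, rb
            self.parent[ra] = rb
        self.info[keep] = surv
        return surv, die


def union_find_barcode(tree: RootedTree) -> list[tuple[float, float]]:
    """Superlevel threshold sweep: insert nodes by decreasing radial
    distance, union with already-present neighbors, record a bar whenever a
    younger component dies, and one essential bar for the final component."""
    f = tree.radial_distances()
    neighbors: dict[int, list[int]] = {n.id: [] for n in tree.nodes}
    for n in tree.nodes:
        if n.parent_id != -1:
            neighbors[n.id].append(n.parent_id)
            neighbors[n.parent_id].append(n.id)

    order = sorted(f, key=lambda nid: (-f[nid], nid))
    dsu = _DSU()
    present: set[int] = set()
    bars: list[tuple[float, float]] = []
    for nid in order:
        dsu.make(nid, f[nid])
        for nb in neighbors[nid]:
            if nb in present and dsu.find(nb) != dsu.find(nid):
                _, dying = dsu.union(nid, nb)
                # the singleton of the node being inserted dying at its own
                # value is not a feature (zero persistence, non-maximum)
                if dying[1] != nid:
                    bars.append((dying[0], f[nid]))
        present.add(nid)
    root_comp = dsu.info[dsu.find(tree.root.id)]
    bars.append((root_comp[0], f[tree.root.id]))
    return bars


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
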