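"""Classic morphometric features and Sholl analysis.

These are the feature-selection baselines of microglial morphology work:
scalar summaries of the skeleton (total process length, branch / bifurcation
/ tip counts, and an extensible registry for larger feature sets) and Sholl
curves — the number of processes crossing concentric spheres centered on the
soma at fixed radius steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .swc_io import RootedTree, tree_summary

__all__ = [
    "MorphometricVector",
    "ShollCurve",
    "classic_morphometrics",
    "sholl_curve",
    "FEATURE_REGISTRY",
    "register_feature",
    "feature_vector",
]


@dataclass(frozen=True)
class MorphometricVector:
    """Named scalar features of one tree."""

    total_length: float
    n_branch: int
    n_bifs: int
    n_tips: int
    extra: dict[str, float] | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "total_length": self.total_length,
            "n_branch": float(self.n_branch),
            "n_bifs": float(self.n_bifs),
            "n_tips": float(self.n_tips),
        }
        if self.extra:
            d.update(self.extra)
        return d


@dataclass(frozen=True)
class ShollCurve:
    """Crossing counts at radii step, 2·step, ... (µm)."""

    radii: np.ndarray
    crossings: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(
            self, "crossings", np.asarray(self.crossings, dtype=int)
        )


def classic_morphometrics(tree: RootedTree) -> MorphometricVector:
    """The four canonical features.

    ``total_length``: sum of parent–child segment lengths (µm).
    ``n_tips``: leaf count.  ``n_bifs``: nodes with ≥ 2 children, excluding
    the soma root.  ``n_branch``: maximal unbranched paths between
    root/bifurcations/tips (each stem's initial path counts once).
    """
    s = tree_summary(tree)
    # each maximal unbranched path ends at a bifurcation child start...
    # count paths by their terminal node: every leaf ends one path, and every
    # bifurcation (non-root) ends one path; plus stems ending at root children
    # are already covered because a path ends where a bifurcation or tip is.
    n_branch = 0
    for n in tree.nodes:
        if n.id == tree.root.id:
            continue
        kids = tree.children[n.id]
        if not kids or len(kids) >= 2:
            n_branch += 1  # path terminating at a tip or a bifurcation
    return MorphometricVector(
        total_length=s.total_length,
        n_branch=n_branch,
        n_bifs=s.n_bifurcations,
        n_tips=s.n_leaves,
    )


def sholl_curve(tree: RootedTree, step: float) -> ShollCurve:
    """Sholl crossing counts at concentric spheres of radius k·step.

    An edge counts as crossing radius ``r`` when its endpoint radial
    distances straddle it: one endpoint < r, the other ≥ r (endpoints exactly
    on the sphere count as ≥ r).  Each straddling edge counts once per
    sphere.  Radii run to the first multiple of ``step`` beyond the maximal
    radial extent, where the count is 0 by construction.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    f = tree.radial_distances()
    edges = [
        (f[n.parent_id], f[n.id]) for n in tree.nodes if n.parent_id != -1
    ]
    rmax = max(f.values())
    n_spheres = int(math.floor(rmax / step)) + 1
    radii = step * np.arange(1, n_spheres + 1)
    crossings = np.zeros(n_spheres, dtype=int)
    for fa, fb in edges:
        lo, hi = min(fa, fb), max(fa, fb)
        for k, r in enumerate(radii):
            if lo < r <= hi:
                crossings[k] += 1
    return ShollCurve(radii, crossings)


# ----------------------------------------------------------------------
# extensible feature registry (for extended classifier sets)
# ----------------------------------------------------------------------

FEATURE_REGISTRY: dict[str, Callable[[RootedTree], float]] = {}


def register_feature(name: str):
    """Decorator adding a scalar feature ``tree -> float`` to the registry."""

    def deco(fn: Callable[[RootedTree], float]):
        FEATURE_REGISTRY[name] = fn
        return fn

    return deco


@register_feature("total_length")
def _f_total_length(tree: RootedTree) -> float:
    return tree_summary(tree).total_length


@register_feature("n_branch")
def _f_n_branch(tree: RootedTree) -> float:
    return float(classic_morphometrics(tree).n_branch)


@register_feature("n_bifs")
def _f_n_bifs(tree: RootedTree) -> float:
    return float(tree_summary(tree).n_bifurcations)


@register_feature("n_tips")
def _f_n_tips(tree: RootedTree) -> float:
    return float(tree_summary(tree).n_leaves)


@register_feature("max_radial_distance")
def _f_max_radial(tree: RootedTree) -> float:
    return tree_summary(tree).max_radial_distance


@register_feature("mean_segment_length")
def _f_mean_seg(tree: RootedTree) -> float:
    s = tree_summary(tree)
    n_edges = s.n_nodes - 1
    return s.total_length / n_edges if n_edges else 0.0


def feature_vector(
    tree: RootedTree, names: list[str] | None = None
) -> np.ndarray:
    """Evaluate registry features (all, or a named subset) on one tree."""
    if names is None:
        names = sorted(FEATURE_REGISTRY)
    return np.array([FEATURE_REGISTRY[n](tree) for n in names], dtype=float)
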