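"""Synthetic soma-rooted trees with controllable branching statistics.

The generator is a biased Galton–Watson growth process: ``n_stems`` primary
processes leave the soma; each growing tip extends a straight segment whose
length is Normal(mean, sd) truncated to positive values, in a direction that
mixes the previous segment direction with the outward radial direction
(``radial_drift`` = 1 gives purely radial, hence monotone, growth), and then
bifurcates with probability ``branch_prob`` until ``max_depth`` generations.
This is deliberately the simplest model with tunable leaf count, depth and
radial extent: leaf counts follow a closed-form branching-process expectation,
and monotone growth admits closed-form persistence barcodes, so every
downstream stage can be tested without imaging data.

Two stock presets, ``condition_A`` and ``condition_B``, differ in ``max_depth``
and ``segment_length_mean`` and serve as separable populations in end-to-end
tests; their geometry targets ramified cells of roughly 40–60 µm radial
extent with a handful of primary processes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .swc_io import RootedTree, SwcNode, write_swc

__all__ = [
    "TreeModelParams",
    "generate_tree",
    "generate_population",
    "write_population",
    "expected_leaf_count",
    "PRESETS",
]


@dataclass(frozen=True)
class TreeModelParams:
    """Parameters of the stochastic growth model.

    Attributes
    ----------
    n_stems : int
        Number of primary processes leaving the soma (≥ 1).
    branch_prob : float
        Probability in (0, 1) that a tip bifurcates at the end of each
        segment, while below ``max_depth``.
    max_depth : int
        Maximum number of segment generations per stem.
    segment_length_mean, segment_length_sd : float
        Mean and SD (µm) of the truncated-normal segment length.
    radial_drift : float
        Weight in [0, 1] mixing the outward radial direction into each new
        segment direction; 1 forces strictly outward (monotone) growth.
    seed : int
        RNG seed; generation is fully reproducible given the seed.
    """

    n_stems: int = 4
    branch_prob: float = 0.45
    max_depth: int = 6
    segment_length_mean: float = 7.0
    segment_length_sd: float = 2.0
    radial_drift: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.branch_prob < 1.0:
            raise ValueError("branch_prob must be in (0, 1)")
        if self.segment_length_mean <= 0:
            raise ValueError("segment_length_mean must be positive")
        if self.n_stems < 1:
            raise ValueError("n_stems must be ≥ 1")
        if not 0.0 <= self.radial_drift <= 1.0:
            raise ValueError("radial_drift must be in [0, 1]")


#: Stock presets used by separation tests: B is shallower but longer-segmented
#: than A, shifting both leaf-count and bar-length distributions.
PRESETS: dict[str, TreeModelParams] = {
    "condition_A": TreeModelParams(
        n_stems=4, branch_prob=0.45, max_depth=6,
        segment_length_mean=6.0, segment_length_sd=1.5, radial_drift=0.7,
    ),
    "condition_B": TreeModelParams(
        n_stems=4, branch_prob=0.45, max_depth=4,
        segment_length_mean=11.0, segment_length_sd=1.5, radial_drift=0.7,
    ),
}


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else v


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # truncation at 0 by resampling; falls back to a nominal small length if
    # the tail makes resampling hopeless (never happens for sane params)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    return 1e-3


def generate_tree(params: TreeModelParams, source_id: str = "synthetic") -> RootedTree:
    """Grow one random tree; soma at the origin, ``n_stems`` root children."""
    rng = np.random.default_rng(params.seed)
    nodes: list[SwcNode] = [SwcNode(1, 1, 0.0, 0.0, 0.0, 2.0, -1)]
    next_id = 2
    # stack of growing tips: (parent_id, position, direction, depth)
    tips: list[tuple[int, np.ndarray, np.ndarray, int]] = []
    for _ in range(params.n_stems):
        tips.append((1, np.zeros(3), _random_unit(rng), 1))
    # depth-first, deterministic order
    while tips:
        parent_id, pos, direction, depth = tips.pop()
        length = _positive_normal(
            rng, params.segment_length_mean, params.segment_length_sd
        )
        radial = _unit(pos) if np.linalg.norm(pos) > 0 else direction
        direction = _unit(
            (1.0 - params.radial_drift) * direction
            + params.radial_drift * radial
        )
        new_pos = pos + length * direction
        node = SwcNode(
            next_id, 3,
            float(new_pos[0]), float(new_pos[1]), float(new_pos[2]),
            0.5, parent_id,
        )
        nodes.append(node)
        nid = next_id
        next_id += 1
        if depth < params.max_depth and rng.random() < params.branch_prob:
            for _ in range(2):
                # jitter child directions so branches diverge
                child_dir = _unit(direction + 0.6 * rng.normal(size=3))
                tips.append((nid, new_pos, child_dir, depth + 1))
    return RootedTree(nodes, source_id=source_id)


def expected_leaf_count(params: TreeModelParams) -> float:
    """Closed-form expected leaf count of the branching process.

    A tip that has just finished the segment of generation ``d`` bifurcates
    with probability ``p`` while ``d < max_depth``; so the expected number of
    leaves below it satisfies L(max_depth) = 1 and
    L(d) = (1 − p) + 2 p L(d + 1).
    """
    p = params.branch_prob
    L = 1.0
    for _ in range(params.max_depth - 1):
        L = (1.0 - p) + 2.0 * p * L
    return params.n_stems * L


def generate_population(
    params_by_condition: dict[str, TreeModelParams],
    n_per_condition: int,
) -> dict[str, list[RootedTree]]:
    """Generate ``n_per_condition`` trees per condition.

    Each tree's seed is derived deterministically from the condition's seed
    and its index, so a population is reproducible per (condition, seed) and
    adding a condition never perturbs another.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be ≥ 1")
    out: dict[str, list[RootedTree]] = {}
    for condition, params in params_by_condition.items():
        seq = np.random.SeedSequence(params.seed)
        child_seeds = seq.generate_state(n_per_condition) % (2**31)
        trees = [
            generate_tree(
                replace(params, seed=int(s)),
                source_id=f"{condition}_{i:04d}",
            )
            for i, s in enumerate(child_seeds)
        ]
        out[condition] = trees
    return out


def write_population(
    population: dict[str, list[RootedTree]], out_dir
) -> str:
    """Write a population as SWC files plus a TSV manifest.

    Returns the manifest path.  Manifest columns: filename, condition,
    source_id.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("filename\tcondition\tsource_id\n")
        for condition, trees in population.items():
            for t in trees:
                fname = f"{t.source_id}.swc"
                write_swc(t, os.path.join(out_dir, fname))
                fh.write(f"{fname}\t{condition}\t{t.source_id}\n")
    return manifest
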