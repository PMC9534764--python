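"""Bootstrapped summaries: variability reduction by subsampling.

Individual cells within a condition vary widely; pooling tames this.  From a
starting population of ``n`` cells per condition, each draw picks
``bootstrap_size`` (x) *unique* cells without replacement, combines them
(pooled bars for persistence images and stable ranks, means for feature and
Sholl vectors), and the draw is repeated ``n_samples`` (m) times
independently — the same subset may recur across draws.  The m combined
summaries form the bootstrap sample, the unit that is embedded downstream.

Per-condition RNG streams are derived from the master seed and the condition
name, so adding or removing a condition never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .morphometrics import MorphometricVector, ShollCurve
from .tmd_core import (
    Bar,
    ImageGrid,
    PersistenceBarcode,
    PersistenceDiagram,
    PersistenceImage,
    diagram_to_persistence_image,
)

__all__ = [
    "BootstrapSpec",
    "BootstrapSample",
    "condition_rng",
    "bootstrap_persistence_images",
    "bootstrap_barcodes",
    "bootstrap_feature_vectors",
    "bootstrap_sholl",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap protocol: x unique cells per draw, m draws, master seed."""

    bootstrap_size: int
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_size < 1:
            raise ValueError("bootstrap_size must be ≥ 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")


@dataclass
class BootstrapSample:
    """m bootstrapped items per condition, with their provenance.

    ``items`` and ``labels`` are parallel; ``member_indices[i]`` records the
    cell indices (within that item's condition) pooled into item i.  Images
    in one sample always share one grid.
    """

    labels: list[str]
    items: list
    spec: BootstrapSpec
    member_indices: list[tuple[int, ...]]
    grid: ImageGrid | None = None
    kind: str = "persistence_image"

    def __len__(self) -> int:
        return len(self.items)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def subset(self, condition: str) -> "BootstrapSample":
        keep = [i for i, lab in enumerate(self.labels) if lab == condition]
        return BootstrapSample(
            [self.labels[i] for i in keep],
            [self.items[i] for i in keep],
            self.spec,
            [self.member_indices[i] for i in keep],
            self.grid,
            self.kind,
        )

    def as_matrix(self) -> np.ndarray:
        """(m_total, p) matrix: flattened pixels or feature vectors."""
        if self.kind == "persistence_image":
            return np.stack([im.ravel() for im in self.items])
        return np.stack([np.asarray(v, dtype=float).ravel() for v in self.items])

    @staticmethod
    def concatenate(samples: Sequence["BootstrapSample"]) -> "BootstrapSample":
        first = samples[0]
        for s in samples[1:]:
            if s.kind != first.kind or s.grid != first.grid:
                raise ValueError("cannot concatenate incompatible samples")
        return BootstrapSample(
            sum((s.labels for s in samples), []),
            sum((s.items for s in samples), []),
            first.spec,
            sum((s.member_indices for s in samples), []),
            first.grid,
            first.kind,
        )


def condition_rng(seed: int, condition: str) -> np.random.Generator:
    """Independent, reproducible stream per (master seed, condition name)."""
    key = zlib.crc32(condition.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _draw_indices(
    rng: np.random.Generator, n: int, spec: BootstrapSpec, condition: str
) -> list[tuple[int, ...]]:
    if spec.bootstrap_size > n:
        raise ValueError(
            f"condition {condition!r}: bootstrap_size {spec.bootstrap_size} "
            f"exceeds population size {n}"
        )
    return [
        tuple(sorted(rng.choice(n, size=spec.bootstrap_size, replace=False)))
        for _ in range(spec.n_samples)
    ]


def bootstrap_barcodes(
    barcodes: Mapping[str, Sequence[PersistenceBarcode]],
    spec: BootstrapSpec,
) -> BootstrapSample:
    """Pool the bar multisets of each draw into one barcode per item.

    This is the shared first step of bootstrapped persistence images and
    bootstrapped stable ranks.
    """
    labels: list[str] = []
    items: list[PersistenceBarcode] = []
    members: list[tuple[int, ...]] = []
    for condition in barcodes:
        pop = list(barcodes[condition])
        rng = condition_rng(spec.seed, condition)
        for j, idx in enumerate(_draw_indices(rng, len(pop), spec, condition)):
            bars: list[Bar] = []
            for i in idx:
                bars.extend(pop[i].bars)
            labels.append(condition)
            items.append(
                PersistenceBarcode(tuple(bars),
                                   source_id=f"{condition}_bs{j:04d}")
            )
            members.append(idx)
    return BootstrapSample(labels, items, spec, members, grid=None,
                           kind="barcode")


def bootstrap_persistence_images(
    barcodes: Mapping[str, Sequence[PersistenceBarcode]],
    spec: BootstrapSpec,
    grid: ImageGrid,
) -> BootstrapSample:
    """Bootstrapped persistence images: pooled bars of each draw, convolved
    and discretized on the shared grid."""
    pooled = bootstrap_barcodes(barcodes, spec)
    items = []
    for bc in pooled.items:
        pts = np.array(bc.bars, dtype=float) if bc.bars else np.empty((0, 2))
        items.append(
            diagram_to_persistence_image(
                PersistenceDiagram(pts), grid,
                n_source_cells=spec.bootstrap_size,
            )
        )
    return BootstrapSample(pooled.labels, items, spec, pooled.member_indices,
                           grid=grid, kind="persistence_image")


def bootstrap_feature_vectors(
    features: Mapping[str, Sequence], spec: BootstrapSpec
) -> BootstrapSample:
    """Per draw, the arithmetic mean of each morphometric feature across the
    x drawn cells — one feature vector per item."""
    labels: list[str] = []
    items: list[np.ndarray] = []
    members: list[tuple[int, ...]] = []
    for condition in features:
        pop = [
            np.array(list(v.as_dict().values()))
            if isinstance(v, MorphometricVector)
            else np.asarray(v, dtype=float)
            for v in features[condition]
        ]
        rng = condition_rng(spec.seed, condition)
        for idx in _draw_indices(rng, len(pop), spec, condition):
            labels.append(condition)
            items.append(np.mean([pop[i] for i in idx], axis=0))
            members.append(idx)
    return BootstrapSample(labels, items, spec, members, grid=None,
                           kind="feature_vector")


def bootstrap_sholl(
    curves: Mapping[str, Sequence[ShollCurve]], spec: BootstrapSpec
) -> BootstrapSample:
    """Per draw, the radius-wise mean Sholl curve across the x drawn cells.

    Curves must share a step size; shorter curves are zero-padded to the
    longest radius vector (crossings are 0 beyond a cell's extent, so
    padding never changes means on shared radii).
    """
    steps = {
        float(c.radii[0])
        for pop in curves.values()
        for c in pop
        if len(c.radii)
    }
    if len(steps) > 1:
        raise ValueError(f"incompatible Sholl step sizes: {sorted(steps)}")
    max_len = max(len(c.radii) for pop in curves.values() for c in pop)
    labels: list[str] = []
    items: list[np.ndarray] = []
    members: list[tuple[int, ...]] = []
    for condition in curves:
        pop = [
            np.pad(np.asarray(c.crossings, dtype=float),
                   (0, max_len - len(c.crossings)))
            for c in curves[condition]
        ]
        rng = condition_rng(spec.seed, condition)
        for idx in _draw_indices(rng, len(pop), spec, condition):
            labels.append(condition)
            items.append(np.mean([pop[i] for i in idx], axis=0))
            members.append(idx)
    return BootstrapSample(labels, items, spec, members, grid=None,
                           kind="sholl_curve")
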