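"""Topological morphology descriptor: barcodes and persistence images.

A soma-rooted tree ``T`` is summarized by its persistence barcode under the
radial-distance filtration ``f(v) = ||v - root||``.  Each bar ``(origin,
merge)`` records one persistent process: the radial distance at which the
process originates (its extremal radial extent) and the radial distance at
which it merges with a longer-lived process or reaches the soma.  Merging
follows the elder rule: at every branch point the child component with the
larger maximal radial distance survives, every other child component dies
there and emits a bar.  Each primary process (stem) finally merges at the
soma, giving one bar per stem with ``merge = 0``; the bar count equals the
leaf count.  The barcode is invariant under rotations about the root and
rigid translations of the tree.

Barcodes are vectorized as persistence images: each diagram point ``(origin,
merge)`` is convolved with an isotropic Gaussian kernel and the resulting
density is discretized on a shared grid and normalized to unit pixel sum.
Pixel-wise arithmetic on images with identical grids gives subtraction
images, the L1 ("TMD") distance, variability heat maps and representative
images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .swc_io import RootedTree

__all__ = [
    "Bar",
    "PersistenceBarcode",
    "PersistenceDiagram",
    "ImageGrid",
    "PersistenceImage",
    "compute_persistence_barcode",
    "barcode_to_diagram",
    "make_shared_grid",
    "diagram_to_persistence_image",
    "average_persistence_image",
    "subtract_images",
    "tmd_distance",
    "filter_barcode",
    "pixelwise_std_map",
    "representative_image",
]


class Bar(NamedTuple):
    """One bar of a persistence barcode, in µm.

    ``origin`` is the radial distance at which the process originates (the
    dying component's extremal value); ``merge`` the radial distance at which
    it merges with a more persistent process (0 for primary processes that
    reach the soma).
    """

    origin: float
    merge: float

    @property
    def length(self) -> float:
        return abs(self.origin - self.merge)

    @property
    def min_endpoint(self) -> float:
        return min(self.origin, self.merge)


@dataclass(frozen=True)
class PersistenceBarcode:
    bars: tuple[Bar, ...]
    source_id: str = ""

    @property
    def n_bars(self) -> int:
        return len(self.bars)

    def lengths(self) -> np.ndarray:
        return np.array([b.length for b in self.bars], dtype=float)

    def endpoints(self) -> np.ndarray:
        """Flat array of all bar endpoints (origins and merges)."""
        if not self.bars:
            return np.empty(0)
        return np.array(self.bars, dtype=float).ravel()


@dataclass(frozen=True)
class PersistenceDiagram:
    """Point-set view of a barcode: one (origin, merge) point per bar."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ImageGrid:
    """Shared discretization for persistence images.

    ``xlim``/``ylim`` are (low, high) bounds in µm, ``resolution`` the pixel
    count per axis, ``bandwidth`` the Gaussian kernel scale in µm or
    ``"auto"`` for Scott's rule on the pooled points (floored at one pixel
    width).  Images are comparable only when their grids are equal.
    """

    xlim: tuple[float, float]
    ylim: tuple[float, float]
    resolution: int = 100
    bandwidth: float | str = "auto"

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be ≥ 2")
        for lo, hi in (self.xlim, self.ylim):
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError("grid bounds must be finite with positive extent")

    @property
    def pixel_width(self) -> float:
        return (self.xlim[1] - self.xlim[0]) / self.resolution

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates along x and y."""
        xs = self.xlim[0] + (np.arange(self.resolution) + 0.5) * self.pixel_width
        dy = (self.ylim[1] - self.ylim[0]) / self.resolution
        ys = self.ylim[0] + (np.arange(self.resolution) + 0.5) * dy
        return xs, ys

    def to_dict(self) -> dict:
        return {
            "xlim": list(self.xlim),
            "ylim": list(self.ylim),
            "resolution": self.resolution,
            "bandwidth": self.bandwidth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGrid":
        return cls(tuple(d["xlim"]), tuple(d["ylim"]), d["resolution"],
                   d["bandwidth"])


@dataclass(frozen=True)
class PersistenceImage:
    """Discretized Gaussian-smoothed diagram; unit pixel sum unless empty.

    ``pixels[i, j]`` holds the density at (x-center j, y-center i).
    """

    pixels: np.ndarray
    grid: ImageGrid
    n_source_cells: int = 1
    is_empty: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)

    def ravel(self) -> np.ndarray:
        return self.pixels.ravel()


# ----------------------------------------------------------------------
# barcode computation
# ----------------------------------------------------------------------

def compute_persistence_barcode(tree: RootedTree) -> PersistenceBarcode:
    """Elder-rule persistence barcode under the radial-distance filtration.

    At each branch point, among the child components the one with the largest
    maximal radial distance survives (ties broken by the smaller carrier node
    id); each dying component emits ``Bar(its maximal value, f(branch))``.
    Multifurcations kill all non-maximal children at the same value.  Every
    stem's final surviving component merges at the soma with ``merge = 0``.

    Returns an empty barcode (with a warning) for a single-node tree.
    The bar count equals the leaf count.
    """
    if len(tree) == 1:
        warnings.warn("single-node tree has an empty barcode", stacklevel=2)
        return PersistenceBarcode((), source_id=tree.source_id)

    f = tree.radial_distances()
    children = tree.children
    bars: list[Bar] = []

    # iterative post-order: surviving component per node as (max_f, carrier id)
    surviving: dict[int, tuple[float, int]] = {}
    stack: list[tuple[int, bool]] = [(tree.root.id, False)]
    while stack:
        nid, expanded = stack.pop()
        kids = children[nid]
        if not expanded:
            stack.append((nid, True))
            for k in kids:
                stack.append((k, False))
            continue
        if nid == tree.root.id:
            continue  # root handled below
        if not kids:
            surviving[nid] = (f[nid], nid)
            continue
        comps = [surviving[k] for k in kids]
        # survivor: largest max f, ties to the smaller carrier node id
        win = max(range(len(comps)), key=lambda i: (comps[i][0], -comps[i][1]))
        for i, (val, _) in enumerate(comps):
            if i != win:
                bars.append(Bar(val, f[nid]))
        best = comps[win]
        if f[nid] > best[0]:
            best = (f[nid], nid)
        surviving[nid] = best

    # each stem's surviving component reaches the soma: merge at f(root) = 0
    for stem in children[tree.root.id]:
        val, _ = surviving[stem]
        bars.append(Bar(val, 0.0))

    return PersistenceBarcode(tuple(bars), source_id=tree.source_id)


def barcode_to_diagram(barcode: PersistenceBarcode) -> PersistenceDiagram:
    """One (origin, merge) point per bar; order-independent representation."""
    if not barcode.bars:
        return PersistenceDiagram(np.empty((0, 2)))
    return PersistenceDiagram(np.array(barcode.bars, dtype=float))


# ----------------------------------------------------------------------
# persistence images
# ----------------------------------------------------------------------

def make_shared_grid(
    barcodes: Iterable[PersistenceBarcode],
    resolution: int = 100,
    padding: float = 0.1,
    bandwidth: float | str = "auto",
) -> ImageGrid:
    """Square grid [0, (1 + padding) · max endpoint]² covering every bar
    endpoint of the collection; pixel-wise operations require all images in a
    comparison to share one such grid."""
    max_ep = 0.0
    any_bar = False
    for bc in barcodes:
        if bc.bars:
            any_bar = True
            max_ep = max(max_ep, float(bc.endpoints().max()))
    if not any_bar:
        raise ValueError("cannot build a grid: all barcodes are empty")
    hi = (1.0 + padding) * max_ep
    return ImageGrid((0.0, hi), (0.0, hi), resolution, bandwidth)


def _resolve_bandwidth(points: np.ndarray, grid: ImageGrid) -> float:
    if grid.bandwidth != "auto":
        bw = float(grid.bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
        return bw
    # Scott's rule for 2D data, isotropic: n^(-1/6) times the mean per-axis
    # spread, floored at one pixel width so single points remain visible
    n = len(points)
    spread = float(np.mean(points.std(axis=0))) if n > 1 else 0.0
    return max(spread * n ** (-1.0 / 6.0), grid.pixel_width)


def diagram_to_persistence_image(
    diagram: PersistenceDiagram,
    grid: ImageGrid,
    n_source_cells: int = 1,
) -> PersistenceImage:
    """Gaussian KDE of the diagram points at pixel centers, unit pixel sum.

    Each point contributes an isotropic Gaussian; the kernel is separable, so
    the image is assembled as an outer product of per-axis kernel matrices.
    An empty diagram yields an all-zero image flagged ``is_empty``.
    """
    res = grid.resolution
    pts = diagram.points
    if len(pts) == 0:
        return PersistenceImage(np.zeros((res, res)), grid, n_source_cells,
                                is_empty=True)
    if (pts[:, 0].min() < grid.xlim[0] or pts[:, 0].max() > grid.xlim[1]
            or pts[:, 1].min() < grid.ylim[0] or pts[:, 1].max() > grid.ylim[1]):
        raise ValueError("diagram points fall outside the grid bounds")
    sigma = _resolve_bandwidth(pts, grid)
    xs, ys = grid.centers()
    # (n_points, res) per-axis kernels; pixels = Ky^T @ Kx
    kx = np.exp(-((xs[None, :] - pts[:, 0:1]) ** 2) / (2.0 * sigma**2))
    ky = np.exp(-((ys[None, :] - pts[:, 1:2]) ** 2) / (2.0 * sigma**2))
    pixels = ky.T @ kx
    total = pixels.sum()
    if total > 0:
        pixels = pixels / total
    return PersistenceImage(pixels, grid, n_source_cells)


def average_persistence_image(
    barcodes: Sequence[PersistenceBarcode],
    grid: ImageGrid,
    method: str = "pooled",
) -> PersistenceImage:
    """Condition-level persistence image.

    ``method="pooled"`` (default) combines all bars of the collection into
    one diagram before convolution and discretization.  ``method="pixel_mean"``
    instead averages the individual cells' images pixel-wise; the two give
    qualitatively similar results.
    """
    barcodes = list(barcodes)
    if not barcodes:
        raise ValueError("need at least one barcode")
    if method == "pooled":
        pts = [np.array(bc.bars, dtype=float) for bc in barcodes if bc.bars]
        pooled = (
            np.vstack(pts) if pts else np.empty((0, 2))
        )
        return diagram_to_persistence_image(
            PersistenceDiagram(pooled), grid, n_source_cells=len(barcodes)
        )
    if method == "pixel_mean":
        imgs = [
            diagram_to_persistence_image(barcode_to_diagram(bc), grid)
            for bc in barcodes
        ]
        mean = np.mean([im.pixels for im in imgs], axis=0)
        return PersistenceImage(mean, grid, n_source_cells=len(barcodes))
    raise ValueError(f"unknown averaging method: {method!r}")


def _check_same_grid(a: PersistenceImage, b: PersistenceImage) -> None:
    if a.grid != b.grid:
        raise ValueError("persistence images are on different grids")


def subtract_images(a: PersistenceImage, b: PersistenceImage) -> np.ndarray:
    """Pixel-wise difference a − b (signed); requires identical grids.

    For unit-normalized inputs the result sums to 0 and reads as local over-
    (positive) versus under-representation (negative) of processes.
    """
    _check_same_grid(a, b)
    return a.pixels - b.pixels


def tmd_distance(a: PersistenceImage, b: PersistenceImage) -> float:
    """Sum of absolute pixel-wise differences (L1) between two images."""
    _check_same_grid(a, b)
    return float(np.abs(a.pixels - b.pixels).sum())


def filter_barcode(
    barcode: PersistenceBarcode,
    min_endpoint_max: float | None = None,
    max_bar_length: float | None = None,
) -> PersistenceBarcode:
    """Select bars by where they live on the filtration scale.

    ``min_endpoint_max`` keeps bars whose smaller endpoint is ≤ the threshold
    — with the default 0 µm (applied with a small tolerance upstream) these
    are the primary processes born at the soma.  ``max_bar_length`` keeps
    bars of length ≤ the threshold (short terminal processes).  Both criteria
    compose by conjunction; at least one must be given.
    """
    if min_endpoint_max is None and max_bar_length is None:
        raise ValueError("at least one filter criterion is required")
    kept = []
    for bar in barcode.bars:
        if min_endpoint_max is not None and bar.min_endpoint > min_endpoint_max:
            continue
        if max_bar_length is not None and bar.length > max_bar_length:
            continue
        kept.append(bar)
    return PersistenceBarcode(tuple(kept), source_id=barcode.source_id)


def pixelwise_std_map(images: Sequence[PersistenceImage]) -> np.ndarray:
    """Per-pixel standard deviation across ≥ 2 images on one grid
    (population convention, divisor m)."""
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least 2 images for a variability map")
    for im in images[1:]:
        _check_same_grid(images[0], im)
    stack = np.stack([im.pixels for im in images])
    return stack.std(axis=0, ddof=0)


def representative_image(
    images: Sequence[PersistenceImage],
) -> tuple[int, PersistenceImage]:
    """The member closest (TMD distance) to the collection's pixel-wise
    mean; ties go to the smallest index.  Returns (index, image)."""
    images = list(images)
    if not images:
        raise ValueError("empty image collection")
    for im in images[1:]:
        _check_same_grid(images[0], im)
    mean = PersistenceImage(
        np.mean([im.pixels for im in images], axis=0), images[0].grid
    )
    dists = [tmd_distance(im, mean) for im in images]
    idx = int(np.argmin(dists))
    return idx, images[idx]
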