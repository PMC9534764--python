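"""Reference atlas: positioning novel conditions on a learned trajectory.

A reference atlas couples a large bootstrap sample spanning the known
conditions with its 2D trajectory coordinates.  Per axis, the coordinates
are min–max rescaled to (0, 1); the 500 most variable pixels across all
reference images are selected; and one linear regression per axis learns the
map from the highly-variable-pixel vector to the rescaled coordinate.  A
novel condition's bootstrapped images are then filtered to those pixels and
pushed through the regressors, giving per-image positions summarized as a
centroid with per-axis standard deviations.  Mapped positions are not
clipped to (0, 1): genuinely novel conditions may extend beyond the
reference spectrum.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapSample
from .tmd_core import ImageGrid

__all__ = ["ReferenceAtlas", "MappedCondition", "build_reference_atlas",
           "map_to_atlas"]

logger = logging.getLogger(__name__)

N_HV_PIXELS = 500
ATLAS_VERSION = 1


@dataclass(frozen=True)
class ReferenceAtlas:
    """Trajectory coordinates, highly variable pixels, per-axis regressors.

    ``regressors`` is a (2, |hv_pixels| + 1) array: row k holds the
    coefficients over hv_pixels followed by the intercept for axis k.
    ``scale_min``/``scale_max`` store the original coordinate bounds so the
    rescaling is reproducible (and novel points may land outside (0, 1)).
    """

    conditions: tuple[str, ...]
    labels: tuple[str, ...]
    coordinates: np.ndarray          # (m, 2), rescaled to (0, 1)
    hv_pixels: np.ndarray            # ordered pixel indices
    regressors: np.ndarray           # (2, n_hv + 1), intercept last
    grid: ImageGrid
    scale_min: np.ndarray
    scale_max: np.ndarray
    version: int = ATLAS_VERSION

    def condition_centroids(self) -> dict[str, np.ndarray]:
        out = {}
        for c in self.conditions:
            rows = [i for i, lab in enumerate(self.labels) if lab == c]
            out[c] = self.coordinates[rows].mean(axis=0)
        return out

    def condition_spreads(self) -> dict[str, np.ndarray]:
        out = {}
        for c in self.conditions:
            rows = [i for i, lab in enumerate(self.labels) if lab == c]
            out[c] = self.coordinates[rows].std(axis=0, ddof=0)
        return out

    # -- persistence -------------------------------------------------
    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "coordinates.tsv"), "w") as fh:
            fh.write("condition\tx\ty\n")
            for lab, (x, y) in zip(self.labels, self.coordinates):
                fh.write(f"{lab}\t{float(x)!r}\t{float(y)!r}\n")
        np.savetxt(os.path.join(out_dir, "hv_pixels.tsv"), self.hv_pixels,
                   fmt="%d")
        np.savetxt(os.path.join(out_dir, "regressors.tsv"), self.regressors)
        meta = {
            "version": self.version,
            "conditions": list(self.conditions),
            "grid": self.grid.to_dict(),
            "scale_min": self.scale_min.tolist(),
            "scale_max": self.scale_max.tolist(),
        }
        with open(os.path.join(out_dir, "atlas.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, out_dir: str) -> "ReferenceAtlas":
        with open(os.path.join(out_dir, "atlas.json")) as fh:
            meta = json.load(fh)
        labels, coords = [], []
        with open(os.path.join(out_dir, "coordinates.tsv")) as fh:
            next(fh)
            for line in fh:
                lab, x, y = line.rstrip("\n").split("\t")
                labels.append(lab)
                coords.append((float(x), float(y)))
        return cls(
            conditions=tuple(meta["conditions"]),
            labels=tuple(labels),
            coordinates=np.array(coords),
            hv_pixels=np.loadtxt(
                os.path.join(out_dir, "hv_pixels.tsv"), dtype=int, ndmin=1
            ),
            regressors=np.loadtxt(
                os.path.join(out_dir, "regressors.tsv"), ndmin=2
            ),
            grid=ImageGrid.from_dict(meta["grid"]),
            scale_min=np.array(meta["scale_min"]),
            scale_max=np.array(meta["scale_max"]),
            version=meta["version"],
        )


@dataclass(frozen=True)
class MappedCondition:
    """A novel condition positioned on the atlas."""

    condition: str
    positions: np.ndarray   # (m, 2)
    centroid: np.ndarray    # (2,)
    spread: np.ndarray      # (2,) per-axis SD

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "centroid": self.centroid.tolist(),
            "spread": self.spread.tolist(),
            "n_items": int(len(self.positions)),
        }


def _select_hv_pixels(X: np.ndarray, n_hv: int) -> np.ndarray:
    """Indices of the n_hv most variable pixels; ties favor lower indices."""
    var = X.var(axis=0, ddof=0)
    if len(var) < n_hv:
        logger.warning(
            "only %d pixels available, using all (requested %d)",
            len(var), n_hv,
        )
        n_hv = len(var)
    # stable sort on negated variance keeps lower indices first among ties
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:n_hv])


def build_reference_atlas(
    reference_sample: BootstrapSample,
    trajectory_coords: np.ndarray,
    n_hv_pixels: int = N_HV_PIXELS,
) -> ReferenceAtlas:
    """Learn the pixel→coordinate mapping from a reference bootstrap sample.

    Coordinates are min–max rescaled to (0, 1) per axis; the ``n_hv_pixels``
    highest-variance pixels across all reference images (pooled over
    conditions) form the design; one least-squares regression per axis (with
    intercept) maps the pixel vector to the rescaled coordinate.  A
    rank-deficient design resolves to the minimal-norm solution, with a
    logged warning.
    """
    if reference_sample.kind != "persistence_image":
        raise ValueError("reference sample must hold persistence images")
    coords = np.asarray(trajectory_coords, dtype=float)
    if coords.shape != (len(reference_sample), 2):
        raise ValueError("one 2D trajectory coordinate per reference item "
                         "is required")
    X = reference_sample.as_matrix()
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (coords - lo) / span

    hv = _select_hv_pixels(X, n_hv_pixels)
    design = np.column_stack([X[:, hv], np.ones(len(X))])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient regression design (rank %d < %d); "
            "using the minimal-norm least-squares solution",
            rank, design.shape[1],
        )
    coef, *_ = np.linalg.lstsq(design, scaled, rcond=None)
    return ReferenceAtlas(
        conditions=tuple(reference_sample.conditions()),
        labels=tuple(reference_sample.labels),
        coordinates=scaled,
        hv_pixels=hv,
        regressors=coef.T,  # (2, n_hv + 1)
        grid=reference_sample.grid,
        scale_min=lo,
        scale_max=hi,
    )


def map_to_atlas(
    atlas: ReferenceAtlas,
    novel_sample: BootstrapSample,
    condition: str | None = None,
) -> MappedCondition:
    """Infer atlas positions for a novel condition's bootstrapped images.

    Each image is reduced to the atlas's highly variable pixels and pushed
    through both axis regressors; the result is the set of positions, their
    centroid, and the per-axis standard deviation.  Images must live on the
    atlas grid — no silent resampling.
    """
    if len(novel_sample) == 0:
        raise ValueError("empty novel sample")
    if novel_sample.kind != "persistence_image":
        raise ValueError("novel sample must hold persistence images")
    if novel_sample.grid != atlas.grid:
        raise ValueError("novel images are not on the atlas grid")
    X = novel_sample.as_matrix()
    design = np.column_stack([X[:, atlas.hv_pixels], np.ones(len(X))])
    positions = design @ atlas.regressors.T
    if condition is None:
        conds = novel_sample.conditions()
        condition = conds[0] if len(conds) == 1 else "+".join(conds)
    return MappedCondition(
        condition=condition,
        positions=positions,
        centroid=positions.mean(axis=0),
        spread=positions.std(axis=0, ddof=0),
    )
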