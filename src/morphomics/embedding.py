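"""Dimensionality reduction and clustering of bootstrap samples.

The pipeline stage follows the distance-first route: pairwise TMD (L1)
distances between bootstrapped persistence images → singular value
decomposition of the (column-centered) distance matrix → the leading
principal-component scores → a 2D manifold embedding (UMAP with
n_neighbors = 50, min_dist = 1.0, spread = 3.0, or t-SNE with
perplexity = 50).  Absolute embedding positions carry no meaning; only
relative cluster structure does.  Average images per condition are compared
by average-linkage hierarchical clustering under the TMD distance.

Pseudo-temporal trajectories are delegated to external single-cell
machinery: 100 PCs of the images directly (not of the distance matrix), a
diffusion map (10 components, knn 20) and a force-directed layout of the
resulting neighbor graph.  This module owns input preparation, parameter
recording and coordinate collection only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import cdist, squareform

from .bootstrap import BootstrapSample
from .tmd_core import PersistenceImage, tmd_distance

__all__ = [
    "EmbeddingResult",
    "pairwise_distance_matrix",
    "pca_projection",
    "embed_2d",
    "hierarchical_clustering",
    "infer_trajectory",
]

#: manifold parameter defaults, recorded verbatim in outputs
UMAP_DEFAULTS = {"n_neighbors": 50, "min_dist": 1.0, "spread": 3.0}
TSNE_DEFAULTS = {"perplexity": 50.0}

#: the elbow of the singular values sits at 7 components; an alternative
#: 10-PC preset matches the schematic description of the same stage
N_PCS_PRESETS = {"methods7": 7, "figure10": 10}


@dataclass
class EmbeddingResult:
    """2D coordinates per bootstrap item plus the full provenance."""

    coordinates: np.ndarray  # (m, 2)
    method: str
    n_pcs: int
    params: dict
    seed: int
    labels: list[str]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_pcs": self.n_pcs,
            "params": self.params,
            "seed": self.seed,
        }


def pairwise_distance_matrix(sample: BootstrapSample) -> np.ndarray:
    """Symmetric matrix of TMD (L1) distances between all items."""
    if sample.kind == "persistence_image":
        grids = {im.grid for im in sample.items}
        if len(grids) > 1:
            raise ValueError("items are on different grids")
    X = sample.as_matrix()
    D = cdist(X, X, metric="cityblock")
    np.fill_diagonal(D, 0.0)
    return D


def pca_projection(
    distance_matrix: np.ndarray,
    n_pcs: int = N_PCS_PRESETS["methods7"],
    center: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Leading principal-component scores of the distance matrix via SVD.

    The matrix is column-centered by default (uncentered first components
    degenerate to row sums; switchable).  Scores are U·S for the first
    ``n_pcs`` components; the full singular-value spectrum is returned for
    elbow inspection.  Sign is fixed per component by making its
    largest-magnitude loading positive.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if n_pcs > min(D.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix dimension {D.shape[0]}")
    M = D - D.mean(axis=0, keepdims=True) if center else D
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    scores = U[:, :n_pcs] * S[:n_pcs]
    return scores, S


def embed_2d(
    scores: np.ndarray,
    method: str = "umap",
    params: dict | None = None,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    n_pcs: int | None = None,
) -> EmbeddingResult:
    """2D manifold embedding of PC scores by an established implementation.

    Coordinates are finite and reproducible per seed; their absolute
    positions carry no meaning.
    """
    scores = np.asarray(scores, dtype=float)
    m = len(scores)
    labels = list(labels) if labels is not None else [""] * m
    if len(labels) != m:
        raise ValueError("one label per item required")
    if method == "umap":
        p = {**UMAP_DEFAULTS, **(params or {})}
        if m <= p["n_neighbors"]:
            raise ValueError(
                f"{m} items cannot support n_neighbors={p['n_neighbors']}; "
                "lower n_neighbors or add bootstrap draws"
            )
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed, **p)
        coords = reducer.fit_transform(scores)
    elif method == "tsne":
        p = {**TSNE_DEFAULTS, **(params or {})}
        if m <= 3 * p["perplexity"]:
            raise ValueError(
                f"{m} items cannot support perplexity={p['perplexity']}; "
                "lower perplexity or add bootstrap draws"
            )
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2, random_state=seed, init="pca", **p
        ).fit_transform(scores)
    else:
        raise ValueError(f"unknown embedding method: {method!r}")
    return EmbeddingResult(
        np.asarray(coords, dtype=float), method,
        n_pcs if n_pcs is not None else scores.shape[1], p, seed, labels,
    )


def hierarchical_clustering(
    average_images: Mapping[str, PersistenceImage],
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomeration of condition-average images under the
    TMD distance.  Returns the scipy linkage matrix and the dendrogram leaf
    order as condition names."""
    names = list(average_images)
    if len(names) < 2:
        raise ValueError("need at least 2 conditions to cluster")
    imgs = [average_images[n] for n in names]
    m = len(imgs)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = tmd_distance(imgs[i], imgs[j])
    Z = linkage(squareform(D, checks=False), method="average")
    order = [names[i] for i in leaves_list(Z)]
    return Z, order


def infer_trajectory(
    sample: BootstrapSample,
    n_pca_components: int = 100,
    n_diffusion_components: int = 10,
    knn: int = 20,
    seed: int = 0,
    layout: str = "kamada_kawai",
) -> tuple[np.ndarray, dict]:
    """Pseudo-temporal trajectory coordinates for the bootstrap items.

    Pipeline contract: PCA of the images themselves (default 100
    components), diffusion maps on the PC projections (10 components,
    knn 20) via scanpy, then a spring layout of the diffusion-space kNN
    graph via python-igraph.  The default Kamada–Kawai stress layout keeps
    weakly connected condition clusters apart; ``layout="fruchterman_
    reingold"`` selects the classic force-directed alternative.  Returns the
    (m, 2) coordinates and the recorded parameters.

    Raises
    ------
    RuntimeError
        If the external implementations (scanpy, python-igraph) are not
        installed; the rest of the pipeline is usable without trajectories.
    """
    try:
        import anndata
        import igraph
        import scanpy as sc
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise RuntimeError(
            "trajectory inference needs the optional dependencies scanpy and "
            "python-igraph (pip install 'morphomics[trajectory]')"
        ) from exc

    X = sample.as_matrix()
    m = len(X)
    n_comp = int(min(n_pca_components, m - 1, X.shape[1]))
    from sklearn.decomposition import PCA

    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    adata = anndata.AnnData(X=pcs.astype(np.float32))
    adata.obsm["X_pca"] = pcs
    k = int(min(knn, m - 1))
    sc.pp.neighbors(adata, n_neighbors=k, use_rep="X_pca",
                    random_state=seed)
    n_dc = int(min(n_diffusion_components, m - 1))
    sc.tl.diffmap(adata, n_comps=n_dc)
    # canonical diffusion coordinates: eigenvectors scaled by eigenvalues,
    # steady-state component dropped (it is constant and carries no geometry)
    evals = np.asarray(adata.uns["diffmap_evals"])
    adata.obsm["X_diffmap_scaled"] = adata.obsm["X_diffmap"][:, 1:] * evals[1:]
    sc.pp.neighbors(adata, n_neighbors=k, use_rep="X_diffmap_scaled",
                    random_state=seed)
    conn = adata.obsp["connectivities"].tocoo()
    edges, weights, seen = [], [], set()
    for i, j, w in zip(conn.row, conn.col, conn.data):
        if i < j and (i, j) not in seen:
            seen.add((i, j))
            edges.append((int(i), int(j)))
            weights.append(float(w))
    g = igraph.Graph(n=m, edges=edges)
    import random as _random

    _random.seed(seed)
    if layout == "kamada_kawai":
        lay = g.layout_kamada_kawai()
    elif layout == "fruchterman_reingold":
        lay = g.layout_fruchterman_reingold(weights=weights, niter=500)
    else:
        raise ValueError(f"unknown layout: {layout!r}")
    coords = np.array(lay.coords, dtype=float)
    params = {
        "n_pca_components": n_comp,
        "n_diffusion_components": n_dc,
        "knn": k,
        "layout": layout,
        "seed": seed,
    }
    return coords, params
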