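"""End-to-end benchmark protocols on synthetic populations.

These are the package's own study conditions for validating the pipeline
without imaging data: bootstrap convergence toward the condition average,
recovery of condition separation by the embedding and by the stable-rank
SVM, a chance-level control with identical generating conditions, and the
reference-atlas round-trip.  Tests and the acceptance script both call
these functions; every protocol is fully determined by its master seed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np

from .atlas import build_reference_atlas, map_to_atlas
from .bootstrap import BootstrapSpec, bootstrap_persistence_images
from .embedding import embed_2d, infer_trajectory, pairwise_distance_matrix, pca_projection
from .stable_ranks import CVProtocol, bootstrapped_stable_ranks, pairwise_svm_accuracy
from .synthetic_trees import PRESETS, TreeModelParams, generate_population
from .tmd_core import (
    PersistenceBarcode,
    average_persistence_image,
    compute_persistence_barcode,
    make_shared_grid,
    tmd_distance,
)

__all__ = [
    "synthetic_barcodes",
    "bootstrap_convergence",
    "separation_silhouette",
    "svm_accuracy_benchmark",
    "atlas_roundtrip",
    "ATLAS_PRESETS",
]

#: four conditions spanning a branching-density spectrum at similar radial
#: extent — the synthetic stand-in for a multi-condition reference atlas
ATLAS_PRESETS: dict[str, TreeModelParams] = {
    "spectrum_1": TreeModelParams(n_stems=4, branch_prob=0.45, max_depth=4,
                                  segment_length_mean=11.0,
                                  segment_length_sd=1.5, radial_drift=0.7),
    "spectrum_2": TreeModelParams(n_stems=4, branch_prob=0.45, max_depth=5,
                                  segment_length_mean=8.5,
                                  segment_length_sd=1.5, radial_drift=0.7),
    "spectrum_3": TreeModelParams(n_stems=4, branch_prob=0.45, max_depth=6,
                                  segment_length_mean=6.5,
                                  segment_length_sd=1.5, radial_drift=0.7),
    "spectrum_4": TreeModelParams(n_stems=4, branch_prob=0.45, max_depth=7,
                                  segment_length_mean=5.5,
                                  segment_length_sd=1.5, radial_drift=0.7),
}


def synthetic_barcodes(
    params_by_condition: Mapping[str, TreeModelParams],
    n_per_condition: int,
    seed: int,
) -> dict[str, list[PersistenceBarcode]]:
    """Generate populations and compute their persistence barcodes.

    Per-condition seeds derive from the master seed and the condition's
    position, so the populations are reproducible as a set.
    """
    seq = np.random.SeedSequence(seed)
    kids = seq.generate_state(len(params_by_condition)) % (2**31)
    pops = generate_population(
        {
            name: replace(params, seed=int(s))
            for (name, params), s in zip(params_by_condition.items(), kids)
        },
        n_per_condition,
    )
    return {
        name: [compute_persistence_barcode(t) for t in trees]
        for name, trees in pops.items()
    }


def bootstrap_convergence(
    seed: int,
    n_cells: int = 40,
    sizes: Sequence[int] = (2, 5, 10, 20, 40),
    n_samples: int = 100,
) -> dict[int, float]:
    """Median TMD distance from bootstrapped to average image, per size.

    As the bootstrap size x grows toward the population size n the
    bootstrapped images converge to the condition average; at x = n every
    draw equals the average exactly.
    """
    barcodes = synthetic_barcodes({"pop": PRESETS["condition_A"]}, n_cells,
                                  seed)
    grid = make_shared_grid(barcodes["pop"], bandwidth=1.0)
    avg = average_persistence_image(barcodes["pop"], grid)
    medians: dict[int, float] = {}
    for x in sizes:
        spec = BootstrapSpec(bootstrap_size=x, n_samples=n_samples, seed=seed)
        sample = bootstrap_persistence_images(barcodes, spec, grid)
        medians[x] = float(
            np.median([tmd_distance(im, avg) for im in sample.items])
        )
    return medians


def separation_silhouette(
    seed: int,
    n_cells: int = 100,
    bootstrap_size: int = 30,
    n_samples: int = 200,
    n_pcs: int = 7,
    permute_labels: bool = False,
) -> float:
    """Silhouette of condition labels in the UMAP of two stock presets.

    Full pipeline: barcodes → shared grid → bootstrapped images → TMD
    distance matrix → PC scores → UMAP (n_neighbors 50, min_dist 1.0,
    spread 3.0).  ``permute_labels`` shuffles the condition labels before
    scoring — the leakage control; separation should then vanish.
    """
    from sklearn.metrics import silhouette_score

    barcodes = synthetic_barcodes(
        {k: PRESETS[k] for k in ("condition_A", "condition_B")},
        n_cells, seed,
    )
    grid = make_shared_grid(
        [bc for pop in barcodes.values() for bc in pop]
    )
    spec = BootstrapSpec(bootstrap_size=bootstrap_size, n_samples=n_samples,
                         seed=seed)
    sample = bootstrap_persistence_images(barcodes, spec, grid)
    D = pairwise_distance_matrix(sample)
    scores, _ = pca_projection(D, n_pcs=n_pcs)
    result = embed_2d(scores, method="umap", seed=seed % (2**31),
                      labels=sample.labels)
    labels = np.array(result.labels)
    if permute_labels:
        rng = np.random.default_rng(seed)
        labels = rng.permutation(labels)
    return float(silhouette_score(result.coordinates, labels))


def svm_accuracy_benchmark(
    seed: int,
    identical: bool = False,
    n_cells: int = 100,
    bootstrap_size: int = 50,
    n_samples: int = 200,
) -> tuple[float, np.ndarray]:
    """Stable-rank kernel SVM accuracy separating two synthetic conditions.

    200 bootstrapped standard stable ranks per class, 240/160 random
    train/test splits, 10 repeats, SVM with the precomputed stable-rank
    kernel at solver defaults.  ``identical=True`` assigns both class labels
    to bootstraps of one and the same population, so the labels are
    exchangeable — the chance-level control.  (Two *independent* populations
    of identical parameters would not be a null: bootstraps concentrate
    around each finite population's own mean, and the classifier would pick
    up that sampling difference.)
    """
    if identical:
        pop = synthetic_barcodes(
            {"shared": PRESETS["condition_A"]}, n_cells, seed
        )["shared"]
        barcodes = {"class_0": pop, "class_1": pop}
    else:
        barcodes = synthetic_barcodes(
            {
                "class_0": PRESETS["condition_A"],
                "class_1": PRESETS["condition_B"],
            },
            n_cells, seed,
        )
    spec = BootstrapSpec(bootstrap_size=bootstrap_size, n_samples=n_samples,
                         seed=seed)
    ranks = bootstrapped_stable_ranks(barcodes, spec)
    a = ranks.subset("class_0").items
    b = ranks.subset("class_1").items
    protocol = CVProtocol(n_train=240, n_test=160, n_repeats=10,
                          seed=seed % (2**31))
    return pairwise_svm_accuracy(a, b, protocol)


def atlas_roundtrip(
    seed: int,
    n_cells: int = 60,
    bootstrap_size: int = 20,
    n_samples: int = 500,
    n_novel: int = 100,
    resolution: int = 100,
) -> dict:
    """Build a synthetic 4-condition reference atlas and map fresh draws.

    Reference: ``n_samples`` bootstrapped images per condition, trajectory
    coordinates from the diffusion-map + force-layout stage, hv-pixel
    per-axis regression.  Query: ``n_novel`` fresh bootstrap draws per
    condition (new draw seed, same populations).  Returns per-condition
    centroid offsets in units of the reference spread and the fraction of
    query items whose nearest reference centroid is the true condition.
    """
    barcodes = synthetic_barcodes(ATLAS_PRESETS, n_cells, seed)
    grid = make_shared_grid(
        [bc for pop in barcodes.values() for bc in pop],
        resolution=resolution,
    )
    ref_spec = BootstrapSpec(bootstrap_size=bootstrap_size,
                             n_samples=n_samples, seed=seed)
    ref = bootstrap_persistence_images(barcodes, ref_spec, grid)
    coords, _ = infer_trajectory(ref, seed=seed % (2**31))
    atlas = build_reference_atlas(ref, coords)
    centroids = atlas.condition_centroids()
    spreads = atlas.condition_spreads()

    novel_spec = BootstrapSpec(bootstrap_size=bootstrap_size,
                               n_samples=n_novel, seed=seed + 1)
    centroid_offsets: dict[str, float] = {}
    n_correct = 0
    n_total = 0
    names = list(atlas.conditions)
    cent_arr = np.stack([centroids[c] for c in names])
    for condition in names:
        novel = bootstrap_persistence_images(
            {condition: barcodes[condition]}, novel_spec, grid
        )
        mapped = map_to_atlas(atlas, novel)
        # centroid offset in units of the reference per-axis SD
        offset = np.abs(mapped.centroid - centroids[condition])
        denom = np.maximum(spreads[condition], 1e-12)
        centroid_offsets[condition] = float(np.max(offset / denom))
        d = np.linalg.norm(
            mapped.positions[:, None, :] - cent_arr[None, :, :], axis=2
        )
        n_correct += int(
            (np.argmin(d, axis=1) == names.index(condition)).sum()
        )
        n_total += len(mapped.positions)
    return {
        "centroid_offsets_sd": centroid_offsets,
        "nearest_centroid_accuracy": n_correct / n_total,
    }
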