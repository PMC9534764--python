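import numpy as np
import pytest

from morphomics.swc_io import RootedTree, SwcNode
from morphomics.synthetic_trees import TreeModelParams, generate_tree
from morphomics.tmd_core import (
    ImageGrid,
    PersistenceBarcode,
    PersistenceDiagram,
    PersistenceImage,
    average_persistence_image,
    barcode_to_diagram,
    compute_persistence_barcode,
    diagram_to_persistence_image,
    filter_barcode,
    make_shared_grid,
    pixelwise_std_map,
    representative_image,
    subtract_images,
    tmd_distance,
)

from _oracles import random_rotation, union_find_barcode
from conftest import make_random_tree


def sorted_bars(bars):
    return sorted((float(o), float(m)) for o, m in bars)


class TestBarcode:
    def test_toy_y_bars(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        assert sorted_bars(bc.bars) == [(14.0, 10.0), (30.0, 0.0)]

    def test_pure_path_single_bar(self):
        nodes = [SwcNode(1, 1, 0, 0, 0, 1, -1)] + [
            SwcNode(i, 3, 5.0 * (i - 1), 0, 0, 1, i - 1) for i in range(2, 6)
        ]
        bc = compute_persistence_barcode(RootedTree(nodes))
        assert sorted_bars(bc.bars) == [(20.0, 0.0)]

    def test_single_node_empty_barcode_with_warning(self):
        t = RootedTree([SwcNode(1, 1, 0, 0, 0, 1, -1)])
        with pytest.warns(UserWarning):
            bc = compute_persistence_barcode(t)
        assert bc.n_bars == 0

    def test_multifurcation_kills_all_younger_children(self):
        # four stems of a star through one branch node at radial 5
        nodes = [SwcNode(1, 1, 0, 0, 0, 1, -1), SwcNode(2, 3, 5, 0, 0, 1, 1)]
        for k, r in enumerate((8.0, 9.0, 11.0), start=3):
            nodes.append(SwcNode(k, 3, r, 0, 0, 1, 2))
        bc = compute_persistence_barcode(RootedTree(nodes))
        assert sorted_bars(bc.bars) == [(8.0, 5.0), (9.0, 5.0), (11.0, 0.0)]

    def test_matches_union_find_oracle(self, random_trees):
        for t in random_trees:
            got = sorted_bars(compute_persistence_barcode(t).bars)
            want = sorted_bars(union_find_barcode(t))
            assert len(got) == len(t.leaves)
            assert np.allclose(got, want, atol=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        t = make_random_tree(3)
        base = sorted_bars(compute_persistence_barcode(t).bars)
        for _ in range(5):
            R = random_rotation(rng)
            shift = rng.uniform(-50, 50, size=3)
            moved = RootedTree(
                [
                    SwcNode(n.id, n.structure_label,
                            *(R @ n.xyz + shift), n.radius, n.parent_id)
                    for n in t.nodes
                ]
            )
            got = sorted_bars(compute_persistence_barcode(moved).bars)
            assert np.allclose(got, base, atol=1e-9)

    def test_monotone_growth_bar_length_identity(self):
        # with purely radial growth, origins are the leaf radial distances
        # and each branch point of k children absorbs k-1 merges
        t = generate_tree(TreeModelParams(n_stems=3, branch_prob=0.5,
                                          max_depth=6, radial_drift=1.0,
                                          seed=9))
        f = t.radial_distances()
        want = sum(f[l.id] for l in t.leaves) - sum(
            (len(t.children[n.id]) - 1) * f[n.id]
            for n in t.nodes
            if n.id != t.root.id and len(t.children[n.id]) >= 2
        )
        got = compute_persistence_barcode(t).lengths().sum()
        assert got == pytest.approx(want, rel=1e-9)


class TestDiagram:
    def test_toy_points(self, toy_y_tree):
        d = barcode_to_diagram(compute_persistence_barcode(toy_y_tree))
        assert sorted(map(tuple, d.points)) == [(14.0, 10.0), (30.0, 0.0)]

    def test_empty_barcode_empty_diagram(self):
        d = barcode_to_diagram(PersistenceBarcode(()))
        assert d.n_points == 0

    def test_point_count_equals_bar_count(self, random_trees):
        bc = compute_persistence_barcode(random_trees[0])
        assert barcode_to_diagram(bc).n_points == bc.n_bars


class TestSharedGrid:
    def test_bounds_from_max_endpoint(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        g = make_shared_grid([bc], padding=0.1)
        assert g.xlim == (0.0, pytest.approx(33.0))
        assert g.ylim == (0.0, pytest.approx(33.0))

    def test_largest_barcode_wins(self):
        a = PersistenceBarcode(tuple([(30.0, 0.0)]))
        b = PersistenceBarcode(tuple([(50.0, 10.0)]))
        g = make_shared_grid([a, b], padding=0.0)
        assert g.xlim[1] == pytest.approx(50.0)

    def test_all_empty_is_error(self):
        with pytest.raises(ValueError):
            make_shared_grid([PersistenceBarcode(())])


class TestPersistenceImage:
    def test_single_central_point_is_symmetric(self):
        g = ImageGrid((0, 10), (0, 10), resolution=21, bandwidth=1.0)
        im = diagram_to_persistence_image(PersistenceDiagram([[5.0, 5.0]]), g)
        assert np.argmax(im.pixels) == np.ravel_multi_index((10, 10), (21, 21))
        assert np.allclose(im.pixels, im.pixels[::-1, :], atol=1e-12)
        assert np.allclose(im.pixels, im.pixels[:, ::-1], atol=1e-12)
        assert im.pixels.sum() == pytest.approx(1.0)

    def test_empty_diagram_zero_image_flagged(self):
        g = ImageGrid((0, 10), (0, 10), resolution=5, bandwidth=1.0)
        im = diagram_to_persistence_image(PersistenceDiagram(np.empty((0, 2))), g)
        assert im.is_empty
        assert np.all(im.pixels == 0)

    def test_point_outside_bounds_rejected(self):
        g = ImageGrid((0, 10), (0, 10), resolution=5, bandwidth=1.0)
        with pytest.raises(ValueError, match="outside"):
            diagram_to_persistence_image(PersistenceDiagram([[11.0, 0.0]]), g)

    def test_two_symmetric_points_are_half_half_mixture(self):
        # mirror-placed points have equal truncated kernel mass, so the KDE
        # of both equals the equal-weight mixture of the single-point images
        g = ImageGrid((0, 10), (0, 10), resolution=20, bandwidth=1.5)
        p1, p2 = [3.0, 3.0], [7.0, 7.0]
        both = diagram_to_persistence_image(PersistenceDiagram([p1, p2]), g)
        one = diagram_to_persistence_image(PersistenceDiagram([p1]), g)
        two = diagram_to_persistence_image(PersistenceDiagram([p2]), g)
        assert np.allclose(both.pixels, 0.5 * (one.pixels + two.pixels),
                           atol=1e-9)


class TestAverageImage:
    def test_single_member_identity(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        g = make_shared_grid([bc], resolution=30)
        avg = average_persistence_image([bc], g)
        own = diagram_to_persistence_image(barcode_to_diagram(bc), g)
        assert np.allclose(avg.pixels, own.pixels)

    def test_identical_barcodes_equal_single(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        g = make_shared_grid([bc], resolution=30, bandwidth=1.0)
        avg = average_persistence_image([bc] * 5, g)
        own = diagram_to_persistence_image(barcode_to_diagram(bc), g)
        assert np.allclose(avg.pixels, own.pixels, atol=1e-12)

    def test_pixel_mean_variant(self, random_trees):
        bcs = [compute_persistence_barcode(t) for t in random_trees[:4]]
        g = make_shared_grid(bcs, resolution=30, bandwidth=2.0)
        pm = average_persistence_image(bcs, g, method="pixel_mean")
        explicit = np.mean(
            [diagram_to_persistence_image(barcode_to_diagram(b), g).pixels
             for b in bcs], axis=0)
        assert np.allclose(pm.pixels, explicit)


class TestImageArithmetic:
    @pytest.fixture
    def images(self, random_trees):
        bcs = [compute_persistence_barcode(t) for t in random_trees[:6]]
        g = make_shared_grid(bcs, resolution=25, bandwidth=2.0)
        return [diagram_to_persistence_image(barcode_to_diagram(b), g)
                for b in bcs]

    def test_self_subtraction_zero_and_conservation(self, images):
        a, b = images[0], images[1]
        assert np.all(subtract_images(a, a) == 0)
        assert subtract_images(a, b).sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(subtract_images(a, b), -subtract_images(b, a))

    def test_grid_mismatch_rejected(self, images):
        other = PersistenceImage(
            np.zeros((10, 10)), ImageGrid((0, 1), (0, 1), 10, 1.0))
        with pytest.raises(ValueError, match="grid"):
            subtract_images(images[0], other)

    def test_distance_metric_axioms(self, images):
        a, b = images[0], images[1]
        assert tmd_distance(a, a) == 0.0
        assert tmd_distance(a, b) == pytest.approx(tmd_distance(b, a))
        for i in range(len(images) - 2):
            x, y, z = images[i: i + 3]
            assert tmd_distance(x, z) <= (
                tmd_distance(x, y) + tmd_distance(y, z) + 1e-12)


class TestFilterBarcode:
    def test_primary_process_filter(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        kept = filter_barcode(bc, min_endpoint_max=0.0)
        assert sorted_bars(kept.bars) == [(30.0, 0.0)]

    def test_short_bar_filter(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        kept = filter_barcode(bc, max_bar_length=10.0)
        assert sorted_bars(kept.bars) == [(14.0, 10.0)]

    def test_conjunction_can_empty(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        kept = filter_barcode(bc, min_endpoint_max=0.0, max_bar_length=10.0)
        assert kept.n_bars == 0

    def test_no_criterion_is_error(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        with pytest.raises(ValueError):
            filter_barcode(bc)


class TestVariabilityAndRepresentative:
    def test_identical_images_zero_std(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        g = make_shared_grid([bc], resolution=20)
        im = diagram_to_persistence_image(barcode_to_diagram(bc), g)
        assert np.allclose(pixelwise_std_map([im, im, im]), 0.0, atol=1e-15)

    def test_two_image_closed_form(self, random_trees):
        bcs = [compute_persistence_barcode(t) for t in random_trees[:2]]
        g = make_shared_grid(bcs, resolution=20, bandwidth=2.0)
        a, b = [diagram_to_persistence_image(barcode_to_diagram(x), g)
                for x in bcs]
        # population SD of two values is half their absolute difference
        assert np.allclose(pixelwise_std_map([a, b]),
                           np.abs(a.pixels - b.pixels) / 2.0)

    def test_order_invariance(self, random_trees):
        bcs = [compute_persistence_barcode(t) for t in random_trees[:4]]
        g = make_shared_grid(bcs, resolution=20, bandwidth=2.0)
        ims = [diagram_to_persistence_image(barcode_to_diagram(x), g)
               for x in bcs]
        assert np.allclose(pixelwise_std_map(ims),
                           pixelwise_std_map(ims[::-1]))

    def test_representative_matches_brute_force(self, random_trees):
        bcs = [compute_persistence_barcode(t) for t in random_trees[:10]]
        g = make_shared_grid(bcs, resolution=20, bandwidth=2.0)
        ims = [diagram_to_persistence_image(barcode_to_diagram(x), g)
               for x in bcs]
        idx, rep = representative_image(ims)
        mean = PersistenceImage(np.mean([i.pixels for i in ims], axis=0), g)
        dists = [tmd_distance(i, mean) for i in ims]
        assert idx == int(np.argmin(dists))
        assert rep is ims[idx]

    def test_singleton_is_its_own_representative(self, toy_y_tree):
        bc = compute_persistence_barcode(toy_y_tree)
        g = make_shared_grid([bc], resolution=20)
        im = diagram_to_persistence_image(barcode_to_diagram(bc), g)
        idx, rep = representative_image([im])
        assert idx == 0 and rep is im
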