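import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

import saxskit as sk


@pytest.fixture(scope="module")
def blob():
    return sk.generate_shape(
        sk.ShapeSpec(kind="ellipsoid", n_beads=200, semi_axes=(30.0, 18.0, 12.0)), seed=1
    )


class TestAlignInertia:
    def test_recovers_known_rotation(self, blob):
        rot = Rotation.from_rotvec([0.4, 1.2, -0.3]).as_matrix()
        moved = blob.transformed(rotation=rot, translation=[25.0, -10.0, 5.0])
        aligned, mirrored = sk.align_inertia(moved, blob)
        assert not mirrored
        assert np.abs(aligned.coords - blob.coords).max() < 1e-6

    def test_recovers_mirror_and_flags_it(self, blob):
        mirrored_model = sk.enantiomer(blob)
        aligned, mirrored = sk.align_inertia(mirrored_model, blob, try_mirror=True)
        assert mirrored
        assert np.abs(aligned.coords - blob.coords).max() < 1e-6

    def test_preserves_pairwise_distances(self, blob):
        rot = Rotation.from_rotvec([0.1, -0.7, 0.9]).as_matrix()
        moved = blob.transformed(rotation=rot, translation=[3.0, 4.0, 5.0])
        aligned, _ = sk.align_inertia(moved, blob)
        assert np.allclose(pdist(aligned.coords), pdist(blob.coords), rtol=0, atol=1e-9)

    def test_degenerate_inertia_is_deterministic(self):
        sphere = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=150, radius=15.0), seed=2)
        other = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=150, radius=15.0), seed=3)
        a1, _ = sk.align_inertia(sphere, other)
        a2, _ = sk.align_inertia(sphere, other)
        assert np.array_equal(a1.coords, a2.coords)


class TestVoxelize:
    def test_single_bead(self):
        g = sk.voxelize(sk.BeadModel([[0.0, 0.0, 0.0]]))
        assert g.occupancy.sum() == 1
        assert (g.occupancy > 0).sum() == 1

    def test_count_conservation(self, blob):
        g = sk.voxelize(blob)
        assert g.occupancy.sum() == len(blob)

    def test_separated_beads_occupy_distinct_voxels(self):
        # beads > 4*sqrt(3) A apart can never share a 4 A box
        coords = np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0], [0.0, 9.0, 0.0],
                           [0.0, 0.0, 10.0], [12.0, 12.0, 12.0]])
        g = sk.voxelize(sk.BeadModel(coords))
        assert (g.occupancy > 0).sum() == 5
        assert g.occupancy.sum() == 5

    def test_boundary_bead_goes_to_higher_voxel(self):
        origin = np.zeros(3)
        g = sk.voxelize(sk.BeadModel([[4.0, 1.0, 1.0]]), 4.0, origin, (3, 3, 3))
        assert g.occupancy[1, 0, 0] == 1  # exactly on the x-edge: higher box

    def test_outside_fixed_grid_rejected(self):
        with pytest.raises(ValueError):
            sk.voxelize(sk.BeadModel([[100.0, 0.0, 0.0]]), 4.0, np.zeros(3), (3, 3, 3))

    def test_binary_mode(self):
        m = sk.BeadModel([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
        g = sk.voxelize(m, mode="binary")
        assert g.occupancy.max() == 1.0


class TestEmbedPca:
    @staticmethod
    def grids_for(models, spacing=4.0):
        origin, shape = sk.common_grid(models, spacing)
        return [sk.voxelize(m, spacing, origin, shape) for m in models]

    def test_identical_models_collapse_to_origin(self, blob):
        grids = self.grids_for([blob, blob, blob, blob])
        coords, evr, _ = sk.embed_pca(grids)
        assert np.allclose(coords, 0.0, atol=1e-9)
        assert np.all(evr <= 1.0)

    def test_two_distinct_shapes_split_on_pc1(self, blob):
        other = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=200, radius=18.0), seed=5)
        grids = self.grids_for([blob, blob, other, other])
        coords, evr, _ = sk.embed_pca(grids)
        assert evr[0] > 0.999  # all variance on PC1
        assert np.allclose(coords[0], coords[1], atol=1e-9)
        assert np.allclose(coords[2], coords[3], atol=1e-9)
        assert abs(coords[0, 0] - coords[2, 0]) > 1.0

    def test_requires_common_lattice(self, blob):
        g1 = sk.voxelize(blob)
        g2 = sk.voxelize(blob.transformed(translation=[50.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            sk.embed_pca([g1, g1, g2])


class TestClusterModels:
    def test_separated_clouds_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.5, (12, 2))
        b = rng.normal(0.0, 0.5, (12, 2)) + [30.0, 0.0]
        labels = sk.cluster_models(np.vstack([a, b]), k=2, seed=1)
        assert len(set(labels[:12])) == 1
        assert len(set(labels[12:])) == 1
        assert labels[0] != labels[12]

    def test_degenerate_identical_points(self):
        labels = sk.cluster_models(np.zeros((6, 2)), k="auto", seed=0)
        assert len(np.unique(labels)) == 1

    def test_k_exceeding_models_rejected(self):
        with pytest.raises(ValueError):
            sk.cluster_models(np.zeros((3, 2)), k=5)


class TestSelectAndAverage:
    def test_single_member_class_is_its_own_consensus(self, blob):
        s = np.linspace(0.002, 0.04, 40)
        i = sk.debye_intensity(blob, s)
        target = sk.ScatteringProfile(s, i, 0.01 * i)
        res = sk.select_and_average([blob], np.array([0]), target)
        ref = sk.voxelize(blob)
        assert len(res.class_averages) == 1
        assert len(res.class_averages[0]) == (ref.occupancy > 0).sum()
        assert res.selected_classes == (0,)

    def test_identical_members_consensus_matches(self, blob):
        s = np.linspace(0.002, 0.04, 40)
        i = sk.debye_intensity(blob, s)
        target = sk.ScatteringProfile(s, i, 0.01 * i)
        res = sk.select_and_average([blob, blob, blob], np.zeros(3, dtype=int), target)
        ref = sk.voxelize(blob)
        assert len(res.class_averages[0]) == (ref.occupancy > 0).sum()

    def test_only_fitting_family_selected(self, blob):
        """One family fits the target; the other is far off by construction."""
        s = np.linspace(0.002, 0.04, 40)
        i = sk.debye_intensity(blob, s)
        target = sk.ScatteringProfile(s, i, 0.01 * i)
        small = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=200, radius=10.0), seed=9)
        models = [blob, blob, small, small]
        labels = np.array([0, 0, 1, 1])
        res = sk.select_and_average(models, labels, target)
        assert res.selected_classes == (0,)
        assert res.class_mean_chi2[1] > 2.0 * res.class_mean_chi2[0]

    def test_empty_ensemble_rejected(self, blob):
        s = np.linspace(0.002, 0.04, 40)
        i = sk.debye_intensity(blob, s)
        target = sk.ScatteringProfile(s, i, 0.01 * i)
        with pytest.raises(ValueError):
            sk.select_and_average([], np.array([]), target)


def test_full_protocol_invariant_under_global_rigid_motion(blob):
    """Classifying a rigidly moved copy of every input gives the same labels."""
    other = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=200, radius=18.0), seed=5)
    s = np.linspace(0.002, 0.04, 40)
    i = sk.debye_intensity(blob, s)
    target = sk.ScatteringProfile(s, i, 0.01 * i)
    models = [blob, blob, other, other, blob]
    res0 = sk.classify_ensemble(models, target, k=2, seed=0)
    rot = Rotation.from_rotvec([0.3, 0.3, 1.4]).as_matrix()
    moved = [m.transformed(rotation=rot, translation=[40.0, 8.0, -12.0]) for m in models]
    res1 = sk.classify_ensemble(moved, target, k=2, seed=0)
    same = np.array_equal(res1.labels, res0.labels)
    flipped = np.array_equal(res1.labels, 1 - res0.labels)
    assert same or flipped
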