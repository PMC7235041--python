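"""Searchlight DM maps, intersubject convergence, thresholding, overlay."""

import warnings

import numpy as np
import pytest

import infonets as inf
from infonets.convergence import ConvergenceMap, RegionClass, SubjectDMMap
from infonets.exceptions import DataError, InsufficientGroupError, InvalidParameterError
from infonets.repgeom import n_pairs


def _subject_map(condensed_per_node, item_ids, group="expert", subject_id="s", missing=None):
    dms = np.asarray(condensed_per_node, dtype=float)
    miss = np.zeros(dms.shape[0], dtype=bool) if missing is None else np.asarray(missing)
    return SubjectDMMap(
        subject_id=subject_id, group=group, dms=dms, missing=miss,
        item_ids=tuple(item_ids), rings=1,
    )


class TestSearchlightDMMap:
    def test_matches_bruteforce_per_node(self, base_icosahedron):
        rng = np.random.default_rng(0)
        betas = rng.normal(size=(4, 12))
        m = inf.searchlight_dm_map(betas, base_icosahedron, rings=1)
        for node in range(12):
            nb = sorted(inf.node_neighborhood(base_icosahedron, node, 1).member_nodes)
            x = betas[:, nb]
            expected = 1 - np.corrcoef(x)[np.triu_indices(4, 1)]
            np.testing.assert_allclose(m.dms[node], expected, atol=1e-10)

    def test_rings_zero_flags_every_node_missing(self, base_icosahedron):
        betas = np.random.default_rng(1).normal(size=(4, 12))
        m = inf.searchlight_dm_map(betas, base_icosahedron, rings=0)
        assert m.missing.all()

    def test_identical_item_patterns_give_zero_dm(self, base_icosahedron):
        row = np.random.default_rng(2).normal(size=12)
        betas = np.tile(row, (3, 1))
        m = inf.searchlight_dm_map(betas, base_icosahedron, rings=1)
        np.testing.assert_allclose(m.dms[~m.missing], 0.0, atol=1e-10)

    def test_single_item_rejected(self, base_icosahedron):
        with pytest.raises(DataError):
            inf.searchlight_dm_map(np.ones((1, 12)), base_icosahedron, rings=1)


class TestIntersubjectConvergence:
    def test_identical_dms_reach_clipped_maximum(self):
        ids = ("a", "b", "c")
        c = np.array([[0.1, 0.5, 0.9], [0.2, 0.3, 0.4]])
        maps = [
            _subject_map(c, ids, subject_id=f"s{i}") for i in range(3)
        ]
        cmap = inf.intersubject_convergence(maps)
        expected = np.arctanh(1 - 1e-7)
        np.testing.assert_allclose(cmap.node_z, expected, atol=1e-9)

    def test_hand_computed_three_subjects(self):
        ids = ("a", "b", "c")
        vs = [np.array([[0.0, 1.0, 0.5]]), np.array([[0.2, 0.8, 0.1]]),
              np.array([[1.0, 0.1, 0.4]])]
        maps = [_subject_map(v, ids, subject_id=f"s{i}") for i, v in enumerate(vs)]
        cmap = inf.intersubject_convergence(maps)
        zs = []
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(vs[i][0], vs[j][0])[0, 1]
                zs.append(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)))
        assert cmap.node_z[0] == pytest.approx(np.mean(zs), abs=1e-12)
        assert cmap.n_pairs == 3

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(3)
        ids = tuple(range(5))
        maps = [
            _subject_map(rng.normal(size=(7, n_pairs(5))), ids, subject_id=f"s{i}")
            for i in range(4)
        ]
        z1 = inf.intersubject_convergence(maps).node_z
        z2 = inf.intersubject_convergence(maps[::-1]).node_z
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_missing_nodes_drop_pairs_nodewise(self):
        ids = ("a", "b", "c")
        base = np.array([[0.1, 0.5, 0.9]])
        m1 = _subject_map(base, ids, subject_id="s1")
        m2 = _subject_map(base, ids, subject_id="s2", missing=[True])
        m3 = _subject_map(base, ids, subject_id="s3")
        cmap = inf.intersubject_convergence([m1, m2, m3])
        # only the (s1, s3) pair is valid at the node
        assert np.isfinite(cmap.node_z[0])

    def test_single_subject_rejected(self):
        m = _subject_map(np.zeros((1, 3)), ("a", "b", "c"))
        with pytest.raises(InsufficientGroupError):
            inf.intersubject_convergence([m])


class TestNoiseThreshold:
    def test_negative_extent_magnitude(self):
        cmap = ConvergenceMap(group="expert", node_z=np.array([-0.05, -0.01, 0.3]), n_pairs=3)
        assert inf.estimate_noise_threshold(cmap) == pytest.approx(0.05)

    def test_example_from_two_hundredths(self):
        cmap = ConvergenceMap(group="expert", node_z=np.array([-0.02, 0.1]), n_pairs=3)
        assert inf.estimate_noise_threshold(cmap) == pytest.approx(0.02)

    def test_all_positive_map_degenerates_to_zero_with_warning(self):
        cmap = ConvergenceMap(group="expert", node_z=np.array([0.1, 0.2]), n_pairs=3)
        with pytest.warns(UserWarning):
            assert inf.estimate_noise_threshold(cmap) == 0.0

    def test_all_missing_map_rejected(self):
        cmap = ConvergenceMap(group="expert", node_z=np.array([np.nan]), n_pairs=3)
        with pytest.raises(DataError):
            inf.estimate_noise_threshold(cmap)


class TestPermutationNull:
    def _maps(self, seed=0, n_sub=4, n_nodes=12):
        rng = np.random.default_rng(seed)
        ids = tuple(range(5))
        return [
            _subject_map(rng.normal(size=(n_nodes, n_pairs(5))), ids, subject_id=f"s{i}")
            for i in range(n_sub)
        ]

    def test_fixed_seed_reproducible(self):
        maps = self._maps()
        a = inf.permutation_null(maps, 6, seed=9)
        b = inf.permutation_null(maps, 6, seed=9)
        assert np.array_equal(a.null_values, b.null_values)
        assert a.n_permutations == 6
        assert "item-label" in a.scheme

    def test_invalid_permutation_count(self):
        with pytest.raises(InvalidParameterError):
            inf.permutation_null(self._maps(), 0, seed=1)

    def test_null_brackets_negative_extent_on_pure_noise(self):
        # on pure noise the permuted max-z distribution should be of the
        # same magnitude as the observed |negative extent|
        maps = self._maps(seed=5, n_sub=6, n_nodes=40)
        observed = inf.intersubject_convergence(maps)
        thr = inf.estimate_noise_threshold(observed)
        null = inf.permutation_null(maps, 20, seed=2)
        q95 = np.quantile(null.null_values, 0.95)
        assert 0.2 * thr < q95 < 5.0 * thr


class TestOverlayAndCluster:
    def _cmap(self, z, group="g"):
        return ConvergenceMap(group=group, node_z=np.asarray(z, dtype=float), n_pairs=3)

    def test_basic_overlay_labels(self, base_icosahedron):
        z_a = np.full(12, -1.0); z_a[[1, 2]] = 1.0
        z_b = np.full(12, -1.0); z_b[[2, 3]] = 1.0
        labels = inf.overlay_and_cluster(
            self._cmap(z_a), self._cmap(z_b), 0.0, 1, base_icosahedron
        )
        assert set(labels.nodes_of(RegionClass.A_ONLY)) == {1}
        assert set(labels.nodes_of(RegionClass.OVERLAP)) == {2}
        assert set(labels.nodes_of(RegionClass.B_ONLY)) == {3}

    def test_minimum_cluster_size_five(self, small_mesh):
        # a 4-node connected component is removed, a 5-node one is kept
        comp4 = sorted(inf.node_neighborhood(small_mesh, 0, 1).member_nodes)[:4]
        comp5 = sorted(inf.node_neighborhood(small_mesh, 100, 1).member_nodes)[:5]
        # ensure contiguity of the chosen subsets
        assert len(inf.connected_components(comp4, small_mesh)) == 1
        assert len(inf.connected_components(comp5, small_mesh)) == 1
        z_a = np.full(small_mesh.n_nodes, -1.0)
        z_a[comp4] = 1.0
        z_a[comp5] = 1.0
        z_b = np.full(small_mesh.n_nodes, -1.0)
        labels = inf.overlay_and_cluster(
            self._cmap(z_a), self._cmap(z_b), 0.02, 5, small_mesh
        )
        assert set(labels.nodes_of(RegionClass.A_ONLY)) == set(comp5)

    def test_threshold_is_strict(self, base_icosahedron):
        z_a = np.full(12, -1.0); z_a[0] = 0.02
        z_b = np.full(12, -1.0)
        labels = inf.overlay_and_cluster(
            self._cmap(z_a), self._cmap(z_b), 0.02, 1, base_icosahedron
        )
        assert labels.node_label[0] == int(RegionClass.NONE)

    def test_every_node_gets_exactly_one_label(self, base_icosahedron):
        rng = np.random.default_rng(8)
        labels = inf.overlay_and_cluster(
            self._cmap(rng.normal(size=12)), self._cmap(rng.normal(size=12)),
            0.1, 1, base_icosahedron,
        )
        assert set(np.unique(labels.node_label)) <= {0, 1, 2, 3}

    def test_mismatched_meshes_rejected(self, base_icosahedron):
        with pytest.raises(DataError):
            inf.overlay_and_cluster(
                self._cmap(np.zeros(12)), self._cmap(np.zeros(13)), 0.0, 1, base_icosahedron
            )
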