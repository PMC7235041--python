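"""Informational-network clustering and split-half k selection."""

import numpy as np
import pytest

import infonets as inf
from infonets.convergence import RegionClass, RegionLabelMap, SubjectDMMap
from infonets.exceptions import EmptyRegionError, InsufficientGroupError, InvalidParameterError
from infonets.networks import (
    RegionNodeDMs,
    _adjusted_rand,
    define_networks,
    region_average_dms,
    select_k_split_half,
    ward_cluster,
)
from infonets.repgeom import n_pairs


def _label_map(n_nodes, region_nodes, cls=RegionClass.A_ONLY):
    labels = np.zeros(n_nodes, dtype=np.int64)
    labels[list(region_nodes)] = int(cls)
    return RegionLabelMap(node_label=labels, threshold_used=0.02, min_cluster_size=1)


def _subject_maps(prototype_per_node, n_subjects, noise, seed, group="expert"):
    """Subject DM maps = shared per-node prototypes + independent noise."""
    rng = np.random.default_rng(seed)
    proto = np.asarray(prototype_per_node, dtype=float)
    n_nodes, P = proto.shape
    n_items = int((1 + np.sqrt(1 + 8 * P)) / 2)
    ids = tuple(range(n_items))
    out = []
    for s in range(n_subjects):
        dms = proto + rng.normal(scale=noise, size=proto.shape)
        out.append(
            SubjectDMMap(
                subject_id=f"s{s}", group=group, dms=dms,
                missing=np.zeros(n_nodes, dtype=bool), item_ids=ids, rings=1,
            )
        )
    return out


def _blocks_prototype(rng, n_blocks=3, nodes_per_block=10, n_items=8):
    """Equidistant (orthogonal, equal-norm) block prototypes: the merge into
    fewer than n_blocks clusters is then noise-determined and irreproducible,
    so split-half stability peaks at the planted count."""
    P = n_pairs(n_items)
    q, _ = np.linalg.qr(rng.normal(size=(P, n_blocks)))
    protos = q.T * np.sqrt(P)
    per_node = np.repeat(protos, nodes_per_block, axis=0)
    truth = np.repeat(np.arange(n_blocks), nodes_per_block)
    return per_node, truth


class TestRegionAverageDMs:
    def test_identical_subjects_average_to_themselves(self):
        proto = np.random.default_rng(0).normal(size=(6, 10))
        maps = _subject_maps(proto, 4, noise=0.0, seed=1)
        labels = _label_map(6, range(6))
        region = region_average_dms(maps, labels, RegionClass.A_ONLY)
        np.testing.assert_allclose(region.node_avg_dms, proto, atol=1e-12)

    def test_matches_entrywise_mean_oracle(self):
        rng = np.random.default_rng(2)
        maps = _subject_maps(rng.normal(size=(8, 6)), 5, noise=1.0, seed=3)
        labels = _label_map(8, range(2, 8))
        region = region_average_dms(maps, labels, RegionClass.A_ONLY)
        expected = np.mean([m.dms[2:8] for m in maps], axis=0)
        np.testing.assert_allclose(region.node_avg_dms, expected, atol=1e-12)

    def test_opposite_dms_flag_degenerate_nodes(self):
        v = np.array([[0.1, 0.5, 0.9]])
        m1 = _subject_maps(v, 1, 0.0, 0)[0]
        m2 = _subject_maps(1.0 - v, 1, 0.0, 0)[0]
        labels = _label_map(1, [0])
        region = region_average_dms([m1, m2], labels, RegionClass.A_ONLY)
        assert region.degenerate[0]

    def test_empty_region_rejected(self):
        maps = _subject_maps(np.zeros((4, 3)), 2, 1.0, 0)
        labels = _label_map(4, [])
        with pytest.raises(EmptyRegionError):
            region_average_dms(maps, labels, RegionClass.A_ONLY)


class TestWardCluster:
    def _region(self, per_node):
        n = per_node.shape[0]
        return RegionNodeDMs(
            region_class=RegionClass.A_ONLY, group="expert",
            nodes=np.arange(n), node_avg_dms=per_node,
            degenerate=np.zeros(n, dtype=bool), item_ids=tuple(range(8)),
        )

    def test_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(4)
        per_node, truth = _blocks_prototype(rng, n_blocks=2, nodes_per_block=12)
        per_node = per_node + rng.normal(scale=0.05, size=per_node.shape)
        sol = ward_cluster(self._region(per_node), 2)
        assert _adjusted_rand(sol.node_assignment, truth) == pytest.approx(1.0)

    def test_k_equal_node_count_gives_singletons(self):
        per_node = np.random.default_rng(5).normal(size=(7, 10))
        sol = ward_cluster(self._region(per_node), 7)
        assert len(np.unique(sol.node_assignment)) == 7

    def test_deterministic(self):
        per_node = np.random.default_rng(6).normal(size=(15, 10))
        a = ward_cluster(self._region(per_node), 4)
        b = ward_cluster(self._region(per_node), 4)
        assert np.array_equal(a.node_assignment, b.node_assignment)

    def test_k_out_of_range_rejected(self):
        per_node = np.random.default_rng(7).normal(size=(5, 10))
        for bad in (1, 6):
            with pytest.raises(InvalidParameterError):
                ward_cluster(self._region(per_node), bad)


class TestAdjustedRand:
    def test_matches_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        for _ in range(50):
            a = rng.integers(0, 5, size=40)
            b = rng.integers(0, 4, size=40)
            assert _adjusted_rand(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestSelectKSplitHalf:
    def test_single_candidate_returns_it(self):
        rng = np.random.default_rng(9)
        per_node, _ = _blocks_prototype(rng, n_blocks=2, nodes_per_block=5)
        maps = _subject_maps(per_node, 6, noise=0.5, seed=10)
        labels = _label_map(10, range(10))
        trace = select_k_split_half(maps, labels, RegionClass.A_ONLY, (2, 2), 5, seed=0)
        assert trace.k_star == 2
        assert set(trace.reproducibility_by_k) == {2}

    def test_recovers_planted_three_prototypes(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            per_node, _ = _blocks_prototype(rng, n_blocks=3, nodes_per_block=10)
            maps = _subject_maps(per_node, 8, noise=0.8, seed=200 + seed)
            labels = _label_map(30, range(30))
            trace = select_k_split_half(
                maps, labels, RegionClass.A_ONLY, (2, 8), 30, seed=seed
            )
            hits += trace.k_star == 3
        assert hits >= 4

    def test_k_range_truncated_to_region_size(self):
        rng = np.random.default_rng(11)
        per_node, _ = _blocks_prototype(rng, n_blocks=2, nodes_per_block=3)
        maps = _subject_maps(per_node, 4, noise=0.5, seed=12)
        labels = _label_map(6, range(6))
        with pytest.warns(UserWarning):
            trace = select_k_split_half(
                maps, labels, RegionClass.A_ONLY, (2, 100), 5, seed=0
            )
        assert trace.k_range == (2, 6)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(13)
        per_node, _ = _blocks_prototype(rng, n_blocks=2, nodes_per_block=6)
        maps = _subject_maps(per_node, 6, noise=1.0, seed=14)
        labels = _label_map(12, range(12))
        t1 = select_k_split_half(maps, labels, RegionClass.A_ONLY, (2, 6), 10, seed=3)
        t2 = select_k_split_half(maps, labels, RegionClass.A_ONLY, (2, 6), 10, seed=3)
        assert t1.reproducibility_by_k == t2.reproducibility_by_k
        assert t1.k_star == t2.k_star

    def test_too_few_subjects_rejected(self):
        maps = _subject_maps(np.zeros((4, 6)), 3, 1.0, 0)
        labels = _label_map(4, range(4))
        with pytest.raises(InsufficientGroupError):
            select_k_split_half(maps, labels, RegionClass.A_ONLY, (2, 3), 5, seed=0)


class TestDefineNetworks:
    def test_networks_partition_region_and_order_by_size(self):
        rng = np.random.default_rng(15)
        per_node, truth = _blocks_prototype(rng, n_blocks=3, nodes_per_block=8)
        region = RegionNodeDMs(
            region_class=RegionClass.B_ONLY, group="novice",
            nodes=np.arange(24) + 100, node_avg_dms=per_node,
            degenerate=np.zeros(24, dtype=bool), item_ids=tuple(range(8)),
        )
        sol = ward_cluster(region, 3)
        nets = define_networks(sol, region)
        assert len(nets) == 3
        all_nodes = np.sort(np.concatenate([n.nodes for n in nets]))
        assert np.array_equal(all_nodes, region.nodes)
        sizes = [n.size for n in nets]
        assert sizes == sorted(sizes, reverse=True)
        assert [n.network_id for n in nets] == [
            f"novice-B_ONLY-net{i:02d}" for i in (1, 2, 3)
        ]
        # membership reproduces the cluster assignment exactly
        for net in nets:
            cluster_ids = {sol.node_assignment[list(region.nodes).index(v)] for v in net.nodes}
            assert len(cluster_ids) == 1
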