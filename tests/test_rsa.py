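"""Model DMs and network-level RSA statistics."""

import warnings

import numpy as np
import pytest

import infonets as inf
from infonets.convergence import RegionClass, SubjectDMMap
from infonets.exceptions import DataError, DegenerateSampleError
from infonets.networks import InformationalNetwork
from infonets.repgeom import ItemDM, n_pairs
from infonets.rsa import (
    CategoryLabels,
    build_network_dm_table,
    category_model_dm,
    find_peak_network,
    gradient_map,
    network_average_dm,
    network_rsa,
)


def _net(nodes, nid="expert-A_ONLY-net01", group="expert"):
    return InformationalNetwork(
        network_id=nid, group=group, region_class=RegionClass.A_ONLY,
        nodes=np.asarray(nodes, dtype=np.int64),
    )


def _map(dms, ids, subject_id="s0", missing=None):
    dms = np.asarray(dms, dtype=float)
    miss = np.zeros(len(dms), dtype=bool) if missing is None else np.asarray(missing)
    return SubjectDMMap(
        subject_id=subject_id, group="expert", dms=dms, missing=miss,
        item_ids=tuple(ids), rings=1,
    )


class TestCategoryModelDM:
    def test_three_item_example(self):
        labels = CategoryLabels(item_ids=("x", "y", "z"), categories=("a", "a", "b"))
        dm = category_model_dm(labels)
        assert np.array_equal(dm.dm.condensed, [0.0, 1.0, 1.0])

    def test_balanced_24_item_pair_counts(self):
        labels = CategoryLabels(
            item_ids=tuple(range(24)),
            categories=tuple(["cantilever"] * 8 + ["truss"] * 8 + ["vertical_load"] * 8),
        )
        c = category_model_dm(labels).dm.condensed
        assert len(c) == 276
        assert int((c == 0).sum()) == 84   # 3 * C(8,2)
        assert int((c == 1).sum()) == 192

    def test_relabeling_equivariance(self):
        ids = tuple("abcdef")
        cats = ("u", "v", "u", "w", "v", "w")
        dm = category_model_dm(CategoryLabels(ids, cats)).dm.to_square()
        perm = [3, 0, 5, 1, 4, 2]
        dm_p = category_model_dm(
            CategoryLabels(tuple(ids[i] for i in perm), tuple(cats[i] for i in perm))
        ).dm.to_square()
        assert np.array_equal(dm[np.ix_(perm, perm)], dm_p)

    def test_single_category_rejected(self):
        with pytest.raises(DataError):
            CategoryLabels(item_ids=("x", "y"), categories=("a", "a"))


class TestNetworkAverageDM:
    def test_single_node_network_returns_that_dm(self):
        ids = ("a", "b", "c")
        m = _map([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]], ids)
        out = network_average_dm(m, _net([1]))
        np.testing.assert_allclose(out.condensed, [0.4, 0.5, 0.6])

    def test_two_node_mean(self):
        ids = ("a", "b", "c")
        m = _map([[0.0, 0.2, 0.4], [0.4, 0.6, 0.8]], ids)
        out = network_average_dm(m, _net([0, 1]))
        np.testing.assert_allclose(out.condensed, [0.2, 0.4, 0.6])

    def test_ten_node_mean_oracle_and_missing_skip(self):
        rng = np.random.default_rng(1)
        ids = tuple(range(5))
        dms = rng.normal(size=(10, n_pairs(5)))
        missing = np.zeros(10, dtype=bool)
        missing[[2, 7]] = True
        m = _map(dms, ids, missing=missing)
        out = network_average_dm(m, _net(list(range(10))))
        np.testing.assert_allclose(
            out.condensed, dms[~missing].mean(axis=0), atol=1e-12
        )

    def test_subject_missing_all_nodes_rejected(self):
        m = _map([[0.1, 0.2, 0.3]], ("a", "b", "c"), missing=[True])
        with pytest.raises(DataError):
            network_average_dm(m, _net([0]))


class TestNetworkRSA:
    def _table_from_dms(self, per_subject_dms, ids, nodes=(0,)):
        maps = [
            _map(d[None, :].repeat(len(nodes), axis=0), ids, subject_id=f"s{i}")
            for i, d in enumerate(per_subject_dms)
        ]
        net = _net(list(nodes))
        return build_network_dm_table(maps, [net]), maps

    def test_model_plus_noise_recovers_positive_mean(self):
        rng = np.random.default_rng(2)
        labels = CategoryLabels(tuple(range(9)), tuple([0, 1, 2] * 3))
        model = category_model_dm(labels)
        dms = [model.dm.condensed + rng.normal(scale=0.3, size=36) for _ in range(12)]
        table, _ = self._table_from_dms(dms, labels.item_ids)
        stats = network_rsa(table, model)
        assert len(stats) == 1
        assert stats[0].mean_z > 0.5
        assert stats[0].p < 1e-4
        assert stats[0].df == 11

    def test_identical_dms_surface_degenerate_sample(self):
        labels = CategoryLabels(tuple(range(6)), tuple([0, 1] * 3))
        model = category_model_dm(labels)
        dms = [model.dm.condensed.copy() for _ in range(4)]
        table, _ = self._table_from_dms(dms, labels.item_ids)
        with pytest.raises(DegenerateSampleError):
            network_rsa(table, model)

    def test_null_dms_give_near_zero_mean(self):
        rng = np.random.default_rng(3)
        labels = CategoryLabels(tuple(range(9)), tuple([0, 1, 2] * 3))
        model = category_model_dm(labels)
        tvals = []
        for _ in range(60):
            dms = [rng.normal(size=36) for _ in range(10)]
            table, _ = self._table_from_dms(dms, labels.item_ids)
            tvals.append(network_rsa(table, model)[0].statistic)
        # t values centred on zero under the null
        assert abs(np.mean(tvals)) < 0.5

    def test_fdr_flag_adds_adjusted_p(self):
        rng = np.random.default_rng(4)
        labels = CategoryLabels(tuple(range(6)), tuple([0, 1] * 3))
        model = category_model_dm(labels)
        maps = [
            _map(rng.normal(size=(4, 15)), labels.item_ids, subject_id=f"s{i}")
            for i in range(5)
        ]
        nets = [_net([0, 1], "g-n1"), _net([2, 3], "g-n2")]
        table = build_network_dm_table(maps, nets)
        stats = network_rsa(table, model, fdr=True)
        assert all(s.q is not None and s.q >= s.p - 1e-12 for s in stats)


class TestGradientAndPeak:
    def _stats(self, tvals, sizes=None):
        from infonets.rsa import ModelKind, RSAStat

        sizes = sizes or [10] * len(tvals)
        return [
            RSAStat(
                network_id=f"net{i:02d}", model_kind=ModelKind.MECHANICAL_CATEGORY,
                z_values=np.zeros(3), statistic=t, df=2, p=0.5, mean_z=0.0,
                n_nodes=s,
            )
            for i, (t, s) in enumerate(zip(tvals, sizes))
        ]

    def test_gradient_is_constant_within_networks(self, base_icosahedron):
        nets = [_net([0, 1, 2], "net00"), _net([5, 6], "net01")]
        stats = self._stats([1.0, 3.0])
        grad = gradient_map(stats, nets, base_icosahedron)
        assert np.all(grad[[0, 1, 2]] == 1.0)
        assert np.all(grad[[5, 6]] == 3.0)
        assert np.isnan(grad[4])

    def test_gradient_matches_membership_lookup_randomly(self, base_icosahedron):
        rng = np.random.default_rng(5)
        perm = rng.permutation(12)
        nets = [_net(perm[:4], "net00"), _net(perm[4:9], "net01"), _net(perm[9:], "net02")]
        tvals = [2.0, -1.0, 0.5]
        grad = gradient_map(self._stats(tvals), nets, base_icosahedron)
        for t, net in zip(tvals, nets):
            assert np.all(grad[net.nodes] == t)

    def test_peak_selection_and_tie_breaks(self):
        stats = self._stats([1.2, 2.27, 0.3])
        assert find_peak_network(stats).network_id == "net01"
        tied = self._stats([1.0, 1.0], sizes=[5, 9])
        assert find_peak_network(tied).network_id == "net01"  # larger network wins
        tied_same = self._stats([1.0, 1.0], sizes=[5, 5])
        assert find_peak_network(tied_same).network_id == "net00"

    def test_peak_matches_bruteforce_max(self):
        rng = np.random.default_rng(6)
        tvals = rng.normal(size=100)
        stats = self._stats(list(tvals))
        assert find_peak_network(stats).statistic == pytest.approx(tvals.max())
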