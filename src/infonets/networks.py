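"""Informational-network definition by split-half cross-validated Ward clustering.

Within each region class of the overlay map, the group-average node-level
DMs are clustered with Ward linkage on their normalized condensed vectors.
The number of clusters is selected by repeated split-half cross-validation:
subjects are split into halves, each half's node-average DMs are clustered
at every candidate k, and the adjusted Rand index between the two halves'
node assignments scores reproducibility.  The k maximizing mean
reproducibility (smallest k on ties) is refit on all subjects, and the
resulting clusters are the group's informational networks for that region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.special import comb

from .convergence import RegionClass, SubjectDMMap
from .exceptions import (
    DataError,
    EmptyRegionError,
    InsufficientGroupError,
    InvalidParameterError,
)
from .repgeom import ItemDM

__all__ = [
    "RegionNodeDMs",
    "ClusterSolution",
    "KSelectionTrace",
    "InformationalNetwork",
    "region_average_dms",
    "ward_cluster",
    "select_k_split_half",
    "define_networks",
]


@dataclass
class RegionNodeDMs:
    """Group-average condensed DM per node of one region class."""

    region_class: RegionClass
    group: str
    nodes: np.ndarray            # global node indices, sorted
    node_avg_dms: np.ndarray     # (n_region_nodes, n_item_pairs)
    degenerate: np.ndarray       # constant-average-DM flag per node
    item_ids: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class ClusterSolution:
    k: int
    node_assignment: np.ndarray  # cluster id (1..k) per region node
    linkage: str = "ward"


@dataclass
class KSelectionTrace:
    k_range: tuple[int, int]
    n_repetitions: int
    seed: int
    reproducibility_by_k: dict[int, float]
    k_star: int


@dataclass
class InformationalNetwork:
    """A data-driven set of nodes with shared representational content."""

    network_id: str
    group: str
    region_class: RegionClass
    nodes: np.ndarray

    @property
    def size(self) -> int:
        return len(self.nodes)


def _average_over_subjects(
    dm_maps: list[SubjectDMMap], nodes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Entrywise mean of subjects' condensed DMs at ``nodes``, skipping
    subjects flagged missing at a node."""
    stack = np.stack([m.dms[nodes] for m in dm_maps])        # (S, R, P)
    ok = ~np.stack([m.missing[nodes] for m in dm_maps])      # (S, R)
    w = ok.astype(np.float64)
    cnt = w.sum(axis=0)                                      # (R,)
    if np.any(cnt == 0):
        raise DataError("some region nodes are missing for every subject")
    num = np.einsum("srp,sr->rp", np.nan_to_num(stack), w)
    avg = num / cnt[:, None]
    degenerate = avg.std(axis=1) == 0.0
    return avg, degenerate


def region_average_dms(
    dm_maps: list[SubjectDMMap],
    labels,
    region_class: RegionClass,
) -> RegionNodeDMs:
    """Per-node entrywise mean of the group's condensed DMs over one region.

    ``labels`` is the cluster-corrected :class:`RegionLabelMap`; nodes of
    ``region_class`` define the region.
    """
    if len(dm_maps) < 1:
        raise InsufficientGroupError("need at least one subject map")
    nodes = labels.nodes_of(region_class)
    if len(nodes) == 0:
        raise EmptyRegionError(f"region class {region_class.name} has no nodes")
    avg, degenerate = _average_over_subjects(dm_maps, nodes)
    return RegionNodeDMs(
        region_class=region_class,
        group=dm_maps[0].group,
        nodes=nodes,
        node_avg_dms=avg,
        degenerate=degenerate,
        item_ids=dm_maps[0].item_ids,
    )


def _node_features(node_avg_dms: np.ndarray) -> np.ndarray:
    """Mean-center and unit-norm each node's condensed DM (Ward features)."""
    c = node_avg_dms - node_avg_dms.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    norms[norms == 0.0] = 1.0  # degenerate nodes sit at the origin
    return c / norms[:, None]


def _ward_assign(features: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(features, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels


def _adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index via the pair-counting contingency table."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    n = len(a)
    sum_ij = comb(cont, 2).sum()
    sum_a = comb(cont.sum(axis=1), 2).sum()
    sum_b = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def ward_cluster(region: RegionNodeDMs, k: int) -> ClusterSolution:
    """Agglomerative Ward clustering of region nodes at a fixed k."""
    n = region.n_nodes
    if not (2 <= k <= n):
        raise InvalidParameterError(f"k must be in [2, {n}], got {k}")
    labels = _ward_assign(_node_features(region.node_avg_dms), k)
    return ClusterSolution(k=int(k), node_assignment=labels)


def select_k_split_half(
    dm_maps: list[SubjectDMMap],
    labels,
    region_class: RegionClass,
    k_range: tuple[int, int] = (2, 100),
    n_repetitions: int = 1000,
    seed: int = 0,
) -> KSelectionTrace:
    """Split-half cross-validated selection of the cluster count.

    Per repetition, subjects are randomly split into halves; each half's
    node-average DMs are Ward-clustered (one linkage per half, cut at every
    candidate k) and reproducibility(k) is the adjusted Rand index between
    the halves' assignments.  ``k_star`` maximizes the mean reproducibility,
    smallest k on ties.
    """
    if len(dm_maps) < 4:
        raise InsufficientGroupError("split-half selection needs at least 4 subjects")
    if n_repetitions < 1:
        raise InvalidParameterError("n_repetitions must be >= 1")
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2 or k_hi < k_lo:
        raise InvalidParameterError(f"invalid k_range {k_range}")
    nodes = labels.nodes_of(region_class)
    if len(nodes) == 0:
        raise EmptyRegionError(f"region class {region_class.name} has no nodes")
    if k_hi > len(nodes):
        warnings.warn(
            f"k_range upper bound {k_hi} exceeds region size {len(nodes)}; truncating",
            stacklevel=2,
        )
        k_hi = len(nodes)
        if k_lo > k_hi:
            raise InvalidParameterError("region too small for any candidate k")
    ks = np.arange(k_lo, k_hi + 1)

    rng = np.random.default_rng(seed)
    S = len(dm_maps)
    scores = np.zeros(len(ks))
    for _ in range(n_repetitions):
        order = rng.permutation(S)
        half_a = [dm_maps[i] for i in order[: S // 2]]
        half_b = [dm_maps[i] for i in order[S // 2:]]
        feats = []
        for half in (half_a, half_b):
            avg, _ = _average_over_subjects(half, nodes)
            feats.append(_node_features(avg))
        Za = linkage(feats[0], method="ward")
        Zb = linkage(feats[1], method="ward")
        cuts_a = cut_tree(Za, n_clusters=ks)   # (n_nodes, len(ks))
        cuts_b = cut_tree(Zb, n_clusters=ks)
        for i in range(len(ks)):
            scores[i] += _adjusted_rand(cuts_a[:, i], cuts_b[:, i])
    scores /= n_repetitions
    k_star = int(ks[int(np.argmax(scores))])  # argmax returns first max: smallest k on ties
    return KSelectionTrace(
        k_range=(k_lo, k_hi),
        n_repetitions=int(n_repetitions),
        seed=int(seed),
        reproducibility_by_k={int(k): float(s) for k, s in zip(ks, scores)},
        k_star=k_star,
    )


def define_networks(
    solution: ClusterSolution,
    region: RegionNodeDMs,
) -> list[InformationalNetwork]:
    """One informational network per cluster, ids ordered by decreasing size
    (ties: smallest member node)."""
    nets = []
    for cid in np.unique(solution.node_assignment):
        members = region.nodes[solution.node_assignment == cid]
        nets.append(members)
    nets.sort(key=lambda m: (-len(m), int(m.min())))
    prefix = f"{region.group}-{region.region_class.name}"
    return [
        InformationalNetwork(
            network_id=f"{prefix}-net{i + 1:02d}",
            group=region.group,
            region_class=region.region_class,
            nodes=members,
        )
        for i, members in enumerate(nets)
    ]
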