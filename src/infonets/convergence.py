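"""Subject DM surface maps and within-group intersubject convergence.

Stage 1 computes, for every surface node, an item dissimilarity matrix from
the pattern estimates inside the node's searchlight patch.  Stage 2
correlates those DMs across every pair of subjects within a group, Fisher
z-transforms each pairwise correlation, and averages per node — the
convergence map.  Thresholding is data-driven: the magnitude of the map's
negative extent estimates the range of correlation attributable to noise,
and nodes must exceed that threshold strictly.  Group maps are overlaid into
group-distinct and overlapping region classes, and components smaller than a
minimum contiguous node count are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from itertools import combinations

import numpy as np

from .exceptions import (
    DataError,
    IncompatibleMeshError,
    InsufficientGroupError,
    InvalidParameterError,
)
from .mesh import connected_components
from .repgeom import DEFAULT_CLIP_EPS, ItemDM, n_pairs

__all__ = [
    "RegionClass",
    "SubjectDMMap",
    "ConvergenceMap",
    "RegionLabelMap",
    "PermutationNull",
    "searchlight_dm_map",
    "intersubject_convergence",
    "estimate_noise_threshold",
    "permutation_null",
    "overlay_and_cluster",
]


class RegionClass(IntEnum):
    """Per-node overlay label after thresholding both group maps."""

    NONE = 0
    A_ONLY = 1
    B_ONLY = 2
    OVERLAP = 3


@dataclass
class SubjectDMMap:
    """Per-node condensed DMs for one subject.

    ``dms`` has shape ``(n_nodes, n_item_pairs)``; nodes where the DM could
    not be formed (zero-variance pattern) are flagged in ``missing`` and
    their rows are NaN.
    """

    subject_id: str
    group: str
    dms: np.ndarray
    missing: np.ndarray
    item_ids: tuple
    rings: int

    @property
    def n_nodes(self) -> int:
        return self.dms.shape[0]

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean())

    def node_dm(self, node: int) -> ItemDM:
        if self.missing[node]:
            raise DataError(f"node {node} is flagged missing for subject {self.subject_id}")
        return ItemDM(condensed=self.dms[node].astype(np.float64), item_ids=self.item_ids)


@dataclass
class ConvergenceMap:
    """Mean Fisher-z intersubject DM correlation per node for one group."""

    group: str
    node_z: np.ndarray  # NaN where no valid subject pair exists
    n_pairs: int
    clip_eps: float = DEFAULT_CLIP_EPS

    @property
    def n_nodes(self) -> int:
        return len(self.node_z)

    def finite_values(self) -> np.ndarray:
        return self.node_z[np.isfinite(self.node_z)]


@dataclass
class RegionLabelMap:
    """Per-node region-class labels after overlay and cluster correction."""

    node_label: np.ndarray  # RegionClass values
    threshold_used: float
    min_cluster_size: int

    def nodes_of(self, region_class: RegionClass) -> np.ndarray:
        return np.flatnonzero(self.node_label == int(region_class))


@dataclass
class PermutationNull:
    """Null distribution of convergence under item-label permutation."""

    n_permutations: int
    seed: int
    null_values: np.ndarray
    scheme: str


def searchlight_dm_map(
    betas: np.ndarray,
    mesh,
    rings: int = 2,
    item_ids=None,
    subject_id: str = "subject",
    group: str = "groupA",
    neighborhoods: list[np.ndarray] | None = None,
) -> SubjectDMMap:
    """Correlation-distance DM at every surface node of one subject.

    Parameters
    ----------
    betas
        ``(n_items, n_nodes)`` pattern-estimate array on the mesh.
    mesh
        A :class:`~infonets.mesh.WholeBrainSurface` (or hemisphere mesh).
    rings
        Searchlight extent in edge rings; each item's feature vector at a
        node is its pattern over the node's k-ring patch.
    neighborhoods
        Precomputed ``mesh.all_neighborhoods(rings)`` (shared across
        subjects for speed).
    """
    betas = np.asarray(betas, dtype=np.float64)
    if betas.ndim != 2:
        raise DataError("betas must be (n_items, n_nodes)")
    n_items, n_nodes = betas.shape
    if n_items < 2:
        raise DataError("need at least 2 items")
    if n_nodes != mesh.n_nodes:
        raise IncompatibleMeshError(
            f"betas cover {n_nodes} nodes but mesh has {mesh.n_nodes}"
        )
    if item_ids is None:
        item_ids = tuple(range(n_items))
    if neighborhoods is None:
        neighborhoods = mesh.all_neighborhoods(rings)

    iu = np.triu_indices(n_items, k=1)
    P = n_pairs(n_items)
    dms = np.full((n_nodes, P), np.nan, dtype=np.float64)
    missing = np.zeros(n_nodes, dtype=bool)
    # batch nodes by neighborhood size so the correlation is one einsum per size
    sizes = np.array([len(nb) for nb in neighborhoods])
    for sz in np.unique(sizes):
        nodes = np.flatnonzero(sizes == sz)
        if sz < 2:
            missing[nodes] = True
            continue
        nb_idx = np.stack([neighborhoods[n] for n in nodes])     # (B, sz)
        x = betas[:, nb_idx]                                     # (items, B, sz)
        xc = x - x.mean(axis=2, keepdims=True)
        norms = np.linalg.norm(xc, axis=2)                       # (items, B)
        bad = np.any(norms == 0.0, axis=0)
        norms[norms == 0.0] = 1.0
        xn = xc / norms[:, :, None]
        corr = np.einsum("ibf,jbf->bij", xn, xn)                 # (B, items, items)
        dms[nodes] = 1.0 - np.clip(corr[:, iu[0], iu[1]], -1.0, 1.0)
        if bad.any():
            missing[nodes[bad]] = True
            dms[nodes[bad]] = np.nan
    return SubjectDMMap(
        subject_id=subject_id,
        group=group,
        dms=dms,
        missing=missing,
        item_ids=tuple(item_ids),
        rings=int(rings),
    )


def _check_group(dm_maps: list[SubjectDMMap]) -> None:
    if len(dm_maps) < 2:
        raise InsufficientGroupError("need at least 2 subjects for intersubject convergence")
    ref = dm_maps[0]
    for m in dm_maps[1:]:
        if m.dms.shape != ref.dms.shape:
            raise IncompatibleMeshError("subject DM maps differ in shape")
        if m.item_ids != ref.item_ids:
            raise DataError("subject DM maps differ in item order")


def _normalized_stack(dm_maps: list[SubjectDMMap]) -> tuple[np.ndarray, np.ndarray]:
    """Stack subjects' condensed DMs, mean-centered and unit-normed per node.

    Returns ``(Z, valid)`` with ``Z`` of shape ``(S, N, P)`` (NaN rows where
    invalid) and ``valid`` of shape ``(S, N)``.
    """
    S = len(dm_maps)
    N, P = dm_maps[0].dms.shape
    Z = np.empty((S, N, P), dtype=np.float64)
    valid = np.empty((S, N), dtype=bool)
    for s, m in enumerate(dm_maps):
        c = m.dms - np.nanmean(m.dms, axis=1, keepdims=True)
        norms = np.sqrt(np.nansum(c * c, axis=1))
        ok = ~m.missing & np.isfinite(norms) & (norms > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z[s] = c / norms[:, None]
        Z[s, ~ok] = np.nan
        valid[s] = ok
    return Z, valid


def _mean_z_map(Z: np.ndarray, valid: np.ndarray, clip_eps: float) -> np.ndarray:
    S, N, _ = Z.shape
    acc = np.zeros(N)
    cnt = np.zeros(N, dtype=np.int64)
    for a, b in combinations(range(S), 2):
        ok = valid[a] & valid[b]
        if not ok.any():
            continue
        r = np.einsum("np,np->n", Z[a][ok], Z[b][ok])
        r = np.clip(r, -1.0 + clip_eps, 1.0 - clip_eps)
        acc[ok] += np.arctanh(r)
        cnt[ok] += 1
    out = np.full(N, np.nan)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz]
    return out


def intersubject_convergence(
    dm_maps: list[SubjectDMMap], clip_eps: float = DEFAULT_CLIP_EPS
) -> ConvergenceMap:
    """Mean pairwise intersubject DM correlation (Fisher z) per node.

    For each node and each pair of subjects, the Pearson correlation of the
    two condensed DMs is taken, arctanh-transformed, and averaged; pairs in
    which either subject is missing at a node are dropped nodewise.
    """
    _check_group(dm_maps)
    Z, valid = _normalized_stack(dm_maps)
    node_z = _mean_z_map(Z, valid, clip_eps)
    S = len(dm_maps)
    return ConvergenceMap(
        group=dm_maps[0].group,
        node_z=node_z,
        n_pairs=S * (S - 1) // 2,
        clip_eps=clip_eps,
    )


def estimate_noise_threshold(conv_map: ConvergenceMap) -> float:
    """Data-driven noise threshold: magnitude of the map's negative extent.

    A negative mean intersubject DM correlation can only arise from noise,
    so the most negative observed value bounds the chance range; the
    threshold is its absolute value, applied strictly (``z > threshold``).
    Returns 0 with a warning if the map has no negative values.
    """
    vals = conv_map.finite_values()
    if len(vals) == 0:
        raise DataError("convergence map has no finite nodes")
    lo = float(vals.min())
    if lo >= 0.0:
        warnings.warn(
            "convergence map has no negative values; noise threshold degenerates to 0",
            stacklevel=2,
        )
        return 0.0
    return -lo


def _pair_permutation_index(n_items: int, perm: np.ndarray) -> np.ndarray:
    """Condensed-index gather map implementing an item relabeling."""
    idx = np.zeros((n_items, n_items), dtype=np.int64)
    iu = np.triu_indices(n_items, k=1)
    idx[iu] = np.arange(len(iu[0]))
    idx = idx + idx.T
    pi, pj = perm[iu[0]], perm[iu[1]]
    return idx[pi, pj]


def permutation_null(
    dm_maps: list[SubjectDMMap],
    n_permutations: int,
    seed: int,
    record: str = "max",
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> PermutationNull:
    """Permuted null distribution of the group convergence map.

    Scheme: per permutation, each subject's item labels are shuffled
    independently (one permutation per subject, applied consistently across
    all of that subject's nodes), the node-level mean-z map is recomputed,
    and either the map's maximum (``record="max"``) or its mean
    (``record="mean"``) is stored.
    """
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    if record not in ("max", "mean"):
        raise InvalidParameterError("record must be 'max' or 'mean'")
    _check_group(dm_maps)
    rng = np.random.default_rng(seed)
    n_items = len(dm_maps[0].item_ids)
    Z, valid = _normalized_stack(dm_maps)
    S = Z.shape[0]
    null_values = np.empty(n_permutations)
    for p in range(n_permutations):
        Zp = np.empty_like(Z)
        for s in range(S):
            perm = rng.permutation(n_items)
            gather = _pair_permutation_index(n_items, perm)
            Zp[s] = Z[s][:, gather]
        node_z = _mean_z_map(Zp, valid, clip_eps)
        finite = node_z[np.isfinite(node_z)]
        null_values[p] = finite.max() if record == "max" else finite.mean()
    scheme = (
        "independent within-subject item-label shuffling, consistent across "
        f"nodes; statistic = nodewise mean z, recorded as map {record}"
    )
    return PermutationNull(
        n_permutations=n_permutations,
        seed=seed,
        null_values=null_values,
        scheme=scheme,
    )


def overlay_and_cluster(
    map_a: ConvergenceMap,
    map_b: ConvergenceMap,
    threshold: float,
    min_cluster_size: int,
    mesh,
) -> RegionLabelMap:
    """Overlay two thresholded group maps and apply surface cluster correction.

    A node is ``OVERLAP`` if both maps strictly exceed the threshold,
    ``A_ONLY``/``B_ONLY`` if exactly one does, else ``NONE``.  Within each
    label class, edge-connected components with fewer than
    ``min_cluster_size`` nodes are relabeled ``NONE``.
    """
    if map_a.n_nodes != map_b.n_nodes or map_a.n_nodes != mesh.n_nodes:
        raise IncompatibleMeshError("convergence maps and mesh disagree on node count")
    if threshold < 0:
        raise InvalidParameterError("threshold must be non-negative")
    with np.errstate(invalid="ignore"):
        above_a = np.nan_to_num(map_a.node_z, nan=-np.inf) > threshold
        above_b = np.nan_to_num(map_b.node_z, nan=-np.inf) > threshold
    labels = np.full(mesh.n_nodes, int(RegionClass.NONE), dtype=np.int64)
    labels[above_a & ~above_b] = int(RegionClass.A_ONLY)
    labels[~above_a & above_b] = int(RegionClass.B_ONLY)
    labels[above_a & above_b] = int(RegionClass.OVERLAP)
    for cls in (RegionClass.A_ONLY, RegionClass.B_ONLY, RegionClass.OVERLAP):
        nodes = np.flatnonzero(labels == int(cls))
        for comp in connected_components(nodes, mesh):
            if len(comp) < min_cluster_size:
                labels[list(comp)] = int(RegionClass.NONE)
    return RegionLabelMap(
        node_label=labels,
        threshold_used=float(threshold),
        min_cluster_size=int(min_cluster_size),
    )
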