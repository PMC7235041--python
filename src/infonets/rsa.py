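"""Model RSA over informational networks.

Each participant's average DM per network is correlated (normalized dot
product = Pearson r of the condensed vectors) with a model DM, Fisher
z-transformed, and the per-network distribution of z values is tested
against zero with a one-sample t-test.  The resulting t values paint the
informational gradient on the surface; the network with the largest t is
the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .convergence import SubjectDMMap
from .exceptions import DataError, DegenerateDMError, InvalidParameterError
from .networks import InformationalNetwork
from .repgeom import (
    ItemDM,
    fisher_z,
    normalized_correlation,
    one_sample_t,
)

__all__ = [
    "ModelKind",
    "ModelDM",
    "CategoryLabels",
    "NetworkDMTable",
    "RSAStat",
    "category_model_dm",
    "load_model_dm",
    "network_average_dm",
    "build_network_dm_table",
    "network_rsa",
    "gradient_map",
    "find_peak_network",
]


class ModelKind(str, Enum):
    MECHANICAL_CATEGORY = "mechanical_category"
    VISUAL_SIMILARITY = "visual_similarity"
    CUSTOM = "custom"


@dataclass(frozen=True)
class ModelDM:
    model_kind: ModelKind
    dm: ItemDM
    provenance: str = ""


@dataclass(frozen=True)
class CategoryLabels:
    """Ordered item -> category mapping (e.g. cantilever / truss / vertical_load)."""

    item_ids: tuple
    categories: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "categories", tuple(self.categories))
        if len(self.item_ids) != len(self.categories):
            raise DataError("item_ids and categories must have equal length")
        if len(set(self.categories)) < 2:
            raise DataError("at least 2 categories are required")

    @property
    def category_names(self) -> tuple:
        seen: dict = {}
        for c in self.categories:
            seen.setdefault(c, None)
        return tuple(seen)


def category_model_dm(labels: CategoryLabels) -> ModelDM:
    """Binary category model: 0 within category, 1 between categories."""
    cats = np.asarray(labels.categories, dtype=object)
    iu = np.triu_indices(len(cats), k=1)
    condensed = (cats[iu[0]] != cats[iu[1]]).astype(np.float64)
    return ModelDM(
        model_kind=ModelKind.MECHANICAL_CATEGORY,
        dm=ItemDM(condensed=condensed, item_ids=labels.item_ids),
        provenance="discrete category model (0 within, 1 between)",
    )


def load_model_dm(path, item_ids=None, model_kind: ModelKind = ModelKind.CUSTOM) -> ModelDM:
    """Load an arbitrary model DM from a square-matrix CSV (header = item ids)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    ids = tuple(item_ids) if item_ids is not None else tuple(df.columns)
    square = df.loc[list(ids), list(ids)].to_numpy(dtype=np.float64)
    return ModelDM(
        model_kind=model_kind,
        dm=ItemDM.from_square(square, ids),
        provenance=f"loaded from {path}",
    )


def network_average_dm(dm_map: SubjectDMMap, network: InformationalNetwork) -> ItemDM:
    """Entry-wise mean of the subject's DMs over the network's non-missing nodes."""
    nodes = np.asarray(network.nodes, dtype=np.int64)
    if len(nodes) == 0:
        raise DataError("network has no nodes")
    ok = nodes[~dm_map.missing[nodes]]
    if len(ok) == 0:
        raise DataError(
            f"subject {dm_map.subject_id} is missing every node of {network.network_id}"
        )
    return ItemDM(condensed=dm_map.dms[ok].mean(axis=0), item_ids=dm_map.item_ids)


@dataclass
class NetworkDMTable:
    """(participant, network) -> average ItemDM for one group's networks."""

    group: str
    networks: list[InformationalNetwork]
    dms: dict = field(default_factory=dict)  # (subject_id, network_id) -> ItemDM
    subject_ids: tuple = ()

    def get(self, subject_id: str, network_id: str) -> ItemDM:
        return self.dms[(subject_id, network_id)]


def build_network_dm_table(
    dm_maps: list[SubjectDMMap], networks: list[InformationalNetwork]
) -> NetworkDMTable:
    table = NetworkDMTable(
        group=dm_maps[0].group,
        networks=list(networks),
        subject_ids=tuple(m.subject_id for m in dm_maps),
    )
    for m in dm_maps:
        for net in networks:
            table.dms[(m.subject_id, net.network_id)] = network_average_dm(m, net)
    return table


@dataclass
class RSAStat:
    """Group-level RSA statistic for one network against one model."""

    network_id: str
    model_kind: ModelKind
    z_values: np.ndarray
    statistic: float
    df: int
    p: float
    mean_z: float
    n_nodes: int
    q: float | None = None  # BH-adjusted p, if requested


def network_rsa(
    table: NetworkDMTable,
    model: ModelDM,
    fdr: bool = False,
) -> list[RSAStat]:
    """Normalized correlation of every participant's network DM with the model
    DM (Fisher z), then a one-sample t-test per network.

    Participants with a degenerate (constant) network DM are dropped for
    that network with a warning; networks with fewer than 2 remaining
    participants are skipped.  ``fdr=True`` adds Benjamini-Hochberg adjusted
    p values across the returned networks.
    """
    stats_out: list[RSAStat] = []
    for net in table.networks:
        zs = []
        for sid in table.subject_ids:
            dm = table.get(sid, net.network_id)
            try:
                r = normalized_correlation(dm, model.dm)
            except DegenerateDMError:
                warnings.warn(
                    f"participant {sid} dropped for {net.network_id}: degenerate DM",
                    stacklevel=2,
                )
                continue
            zs.append(fisher_z(r))
        if len(zs) < 2:
            warnings.warn(
                f"network {net.network_id} skipped: fewer than 2 valid participants",
                stacklevel=2,
            )
            continue
        res = one_sample_t(zs)
        stats_out.append(
            RSAStat(
                network_id=net.network_id,
                model_kind=model.model_kind,
                z_values=np.asarray(zs),
                statistic=res.statistic,
                df=res.df,
                p=res.p,
                mean_z=res.mean,
                n_nodes=net.size,
            )
        )
    if fdr and stats_out:
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([s.p for s in stats_out], method="fdr_bh")
        for s, qi in zip(stats_out, q):
            s.q = float(qi)
    return stats_out


def gradient_map(
    stats: list[RSAStat], networks: list[InformationalNetwork], mesh
) -> np.ndarray:
    """Per-node t value inherited from the node's network (NaN elsewhere)."""
    by_id = {s.network_id: s for s in stats}
    out = np.full(mesh.n_nodes, np.nan)
    for net in networks:
        s = by_id.get(net.network_id)
        if s is not None:
            out[np.asarray(net.nodes, dtype=np.int64)] = s.statistic
    return out


def find_peak_network(stats: list[RSAStat]) -> RSAStat:
    """Network with the maximal t; ties go to the larger network, then the
    lexicographically smaller id."""
    if not stats:
        raise InvalidParameterError("no RSA statistics provided")
    return min(stats, key=lambda s: (-s.statistic, -s.n_nodes, s.network_id))
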