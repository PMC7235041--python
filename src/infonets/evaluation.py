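"""Parameter-recovery and calibration experiments on synthetic studies.

These routines run the full pipeline at the reference synthetic
configuration and score how well the planted structure is recovered.  They
are the package's own validation battery; ``scripts/acceptance.py`` and the
acceptance tests both call into them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .convergence import RegionClass
from .embedding import ellipsoid_from_moments
from .mesh import build_whole_brain_surface
from .networks import InformationalNetwork
from .repgeom import ItemDM, PatternMatrix, compute_item_dm, fisher_z, normalized_correlation, one_sample_t
from .rsa import CategoryLabels, category_model_dm, find_peak_network, network_average_dm
from .pipeline import AnalysisConfig, run_pipeline
from .synth import StudyConfig, simulate_study, _default_labels, generate_stimulus_images
from .hmax import default_gabor_bank, visual_model_dm

__all__ = [
    "reference_analysis_config",
    "SeedRecovery",
    "RecoverySummary",
    "recovery_experiment",
    "rsa_null_type1_rate",
    "visual_category_model_correlation",
    "ellipsoid_coverage",
    "whole_brain_node_count",
]

ROLE_TO_CLASS = {
    "expert_category": RegionClass.A_ONLY,
    "novice_only": RegionClass.B_ONLY,
    "both_visual": RegionClass.OVERLAP,
}
# (group, region class) combinations that carry a planted prototype count
PROTOTYPE_REGIONS = (
    ("expert", RegionClass.A_ONLY, "expert_category"),
    ("novice", RegionClass.B_ONLY, "novice_only"),
    ("expert", RegionClass.OVERLAP, "both_visual"),
    ("novice", RegionClass.OVERLAP, "both_visual"),
)


def reference_analysis_config(seed: int = 0) -> AnalysisConfig:
    """Analysis settings used for recovery runs at the test mesh scale.

    Split-half k selection uses 100 repetitions (the full-scale default is
    1000); the k grid keeps its 2..100 span and truncates to the region
    size.
    """
    return AnalysisConfig(
        searchlight_rings=2,
        min_cluster_size=5,
        k_range=(2, 100),
        n_repetitions=100,
        n_permutations=0,
        seed=seed,
    )


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = set(a.tolist()), set(b.tolist())
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class SeedRecovery:
    seed: int
    jaccard: dict                    # role -> Jaccard(planted, recovered)
    k_matches: dict                  # (group, class name) -> bool
    expert_peak_in_planted: bool
    novice_t_at_expert_peak_nonsig: bool
    visual_peak_in_planted: dict     # group -> bool


@dataclass
class RecoverySummary:
    records: list
    jaccard_majority: dict           # role -> fraction of seeds with J >= 0.7
    median_jaccard: dict
    k_recovery_rate: float
    expert_peak_rate: float
    novice_nonsig_rate: float
    visual_peak_rate: dict


def _network_containment(net: InformationalNetwork, planted: np.ndarray) -> bool:
    """Peak network counted inside a planted role region when the majority
    of its nodes are planted nodes."""
    planted_set = set(planted.tolist())
    inside = sum(1 for n in net.nodes if int(n) in planted_set)
    return inside > len(net.nodes) / 2


def _recover_one(seed: int, study_overrides: dict, analysis: AnalysisConfig) -> SeedRecovery:
    cfg = StudyConfig(seed=seed, **study_overrides)
    study = simulate_study(cfg)
    result = run_pipeline(study, analysis)
    gt = study.ground_truth

    jaccard = {
        role: _jaccard(gt.role_nodes[role], result.labels.nodes_of(cls))
        for role, cls in ROLE_TO_CLASS.items()
    }

    k_matches = {}
    for group, cls, role in PROTOTYPE_REGIONS:
        trace = result.k_traces.get((group, cls))
        k_matches[(group, cls.name)] = (
            trace is not None and trace.k_star == gt.planted_k[role]
        )

    nets_by_id = {
        net.network_id: net for group in ("expert", "novice")
        for net in result.group_networks(group)
    }

    expert_peak = result.peaks.get(("expert", "mechanical_category"))
    expert_peak_ok = False
    novice_nonsig = False
    if expert_peak is not None:
        peak_net = nets_by_id[expert_peak.network_id]
        expert_peak_ok = _network_containment(peak_net, gt.role_nodes["expert_category"])
        # novice mechanical t over the same node set
        zs = []
        for m in result.subject_maps["novice"]:
            try:
                dm = network_average_dm(m, peak_net)
                zs.append(fisher_z(normalized_correlation(dm, study.category_model.dm)))
            except Exception:
                continue
        if len(zs) >= 2:
            novice_nonsig = one_sample_t(zs).p > 0.05

    visual_ok = {}
    for group in ("expert", "novice"):
        pk = result.peaks.get((group, "visual_similarity"))
        visual_ok[group] = bool(
            pk is not None
            and _network_containment(nets_by_id[pk.network_id], gt.role_nodes["both_visual"])
        )

    return SeedRecovery(
        seed=seed,
        jaccard=jaccard,
        k_matches=k_matches,
        expert_peak_in_planted=expert_peak_ok,
        novice_t_at_expert_peak_nonsig=novice_nonsig,
        visual_peak_in_planted=visual_ok,
    )


def recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    study_overrides: dict | None = None,
    analysis: AnalysisConfig | None = None,
) -> RecoverySummary:
    """Full-pipeline parameter recovery over independent study seeds.

    Each seed simulates a fresh reference study (mesh L=8, groups 16/15,
    24 items in 8/8/8 categories, snr 1.0) and scores region-label Jaccard
    per role, planted-k selection, and peak-network placement.
    """
    study_overrides = dict(study_overrides or {})
    records = []
    for i in range(n_seeds):
        seed = (base_seed * 100003 + i) % (2**31)
        records.append(_recover_one(seed, study_overrides, analysis or reference_analysis_config(seed)))

    roles = list(ROLE_TO_CLASS)
    jacc = {role: np.array([r.jaccard[role] for r in records]) for role in roles}
    k_flags = np.array([
        all(r.k_matches.values()) for r in records
    ])
    return RecoverySummary(
        records=records,
        jaccard_majority={role: float((jacc[role] >= 0.7).mean()) for role in roles},
        median_jaccard={role: float(np.median(jacc[role])) for role in roles},
        k_recovery_rate=float(k_flags.mean()),
        expert_peak_rate=float(np.mean([r.expert_peak_in_planted for r in records])),
        novice_nonsig_rate=float(np.mean([r.novice_t_at_expert_peak_nonsig for r in records])),
        visual_peak_rate={
            g: float(np.mean([r.visual_peak_in_planted[g] for r in records]))
            for g in ("expert", "novice")
        },
    )


def rsa_null_type1_rate(
    n_networks: int = 1000,
    n_participants: int = 16,
    n_items: int = 24,
    n_features: int = 32,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the network RSA t-test under the null.

    Each simulated network gives every participant an independent DM (from
    random Gaussian patterns, so DM entries carry realistic dependence) that
    is unrelated to the model; the fraction of networks with p < alpha
    estimates the false-positive rate, nominally alpha.
    """
    rng = np.random.default_rng(seed)
    labels = CategoryLabels(
        item_ids=tuple(range(n_items)),
        categories=tuple(i % 3 for i in range(n_items)),
    )
    model = category_model_dm(labels)
    rejections = 0
    for _ in range(n_networks):
        zs = np.empty(n_participants)
        for s in range(n_participants):
            pats = PatternMatrix(
                item_ids=labels.item_ids,
                features=rng.normal(size=(n_items, n_features)),
            )
            dm = compute_item_dm(pats)
            zs[s] = fisher_z(normalized_correlation(dm, model.dm))
        if one_sample_t(zs).p < alpha:
            rejections += 1
    return rejections / n_networks


def visual_category_model_correlation(seed: int = 0, n_items: int = 24) -> float:
    """Normalized correlation between the HMAX-C1 visual DM of the shipped
    synthetic stimulus generator and the binary category DM."""
    cfg = StudyConfig(seed=seed, n_items=n_items)
    labels = _default_labels(cfg)
    images = generate_stimulus_images(labels, seed=seed, size=cfg.image_size)
    vdm = visual_model_dm(images, default_gabor_bank())
    cdm = category_model_dm(labels)
    return normalized_correlation(vdm.dm, cdm.dm)


def ellipsoid_coverage(
    n_draws: int = 100_000, probability: float = 0.95, seed: int = 0
) -> float:
    """Fraction of fresh trivariate-normal draws inside the population
    concentration ellipsoid at the stated probability."""
    rng = np.random.default_rng(seed)
    # a deliberately anisotropic, rotated population covariance
    A = rng.normal(size=(3, 3))
    cov = A @ A.T + 0.5 * np.eye(3)
    mean = rng.normal(size=3)
    ell = ellipsoid_from_moments(mean, cov, probability)
    draws = rng.multivariate_normal(mean, cov, size=n_draws)
    return float(ell.contains(draws).mean())


def whole_brain_node_count(linear_divisions: int = 32) -> int:
    """Total node count of the standard whole-brain surface."""
    return build_whole_brain_surface(linear_divisions).n_nodes
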