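"""End-to-end orchestration of the four-stage analysis.

``run_pipeline`` executes: searchlight DM maps per subject -> within-group
intersubject convergence maps -> data-driven noise threshold and overlay
with surface cluster correction -> informational networks per (group,
region class) via split-half cross-validated Ward clustering -> RSA of
every network against the mechanical-category and visual-similarity model
DMs -> gradient maps and peak networks.  A run manifest records the
configuration, seeds, stage timings and digests of everything written.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .convergence import (
    ConvergenceMap,
    RegionClass,
    RegionLabelMap,
    SubjectDMMap,
    estimate_noise_threshold,
    intersubject_convergence,
    overlay_and_cluster,
    permutation_null,
    searchlight_dm_map,
)
from .exceptions import DataError, EmptyRegionError, InsufficientGroupError
from .networks import (
    InformationalNetwork,
    define_networks,
    region_average_dms,
    select_k_split_half,
    ward_cluster,
)
from .rsa import (
    ModelDM,
    RSAStat,
    build_network_dm_table,
    find_peak_network,
    gradient_map,
    network_rsa,
)
from .synth import SyntheticStudy, StudyConfig, simulate_study

__all__ = ["AnalysisConfig", "PipelineResult", "run_pipeline"]

GROUP_TO_CLASS = {"expert": RegionClass.A_ONLY, "novice": RegionClass.B_ONLY}
REGION_CLASSES = (RegionClass.A_ONLY, RegionClass.B_ONLY, RegionClass.OVERLAP)


@dataclass
class AnalysisConfig:
    """Analysis-side knobs (the study conditions live in StudyConfig)."""

    searchlight_rings: int = 2
    min_cluster_size: int = 5
    k_range: tuple = (2, 100)
    n_repetitions: int = 1000
    n_permutations: int = 0  # 0 skips the permutation validation stage
    seed: int = 0
    fdr: bool = False


@dataclass
class PipelineResult:
    study: SyntheticStudy
    analysis: AnalysisConfig
    subject_maps: dict                     # group -> list[SubjectDMMap]
    convergence: dict                      # group -> ConvergenceMap
    thresholds: dict                       # group -> float; "applied" -> float
    labels: RegionLabelMap
    k_traces: dict                         # (group, RegionClass) -> KSelectionTrace
    networks: dict                         # (group, RegionClass) -> list[InformationalNetwork]
    rsa: dict                              # (group, model kind str) -> list[RSAStat]
    gradients: dict                        # (group, model kind str) -> node array
    peaks: dict                            # (group, model kind str) -> RSAStat
    permutation: dict                      # group -> PermutationNull (if requested)
    manifest: dict

    def group_networks(self, group: str) -> list[InformationalNetwork]:
        out: list[InformationalNetwork] = []
        for cls in REGION_CLASSES:
            out.extend(self.networks.get((group, cls), []))
        return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    study: SyntheticStudy | StudyConfig,
    analysis: AnalysisConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run every stage on a (synthetic) study; optionally write outputs.

    ``study`` may be a ready :class:`SyntheticStudy` or a
    :class:`StudyConfig` to simulate first.  All randomness is funneled
    through ``analysis.seed`` (stage-specific substreams) and the study's
    own seed, so a rerun is bit-identical.
    """
    analysis = analysis or AnalysisConfig()
    if isinstance(study, StudyConfig):
        study = simulate_study(study)
    mesh = study.mesh
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # stage 1: searchlight DM maps
    neighborhoods = mesh.all_neighborhoods(analysis.searchlight_rings)
    subject_maps: dict[str, list[SubjectDMMap]] = {"expert": [], "novice": []}
    for sid in study.subject_ids:
        m = searchlight_dm_map(
            study.betas[sid],
            mesh,
            rings=analysis.searchlight_rings,
            item_ids=study.labels.item_ids,
            subject_id=sid,
            group=study.groups[sid],
            neighborhoods=neighborhoods,
        )
        subject_maps[study.groups[sid]].append(m)
    timings["searchlight"] = time.perf_counter() - t0

    # stage 2: convergence, threshold, overlay, cluster correction
    t0 = time.perf_counter()
    convergence = {g: intersubject_convergence(ms) for g, ms in subject_maps.items()}
    thresholds = {g: estimate_noise_threshold(c) for g, c in convergence.items()}
    # one common threshold: the stricter (larger) of the two group estimates
    applied = max(thresholds.values())
    thresholds["applied"] = applied
    labels = overlay_and_cluster(
        convergence["expert"],
        convergence["novice"],
        applied,
        analysis.min_cluster_size,
        mesh,
    )
    permutation = {}
    if analysis.n_permutations > 0:
        for gi, (g, ms) in enumerate(subject_maps.items()):
            permutation[g] = permutation_null(
                ms, analysis.n_permutations, seed=analysis.seed + 7919 * (gi + 1)
            )
    timings["convergence"] = time.perf_counter() - t0

    # stage 3: informational networks per (group, region class)
    t0 = time.perf_counter()
    k_traces = {}
    networks = {}
    for gi, group in enumerate(("expert", "novice")):
        for ci, cls in enumerate(REGION_CLASSES):
            try:
                region = region_average_dms(subject_maps[group], labels, cls)
            except EmptyRegionError:
                warnings.warn(f"no {cls.name} nodes for {group}; skipping", stacklevel=2)
                continue
            if region.n_nodes < 2:
                warnings.warn(
                    f"{cls.name} has a single node for {group}; skipping", stacklevel=2
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # k-range truncation on small regions
                trace = select_k_split_half(
                    subject_maps[group],
                    labels,
                    cls,
                    k_range=analysis.k_range,
                    n_repetitions=analysis.n_repetitions,
                    seed=analysis.seed + 104729 * (3 * gi + ci + 1),
                )
            solution = ward_cluster(region, trace.k_star)
            k_traces[(group, cls)] = trace
            networks[(group, cls)] = define_networks(solution, region)
    timings["networks"] = time.perf_counter() - t0

    # stages 3b-4: RSA against mechanical and visual model DMs
    t0 = time.perf_counter()
    rsa: dict = {}
    gradients: dict = {}
    peaks: dict = {}
    models: dict[str, ModelDM] = {
        "mechanical_category": study.category_model,
        "visual_similarity": study.visual_model,
    }
    for group in ("expert", "novice"):
        nets = []
        for cls in REGION_CLASSES:
            nets.extend(networks.get((group, cls), []))
        if not nets:
            continue
        table = build_network_dm_table(subject_maps[group], nets)
        for kind, model in models.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats = network_rsa(table, model, fdr=analysis.fdr)
            rsa[(group, kind)] = stats
            gradients[(group, kind)] = gradient_map(stats, nets, mesh)
            if stats:
                peaks[(group, kind)] = find_peak_network(stats)
    timings["rsa"] = time.perf_counter() - t0

    manifest = {
        "package_version": _pkg_version,
        "study_seed": study.config.seed,
        "analysis": asdict(analysis),
        "study_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(study.config).items()
            if k != "planted_regions"
        },
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {},
    }
    result = PipelineResult(
        study=study,
        analysis=analysis,
        subject_maps=subject_maps,
        convergence=convergence,
        thresholds=thresholds,
        labels=labels,
        k_traces=k_traces,
        networks=networks,
        rsa=rsa,
        gradients=gradients,
        peaks=peaks,
        permutation=permutation,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    from .io import save_label_map_gifti, save_scalar_map_gifti, scalar_map_to_csv

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for g, cmap in result.convergence.items():
        written.append(scalar_map_to_csv(cmap.node_z, out_dir / f"convergence_{g}.csv"))
        written.append(save_scalar_map_gifti(cmap.node_z, out_dir / f"convergence_{g}.func.gii"))
    written.append(
        scalar_map_to_csv(result.labels.node_label, out_dir / "region_labels.csv")
    )
    written.append(
        save_label_map_gifti(result.labels.node_label, out_dir / "region_labels.label.gii")
    )
    rows = []
    for (group, kind), stats in result.rsa.items():
        for s in stats:
            rows.append(
                dict(
                    group=group, model=kind, network_id=s.network_id, t=s.statistic,
                    df=s.df, p=s.p, mean_z=s.mean_z, n_nodes=s.n_nodes,
                )
            )
    rsa_path = out_dir / "rsa_stats.csv"
    pd.DataFrame(rows).to_csv(rsa_path, index=False)
    written.append(rsa_path)
    krows = []
    for (group, cls), trace in result.k_traces.items():
        for k, score in trace.reproducibility_by_k.items():
            krows.append(
                dict(group=group, region_class=cls.name, k=k,
                     reproducibility=score, k_star=trace.k_star)
            )
    ksel_path = out_dir / "k_selection.csv"
    pd.DataFrame(krows).to_csv(ksel_path, index=False)
    written.append(ksel_path)
    nrows = []
    for (group, cls), nets in result.networks.items():
        for net in nets:
            for node in net.nodes:
                nrows.append(
                    dict(group=group, region_class=cls.name,
                         network_id=net.network_id, node_index=int(node))
                )
    nets_path = out_dir / "network_membership.csv"
    pd.DataFrame(nrows).to_csv(nets_path, index=False)
    written.append(nets_path)
    for (group, kind), grad in result.gradients.items():
        written.append(
            scalar_map_to_csv(grad, out_dir / f"gradient_{group}_{kind}.csv")
        )
    result.manifest["outputs"] = {p.name: _digest(p) for p in written}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
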