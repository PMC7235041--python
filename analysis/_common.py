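"""Shared driver plumbing: the reference study and a cached pipeline run.

The numbered analysis scripts all operate on the same reference synthetic
study (seed 42).  The pipeline result is cached as a pickle under
``scratch/`` so later stages do not recompute earlier ones; delete the
cache to force a full rerun.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import infonets as inf
from infonets.evaluation import reference_analysis_config

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
REFERENCE_SEED = 42


def get_study() -> inf.SyntheticStudy:
    return inf.simulate_study(inf.StudyConfig(seed=REFERENCE_SEED))


def get_result() -> inf.PipelineResult:
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"pipeline_seed{REFERENCE_SEED}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    result = inf.run_pipeline(get_study(), reference_analysis_config(REFERENCE_SEED))
    with open(cache, "wb") as fh:
        pickle.dump(result, fh)
    return result


def ensure_results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
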