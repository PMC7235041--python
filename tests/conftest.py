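import numpy as np
import pytest

import infonets as inf


@pytest.fixture(scope="session")
def base_icosahedron():
    return inf.build_icosahedral_mesh(1)


@pytest.fixture(scope="session")
def small_mesh():
    """L=4 single hemisphere (162 nodes)."""
    return inf.build_icosahedral_mesh(4)


@pytest.fixture(scope="session")
def tiny_study():
    """A fast end-to-end study: L=4 whole brain, 4+4 subjects, small patches."""
    cfg = inf.StudyConfig(
        seed=2024,
        mesh_divisions=4,
        group_sizes=(4, 4),
        patch_rings=2,
        snr=2.0,
    )
    return inf.simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_result(tiny_study):
    analysis = inf.AnalysisConfig(n_repetitions=20, seed=7)
    return inf.run_pipeline(tiny_study, analysis)
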