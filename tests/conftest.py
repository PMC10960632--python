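import numpy as np
import pytest

from dediff.synthetic import DesignSpec, SignalParams, generate_betas, generate_design


def small_design_spec(seed: int = 3) -> DesignSpec:
    """Reduced study design used across tests: 24 objects (2 targets,
    18 paired, 4 baseline), 8 scenes (1 target), 28 retrieval trials."""
    return DesignSpec(
        n_objects=24, n_object_targets=2, n_paired=18, n_baseline=4,
        n_scenes=8, n_scene_targets=1,
        retrieval_counts={"old_match": 8, "old_mismatch": 6,
                          "old_new_scene": 4, "new_objects": 10},
        seed=seed,
    )


@pytest.fixture
def small_design():
    return generate_design(small_design_spec())


@pytest.fixture
def small_subject(small_design):
    """One subject on an 8^3 grid with a 4^3 signal region."""
    grid = (8, 8, 8)
    reg = np.zeros(grid, dtype=bool)
    reg[2:6, 2:6, 2:6] = True
    params = SignalParams(a_cat=0.2, b_item=0.2, grid_shape=grid,
                          signal_region=np.flatnonzero(reg.reshape(-1)))
    betas = generate_betas(small_design, params, seed=7)
    return small_design, betas, params
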