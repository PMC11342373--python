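import pytest

from pfasmrm import (
    build_default_panel,
    default_generation_params,
    design_validation_batch,
    simulate_peak_table,
)
from pfasmrm.pipeline import quantify_batch


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def noise_free_batch(panel):
    """One leafy-category batch with no noise and no RT jitter."""
    design = design_validation_batch("leafy", seed=11)
    params = default_generation_params(noise_cv=0.0)
    params.rt_jitter_sd = 0.0
    table = simulate_peak_table(design, params, panel)
    return design, params, table


@pytest.fixture(scope="session")
def noise_free_result(noise_free_batch, panel):
    design, params, table = noise_free_batch
    return quantify_batch(table, design.samples(), panel, mfs_levels=design.mfs_levels)
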