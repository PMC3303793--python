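import numpy as np
import pytest

import photolineage as pl
from photolineage.pipeline import quantify_stack, segment_stack


@pytest.fixture(scope="session")
def regen_sim():
    """Default end-point regeneration scenario at seed 0."""
    scenario = pl.scenario_preset("regeneration_7dpa", seed=0)
    stack, truth = pl.simulate_tissue(scenario)
    return scenario, stack, truth


@pytest.fixture(scope="session")
def regen_segmented(regen_sim):
    scenario, stack, truth = regen_sim
    masks, backgrounds = segment_stack(stack)
    records = quantify_stack(masks, stack, backgrounds)
    return masks, backgrounds, records


@pytest.fixture(scope="session")
def regen_mixture(regen_segmented):
    _, _, records = regen_segmented
    x = records.loc[
        records["bgsub_mean_nuclear_converted"] > 0, "bgsub_mean_nuclear_converted"
    ].to_numpy()
    model, table = pl.select_K(x, 1, 6, restarts=20, seed=0)
    return model, table


@pytest.fixture(scope="session")
def gastr_sim():
    """Noiseless gastrulation time-lapse at seed 0."""
    scenario = pl.scenario_preset("gastrulation_videoS1", seed=0)
    stack, truth = pl.simulate_tissue(scenario)
    return scenario, stack, truth


@pytest.fixture(scope="session")
def gastr_frames(gastr_sim):
    scenario, stack, truth = gastr_sim
    masks, backgrounds = segment_stack(stack, membrane_guided=True)
    records = quantify_stack(masks, stack, backgrounds)
    frames = [
        records[records["frame"] == t].reset_index(drop=True) for t in range(stack.n_frames)
    ]
    return masks, records, frames


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
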