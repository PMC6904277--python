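"""Shared fixtures: small rendered scenes and plate tables.

Expensive stacks are module- or session-scoped so the suite stays fast.
"""

import numpy as np
import pytest

from lblcellfit.presets import RenderConfig
from lblcellfit.synthetic_data.colony import CellAgent, render_frame


@pytest.fixture(scope="session")
def noise_free_render() -> RenderConfig:
    return RenderConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def single_rod_frame(noise_free_render):
    """One 4 x 1 μm rod rendered without noise, plus its parameters."""
    cell = CellAgent(
        id=0,
        center=np.array([25.6, 25.6]),
        angle=0.3,
        length=4.0,
        width=1.0,
        t_birth=0.0,
        t_lag_end=0.0,
        elong_rate=0.0,
        gfp_level=1000.0,
    )
    channels = render_frame([cell], noise_free_render, np.random.default_rng(0))
    return channels["gfp"], cell, noise_free_render


@pytest.fixture(scope="session")
def small_control_stack():
    """A small control-colony movie shared by imaging tests."""
    from lblcellfit.synthetic_data import simulate_colony_stack

    stack, truth = simulate_colony_stack("control", n_cells0=8, seed=42)
    return stack, truth
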