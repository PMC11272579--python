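import numpy as np
import pytest

from goalpursuit import agents, experiments, task_engine


@pytest.fixture(scope="session")
def zero_noise_params():
    """Generative parameters with no walk noise and no jumps."""
    return task_engine.GenerativeParams(
        init_var=0.0, walk_var=0.0, p_jump_up=0.0, p_jump_down=0.0
    )


@pytest.fixture(scope="session")
def small_schedule():
    """A small accepted schedule shared across tests (seeded)."""
    rng = np.random.default_rng(123)
    return experiments.make_schedule(rng, n_blocks=8, n_trials_per_block=40, n_rollouts=30)


@pytest.fixture(scope="session")
def small_ts_cfg(small_schedule):
    return agents.TreeSearchConfig(n_rollouts=30, max_horizon=60, params=small_schedule.params)


def constant_block(net_size, offers, n_trials=30, block_id=0):
    """A block whose offers are constant across trials."""
    offers = np.tile(np.asarray(offers, dtype=float), (n_trials, 1))
    return task_engine.Block(block_id=block_id, net_size=float(net_size), offers=offers)
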