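import numpy as np
import pytest
from hypothesis import settings

from radcap.config import ProblemConfig, baseline_config

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_config(
    n_regular=3,
    n_overtime=1,
    schedule=(1, 1, 0),
    regular_capacity=(1, 1, 1),
    overtime_capacity=(1,),
    p_ip=0.3,
    p_ep=0.2,
    show=0.7,
    wc_ip=0.78,
    wc_op=1.56,
    oc=2.76,
    pc_ip=24.96,
    pc_op=12.48,
) -> ProblemConfig:
    """Small hand-specified instances for exact and oracle tests."""
    return ProblemConfig(
        n_regular=n_regular,
        n_overtime=n_overtime,
        regular_capacity=tuple(regular_capacity),
        overtime_capacity=tuple(overtime_capacity),
        schedule=tuple(schedule),
        wc_ip=wc_ip,
        wc_op=wc_op,
        oc_ip=oc,
        oc_op=oc,
        pc_ip=pc_ip,
        pc_op=pc_op,
        p_ip=tuple([p_ip] * n_regular),
        p_ep=tuple([p_ep] * n_regular),
        show_probs=tuple(tuple([show] * ag) for ag in schedule),
    )


@pytest.fixture
def tiny_config() -> ProblemConfig:
    """N=3, K=1, single-machine instance; small enough for brute force."""
    return make_config()


@pytest.fixture
def oracle_config() -> ProblemConfig:
    """N=2, K=1 instance small enough to enumerate every deterministic
    Markov policy (256 of them) for exact cross-checks."""
    return make_config(
        n_regular=2, n_overtime=1, schedule=(1, 1),
        regular_capacity=(1, 1), overtime_capacity=(1,),
    )


@pytest.fixture(scope="session")
def baseline() -> ProblemConfig:
    """The case-study instance: N=37, K=4, double overbooking, 2+1 fleet."""
    return baseline_config()


@pytest.fixture(scope="session")
def small_solved():
    """A solved mid-size instance shared across simulator tests."""
    from radcap.solver import solve

    config = baseline_config(
        n_regular=8, n_overtime=2, n_extra=2, overbook_gap=4, show_probs=0.8
    )
    return config, solve(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
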