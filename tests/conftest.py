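import pytest

from phenospace import (
    MutationModel,
    build_clock_model,
    build_design_space,
    build_transition_matrix,
    default_clock_slice,
    fitness_profile,
)


@pytest.fixture(scope="session")
def clock():
    return build_clock_model(2, 2)


@pytest.fixture(scope="session")
def clock_space(clock):
    return build_design_space(clock, default_clock_slice(clock))


@pytest.fixture(scope="session")
def bias_model():
    return MutationModel(lam=0.6, delta=1.85, pi=6.0, m=1e-7)


@pytest.fixture(scope="session")
def bias_tm(clock_space, bias_model):
    return build_transition_matrix(clock_space, bias_model)


@pytest.fixture(scope="session")
def volume_tm(clock_space):
    return build_transition_matrix(
        clock_space, MutationModel(lam=float("inf"), delta=1.0, m=1e-7)
    )


@pytest.fixture(scope="session")
def neutral_fitness(clock_space):
    return fitness_profile("neutral", numbers=clock_space.numbers)


@pytest.fixture(scope="session")
def burden_fitness():
    return fitness_profile("burden_printed")
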