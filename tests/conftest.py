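import numpy as np
import pytest

from planaxis import (
    MarkovParams,
    NerveMapParams,
    build_1d_grid,
    default_network,
    fragment_outcome,
    generate_field,
    make_schedule,
    make_worm_outline,
    production_from_divergence,
    run_schedule,
    scenario_library,
)

L_BODY = 0.012  # reference worm length (m)


@pytest.fixture(scope="session")
def grid1d():
    return build_1d_grid(L_BODY, 100)


@pytest.fixture(scope="session")
def field1d(grid1d):
    return generate_field(grid1d, NerveMapParams(body_plan="1H"))


@pytest.fixture(scope="session")
def production1d(grid1d, field1d):
    return production_from_divergence(field1d, grid1d)


@pytest.fixture(scope="session")
def model():
    return default_network()


@pytest.fixture(scope="session")
def markov_params():
    return MarkovParams()


@pytest.fixture(scope="session")
def untreated_result(model, grid1d, field1d, production1d):
    """Untreated 1D worm, five-fragment cut, 4.5 d init + 4.5 d post-cut.

    Shared by the wild-type prediction, trend and gradient-polarity tests.
    """
    cuts = scenario_library()["five-transverse"].cuts(L_BODY)
    return run_schedule(
        model, grid1d, field1d, production1d, make_schedule(None), cuts
    )


@pytest.fixture(scope="session")
def untreated_outcomes(untreated_result, markov_params):
    return [
        fragment_outcome(fs, markov_params)[0]
        for fs in untreated_result.fragments
    ]


@pytest.fixture(scope="session")
def worm_outline():
    return make_worm_outline()


def run_intervention(model, grid, u, G, label, scenario="five-transverse"):
    cuts = scenario_library()[scenario].cuts(L_BODY)
    return run_schedule(model, grid, u, G, make_schedule(label), cuts)
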