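"""Shared fixtures: parameter sets, the stand-in sequence series, toy chains."""

import numpy as np
import pytest

from tmsd.landscape import (
    DETACHED,
    DISPLACED,
    TOEHOLD_BOUND,
    LandscapeParams,
    MarkovChain,
)
from tmsd.nn_thermo import NNParameterSet
from tmsd.synthetic import (
    MismatchSeriesSpec,
    generate_mismatch_series,
    reference_design,
)


@pytest.fixture(scope="session")
def params():
    return NNParameterSet.default()


@pytest.fixture(scope="session")
def params_nosalt():
    return NNParameterSet.default(salt=None)


@pytest.fixture(scope="session")
def uniform_params():
    return NNParameterSet.uniform()


@pytest.fixture(scope="session")
def series_spec():
    return MismatchSeriesSpec(positions=(2, 3, 4, 5, 7, 9, 11, 13))


@pytest.fixture(scope="session")
def slide_series(series_spec):
    return generate_mismatch_series(series_spec)


@pytest.fixture(scope="session")
def point_series():
    spec = MismatchSeriesSpec(positions=(15, 17),
                              construction="point_mutation")
    return generate_mismatch_series(spec)


@pytest.fixture(scope="session")
def reference_system(series_spec):
    return reference_design(series_spec).as_system(4)


@pytest.fixture(scope="session")
def landscape_defaults():
    return LandscapeParams()


def make_flat_chain(n_interior: int, k: float = 1.0,
                    detach: float | None = None) -> MarkovChain:
    """Unbiased walk: n_interior transient states between two absorbers.

    TOEHOLD_BOUND is the first interior state; all interior hops have rate
    ``k`` and the first state detaches at rate ``detach`` (default ``k``),
    which makes the displaced-before-detached probability the classic
    gambler's-ruin value 1/(n_interior + 1).
    """
    detach = k if detach is None else detach
    h = 4
    labels = [DETACHED, TOEHOLD_BOUND]
    coords = [h - 1, h]
    for i in range(1, n_interior):
        labels.append(f"BRANCH({h + i})")
        coords.append(h + i)
    labels.append(DISPLACED)
    coords.append(h + n_interior)
    S = len(labels)
    rates = np.zeros((S, S))
    rates[1, 0] = detach
    for i in range(1, S - 1):
        if i + 1 < S:
            rates[i, i + 1] = k
        if i > 1:
            rates[i, i - 1] = k
    G = np.full(S, np.nan)
    G[1:S - 1] = 0.0
    return MarkovChain(labels=tuple(labels), G=G, rates=rates,
                       coordinate=np.array(coords))


@pytest.fixture
def flat_chain_9():
    return make_flat_chain(9)
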