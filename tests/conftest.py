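import numpy as np
import pytest

from tvcentrality import (
    AdjacencyMatrix,
    CorrelationMatrix,
    ParcelTimeSeries,
    SyntheticCohortSpec,
    sinusoidal_driver,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Cheap 24-parcel cohort with planted communities."""
    return SyntheticCohortSpec(
        n_participants=3,
        n_parcels=24,
        community_sizes=(8, 8, 8),
        n_timepoints=240,
        tr_seconds=1.0,
        r_within=0.6,
        r_between=0.1,
        seed=7,
    )


@pytest.fixture
def coupled_spec():
    """Small coupled cohort: first community driven by a slow sinusoid."""
    return SyntheticCohortSpec(
        n_participants=6,
        n_parcels=24,
        community_sizes=(8, 8, 8),
        n_timepoints=400,
        tr_seconds=1.0,
        r_within=0.6,
        r_between=0.1,
        coupled_parcels=tuple(range(8)),
        coupling_gain=1.5,
        driver=sinusoidal_driver(400, 1.0, period_s=80.0),
        seed=11,
    )


def random_timeseries(rng, n=10, t=60, tr=1.0):
    return ParcelTimeSeries(
        values=rng.standard_normal((n, t)),
        parcel_ids=[f"P{i:03d}" for i in range(n)],
        tr_seconds=tr,
    )


def random_correlation(rng, n=10, t=200):
    x = rng.standard_normal((n, t))
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(values=c, parcel_ids=[f"P{i:03d}"
                                                   for i in range(n)])


def adjacency_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    density = len(edges) / (n * (n - 1) / 2)
    return AdjacencyMatrix(values=a, density=density)


def random_adjacency(rng, n=40, density=0.15):
    from tvcentrality import proportional_threshold

    return proportional_threshold(random_correlation(rng, n=n, t=120),
                                  density)
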