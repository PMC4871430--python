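import numpy as np
import pytest

from pyvitality import (
    IntervalDeaths,
    ModelParams,
    SimConfig,
    fit_mle,
    records_to_interval_counts,
    simulate_cohort,
    total_survival,
)

# Parameter set typical of a late-19th-century human cohort (units: r, lam in
# 1/year; s in year^-1/2; beta as a fraction of initial vitality).  Mean
# intrinsic lifespan 1/r ~ 74 years, extrinsic (Gompertz-like) hazard with
# slope r/beta ~ 0.034/year.
BENCHMARK = ModelParams(r=0.0135, s=0.0126, lam=0.0449, beta=0.3999)

AGE_GRID = np.arange(0.0, 111.0)


@pytest.fixture(scope="session")
def benchmark_params() -> ModelParams:
    return BENCHMARK


@pytest.fixture(scope="session")
def age_grid() -> np.ndarray:
    return AGE_GRID


def expectation_interval_deaths(params: ModelParams, n: int, breaks=AGE_GRID) -> IntervalDeaths:
    """Interval counts equal to their expectation under the closed form.

    Rounding residual goes to the largest cell; at the n used in tests the
    rounding perturbation is negligible relative to 1/n.
    """
    S = np.atleast_1d(total_survival(params, breaks))
    raw = np.empty(breaks.size)
    raw[:-1] = n * (S[:-1] - S[1:])
    raw[-1] = n * S[-1]
    deaths = np.round(raw).astype(np.int64)
    deaths[int(np.argmax(deaths))] += n - deaths.sum()
    return IntervalDeaths(breaks=np.asarray(breaks, dtype=float), deaths=deaths, n_entry=n)


@pytest.fixture(scope="session")
def benchmark_cohort():
    """One simulated cohort at the benchmark parameters, reused across tests."""
    cfg = SimConfig(params=BENCHMARK, n=10_000, seed=11, dt=0.05, max_age=110.0)
    records = simulate_cohort(cfg)
    counts = records_to_interval_counts(records, AGE_GRID)
    return records, counts


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_cohort):
    """Raw ML fit of the session cohort (no bias correction)."""
    _, counts = benchmark_cohort
    return fit_mle(counts)
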