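import numpy as np
import pytest

from deepclick import movesim


@pytest.fixture(scope="session")
def strategy_tables():
    """Monthly detection tables for all four strategies at full study size
    (100 agents x 10 years, years 2-10 analyzed), one shared seed."""
    tables = {}
    for strat in movesim.STRATEGIES:
        res = movesim.run_simulation(
            movesim.StrategyConfig.defaults(strat), n_agents=100, n_years=10, seed=11
        )
        tables[strat] = movesim.monthly_detection(res)
    return tables


@pytest.fixture(scope="session")
def strategy_comparison():
    """RMSD comparison of all strategies over 10 seeded reps against the
    default reference table."""
    return movesim.compare_strategies(n_reps=10, base_seed=3)


def annual_harmonic_peak_to_trough(values) -> float:
    """Peak-to-trough amplitude of the annual (period-12) harmonic of a
    12-value monthly cycle."""
    v = np.asarray(values, dtype=float)
    m = np.arange(1, 13)
    amp = np.abs(np.sum(v * np.exp(-2j * np.pi * m / 12))) * 2 / 12
    return 2 * amp
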