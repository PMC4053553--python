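import numpy as np
import pandas as pd
import pytest

from pphmap.areal import AreaConditionData, AreaGraph, StratumTable, assemble
from pphmap.simulate import GeneratorConfig, generate, make_lattice


@pytest.fixture(scope="session")
def small_dataset():
    """6x6 lattice, 3 conditions, modest counts — fast enough for MCMC."""
    cfg = GeneratorConfig(
        n_areas=36, n_conditions=3,
        conditions=("copd", "chf", "angina"),
        baseline_rates=(155.0, 88.9, 23.9),
        delta=(1.12, 0.74, 1.11),
        sigma_specific=(0.112, 0.079, 0.489),
        py_annual_range=(4_065.0, 60_000.0),
        seed=42,
    )
    table, graph, truth = generate(cfg)
    return table, graph, truth


@pytest.fixture(scope="session")
def small_data(small_dataset):
    table, graph, _ = small_dataset
    return assemble(table, graph)


@pytest.fixture(scope="session")
def rook22():
    return make_lattice(2, 2, "rook")


@pytest.fixture()
def toy_stratum_frame():
    return pd.DataFrame({
        "area_id": ["a1", "a1", "a2", "a2"],
        "condition": ["copd"] * 4,
        "stratum_id": ["s1", "s2", "s1", "s2"],
        "person_years": [100.0, 200.0, 300.0, 400.0],
        "count": [1, 2, 3, 4],
    })


def two_area_data(observed=(12, 5), expected_scale=1.0):
    """Minimal valid AreaConditionData on a 2-area graph, expecteds
    proportional so that conservation holds."""
    graph = AreaGraph(("a", "b"),
                      {"a": frozenset({"b"}), "b": frozenset({"a"})})
    o = np.array(observed, dtype=np.int64).reshape(2, 1)
    e = np.full((2, 1), o.sum() / 2.0) * expected_scale
    e *= o.sum() / e.sum()
    return AreaConditionData(graph=graph, conditions=("x",), observed=o,
                             expected=e, person_years=np.array([1e4, 1e4]))
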