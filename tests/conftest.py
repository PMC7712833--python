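import numpy as np
import pytest

from mbndiallel import (
    FarrowingRecord,
    McmcConfig,
    ModelSpec,
    Pedigree,
    SimConfig,
    run_chain,
    simulate,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic diallel dataset shared across tests (~450 records)."""
    return simulate(SimConfig(scale=0.05, seed=3))


@pytest.fixture(scope="session")
def short_chain(small_sim):
    """A short model-II fit of the small dataset (enough draws to summarize)."""
    spec = ModelSpec(model_id="II")
    cfg = McmcConfig(n_iter=1500, burn_in=500, thin=5, seed=11)
    return run_chain(small_sim.records, small_sim.pedigree, spec, cfg)


@pytest.fixture
def single_sow_pedigree():
    return Pedigree.from_tuples([("sow1", None, None, "E")])


@pytest.fixture
def two_record_toy(single_sow_pedigree):
    records = [
        FarrowingRecord("sow1", "EE", 1, "ys0", 10, 2),
        FarrowingRecord("sow1", "EE", 1, "ys0", 12, 1),
    ]
    return single_sow_pedigree, records


def random_pedigree(rng: np.random.Generator, n: int = 50) -> Pedigree:
    """Random valid pedigree: founders first, later individuals get random parents."""
    rows = []
    for i in range(n):
        if i < 10:
            rows.append((f"i{i}", None, None, "E"))
        else:
            s = int(rng.integers(0, i))
            d = int(rng.integers(0, i))
            rows.append((f"i{i}", f"i{s}", f"i{d}" if d != s else None, None))
    return Pedigree.from_tuples(rows)
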