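import numpy as np
import pytest

from compgrowth.growth_core import ComponentParams, CompositeParams
from compgrowth.presets import reference_composite


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_component():
    return ComponentParams(H=1.0, K=0.5, q=0.7, i=0.0)


@pytest.fixture
def reference_f():
    return reference_composite("F")


@pytest.fixture
def reference_m():
    return reference_composite("M")


def random_component(rng, i_max: float = 10.0) -> ComponentParams:
    """A random valid component with rates spanning realistic magnitudes."""
    return ComponentParams(
        H=float(np.exp(rng.uniform(-1.5, 4.0))),
        K=float(np.exp(rng.uniform(-2.0, 2.0))),
        q=float(rng.uniform(0.2, 0.8)),
        i=float(rng.uniform(0.0, i_max)),
    )


@pytest.fixture
def random_components(rng):
    return [random_component(rng) for _ in range(100)]


@pytest.fixture(scope="session")
def small_fit():
    """A tiny but real posterior fit shared across summary/intervention tests.

    Two groups of dense-design persons with a known focal offset, reduced
    chain lengths: big enough to exercise every downstream code path,
    small enough to keep the suite fast.
    """
    import numpy as np

    from compgrowth.inference import HierarchicalGrowthModel
    from compgrowth.synthetic_data import (
        PopulationConfig,
        ScheduleDesign,
        prepare_study,
        simulate_study,
    )

    off = np.zeros(19)
    off[6] = 0.2  # log_K2
    cfg = PopulationConfig(
        group_sizes={"reference": 6, "focal": 6},
        group_offsets={"focal": off},
        seed=404,
    )
    designs = {
        "reference": ScheduleDesign(kind="dense"),
        "focal": ScheduleDesign(kind="dense"),
    }
    records, pop = simulate_study(cfg, designs=designs, seed=404)
    ds = prepare_study(records, designs)
    est = HierarchicalGrowthModel(chains=2, warmup=150, draws=150, seed=7)
    est.fit(ds)
    return dict(estimator=est, posterior=est.posterior_, config=cfg, dataset=ds, pop=pop)
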