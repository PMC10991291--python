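import numpy as np
import pytest

import fedsurv as fs


def make_network(
    seed=3,
    nodes=(("a", 120), ("b", 150)),
    p=4,
    blocks=((2, 0.5), (2, 0.0)),
    true_beta=None,
    censoring=0.25,
):
    """Small synthetic federation used across the unit tests."""
    width = len(str(p))
    name = lambda j: f"radiomic_{j:0{width}d}"  # noqa: E731
    if true_beta is None:
        true_beta = {name(1): 0.5, name(3): -0.7}
    baselines = {"a": (1.1, 900.0), "b": (1.0, 600.0), "c": (1.2, 700.0)}
    cfg = fs.SimulationConfig(
        seed=seed,
        nodes=[tuple(x) for x in nodes],
        p=p,
        blocks=[tuple(b) for b in blocks],
        true_beta=true_beta,
        baseline={nid: baselines[nid] for nid, _n in nodes},
        censoring_rate_target=censoring,
    )
    return fs.generate_network(cfg)


@pytest.fixture(scope="session")
def toy_network():
    return make_network()


@pytest.fixture()
def toy_fed(toy_network):
    datasets, _truth = toy_network
    return fs.build_federation(datasets, fs.PipelineConfig(seed=5))


@pytest.fixture()
def toy_std(toy_fed, toy_network):
    datasets, _ = toy_network
    agg = fs.federated_moments(toy_fed)
    return fs.standardization_params(agg, datasets[0].feature_names)


def random_survival(rng, n, tie_free=False):
    """Arbitrary censored sample for metric tests."""
    if tie_free:
        times = rng.uniform(1.0, 20.0, n)
    else:
        times = rng.integers(1, 15, n).astype(float)
    events = rng.integers(0, 2, n)
    return times, events


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240403)
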