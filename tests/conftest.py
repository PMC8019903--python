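import numpy as np
import pytest

from melmp.goneg import term_freq, term_prob
from melmp.learners import LabeledDataset
from melmp.synthgen import SynthConfig, gen_go_dag


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def star_dag():
    """Root (anno 0) with two leaf children (anno 5 each): p(a)=p(b)=0.5."""
    from melmp.goneg import GoDag

    dag = GoDag(
        parents={"r": set(), "a": {"r"}, "b": {"r"}},
        namespace={"r": "BP", "a": "BP", "b": "BP"},
        anno={"r": 0, "a": 5, "b": 5},
    )
    stats = term_prob(term_freq(dag), dag)
    return dag, stats


@pytest.fixture(scope="session")
def planted_go():
    """Synthetic ontology with planted accept/reject proteins."""
    dag, annotations, expected = gen_go_dag(SynthConfig())
    stats = term_prob(term_freq(dag), dag)
    return dag, stats, annotations, expected


def make_toy_dataset(
    n_per_class: int = 10,
    dims: dict[str, int] | None = None,
    separation: float = 2.0,
    seed: int = 0,
) -> LabeledDataset:
    """Small random per-view matrices with a mean shift between classes."""
    dims = dims or {"Seq": 8, "PSSM": 10, "AA": 6, "SS": 12}
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    views = {}
    for view, d in dims.items():
        x = rng.normal(size=(n, d))
        x[labels == 1, : max(1, d // 2)] += separation
        views[view] = x
    ids = [f"P{i:03d}" for i in range(n)]
    return LabeledDataset(ids=ids, views=views, labels=labels)


@pytest.fixture
def toy_dataset():
    return make_toy_dataset()
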