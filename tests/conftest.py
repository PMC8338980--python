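import numpy as np
import pytest

from ginscreen.cohort import fit_quartile_coder
from ginscreen.graphs import EdgeMatrix, NodeVocabulary
from ginscreen.synthetic import default_outcome_spec, default_trait_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject cohort with enriched labels for fast pipeline tests."""
    spec = default_outcome_spec()
    spec.made_labeled_fraction = 0.3
    spec.prevalence = {"lifetime_SA": 0.05, "MaDE": 0.15, "acute_SI": 0.08}
    return generate_cohort(default_trait_spec(), spec, n=400, seed=11)


@pytest.fixture(scope="session")
def coded_small_table(small_cohort):
    coder = fit_quartile_coder(small_cohort.table, reverse={"RAS_T": True})
    return coder.transform(small_cohort.table)


@pytest.fixture()
def toy_vocab():
    names = ("a", "b", "c", "d", "e")
    return NodeVocabulary(names=names, kinds={n: "ordinal" for n in names})


@pytest.fixture()
def toy_edges(toy_vocab):
    rng = np.random.default_rng(3)
    W = rng.normal(0, 0.4, (5, 5))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return EdgeMatrix(names=toy_vocab.names, weights=W, threshold=0.0, method="pearson")


def one_hot_levels(levels: np.ndarray) -> np.ndarray:
    """(n, N) ordinal levels in 1..4 -> (n, N, 6) one-hot features."""
    n, N = levels.shape
    feats = np.zeros((n, N, 6))
    for j in range(N):
        feats[np.arange(n), j, levels[:, j] - 1] = 1.0
    return feats
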