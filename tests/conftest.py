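import numpy as np
import pytest

from survtopic.dlda import EncodedCorpus
from survtopic.io_preprocess import SurvivalLabels
from survtopic.simulate import SimulationConfig, generate_cohort


def make_planted_corpus(
    n_docs: int = 200,
    n_genes: int = 60,
    K: int = 3,
    doc_len: float = 80.0,
    seed: int = 0,
    alpha: float = 0.3,
):
    """Small direction-aware corpus with K disjoint planted topics.

    Returns (corpus, true_beta, theta). Topics put their mass on disjoint
    OVER-word blocks plus a little background so every word is reachable.
    """
    rng = np.random.default_rng(seed)
    V = 2 * n_genes
    block = n_genes // K
    beta = np.full((K, V), 0.02 / V)
    for k in range(K):
        words = np.arange(k * block, (k + 1) * block)
        w = rng.gamma(2.0, 1.0, size=block)
        beta[k, words] += 0.98 * w / w.sum()
    beta /= beta.sum(axis=1, keepdims=True)
    theta = rng.dirichlet(np.full(K, alpha), size=n_docs)
    lens = rng.poisson(doc_len, size=n_docs)
    counts = np.vstack(
        [rng.multinomial(lens[i], theta[i] @ beta) for i in range(n_docs)]
    )
    vocab = [f"OVER-g{j}" for j in range(n_genes)] + [f"UNDER-g{j}" for j in range(n_genes)]
    return EncodedCorpus("enc_b", vocab, counts), beta, theta


def make_survival_labels(n: int = 100, censor_frac: float = 0.3, seed: int = 0,
                         beta: np.ndarray | None = None, X: np.ndarray | None = None):
    """Exponential survival data, optionally with a linear log-hazard."""
    rng = np.random.default_rng(seed)
    eta = np.zeros(n) if beta is None else X @ beta
    T = rng.exponential(np.exp(-eta))
    if censor_frac > 0:
        C = rng.exponential(T.mean() / censor_frac * (1 - censor_frac), size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)
    return SurvivalLabels([f"p{i}" for i in range(n)], time, event)


@pytest.fixture(scope="session")
def planted_corpus():
    return make_planted_corpus()


@pytest.fixture(scope="session")
def small_cohort():
    """Small end-to-end cohort reused across pipeline tests."""
    cfg = SimulationConfig(n=150, p=60, K_true=2, doc_length_mean=60.0, seed=42)
    return generate_cohort(cfg)
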