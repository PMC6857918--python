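"""Discretized LDA: cancer-topic modelling of expression matrices.

The chain implemented here mirrors how NLP topic models treat documents:

1. standardized expression values are *discretized* into 21 integer bins
   {-10..10} (0 for the trivial band (-1, 1), ten equal-width bins on each
   non-trivial side, with per-gene bin edges fitted on training data);
2. the signed bins are encoded as non-negative "gene word" counts, either
   magnitude-only (Enc_A, one word per gene) or direction-aware (Enc_B,
   separate OVER-/UNDER-expression words per gene);
3. a latent Dirichlet allocation model is fitted to the resulting corpus by
   variational EM, giving K row-stochastic topic -> word distributions;
4. patients are represented by their inferred topic loadings, and the
   encoding and topic count are selected by internal cross-validation
   against held-out Cox concordance and held-out likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, polygamma, psi

from .io_preprocess import PreprocessState, SurvivalLabels

logger = logging.getLogger("survtopic")

__all__ = [
    "DiscretizedMatrix",
    "EncodedCorpus",
    "TopicBasis",
    "SelectionResult",
    "fit_discretizer",
    "discretize",
    "encode_counts",
    "fit_lda",
    "infer_loadings",
    "heldout_likelihood",
    "select_basis",
    "stratified_folds",
]

ENC_A = "enc_a"
ENC_B = "enc_b"
DEFAULT_K_GRID = tuple(range(5, 151, 5))


@dataclass
class DiscretizedMatrix:
    """Integer bin matrix b[i, j] in {-10..10}, patients x genes."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if np.any(np.abs(self.values) > 10):
            raise ValueError("bin indices must lie in {-10..10}")


@dataclass
class EncodedCorpus:
    """Non-negative gene-word counts, one document per patient."""

    encoding: str
    vocabulary: list[str]
    counts: np.ndarray  # n_docs x V, non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1] != len(self.vocabulary):
            raise ValueError("counts / vocabulary size mismatch")

    def subset(self, idx: np.ndarray) -> "EncodedCorpus":
        return EncodedCorpus(self.encoding, self.vocabulary, self.counts[np.asarray(idx)])


@dataclass
class TopicBasis:
    """Fitted topic model: K expected topic-word rows plus its priors.

    ``beta_bar`` is the K x V matrix of expected topic-word probabilities
    (each row sums to one); ``alpha`` is the symmetric document-topic prior
    after internal re-estimation. ``elbo_history`` tracks the variational
    bound across EM iterations (it is non-decreasing).
    """

    K: int
    beta_bar: np.ndarray
    alpha: float
    encoding: str
    vocabulary: list[str]
    elbo_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_bar = np.asarray(self.beta_bar, dtype=float)
        if self.beta_bar.shape != (self.K, len(self.vocabulary)):
            raise ValueError("beta_bar shape inconsistent with K and vocabulary")
        if np.any(self.beta_bar < 0):
            raise ValueError("beta_bar entries must be non-negative")
        if np.max(np.abs(self.beta_bar.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("beta_bar rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "beta_bar": self.beta_bar.tolist(),
            "alpha": float(self.alpha),
            "encoding": self.encoding,
            "vocabulary": list(self.vocabulary),
        }

    @classmethod
    def from_dict(cls, d) -> "TopicBasis":
        return cls(
            K=d["K"],
            beta_bar=np.asarray(d["beta_bar"], dtype=float),
            alpha=d["alpha"],
            encoding=d["encoding"],
            vocabulary=list(d["vocabulary"]),
        )


@dataclass
class SelectionResult:
    """Outcome of the encoding / topic-count search."""

    encoding: str  # t*
    K: int  # K*
    K_hat: int  # likelihood-optimal K
    mean_concordance: dict  # (t, K) -> mean held-out CI
    mean_likelihood: dict  # (t, K) -> mean held-out log-likelihood
    fold_concordance: dict
    fold_likelihood: dict


# ---------------------------------------------------------------------------
# discretization


def fit_discretizer(
    z: np.ndarray, gene_ids: Sequence[str], state: PreprocessState | None = None
) -> dict[str, list]:
    """Fit per-gene bin edges on training z values.

    For each gene the non-trivial positive values (z >= 1) define
    ``min_pos`` and width ``delta_pos = max - min``; symmetrically for the
    negative side (z <= -1) ``min_neg`` is the value *closest to* -1 and
    ``delta_neg`` the spread. A side with no non-trivial values is marked
    absent (None).
    """
    z = np.asarray(z, dtype=float)
    edges: dict[str, list] = {}
    for j, g in enumerate(gene_ids):
        col = z[:, j]
        pos = col[col >= 1.0]
        neg = col[col <= -1.0]
        if pos.size:
            mn, mx = float(pos.min()), float(pos.max())
            e_pos = [mn, mx - mn]
        else:
            e_pos = [None, None]
        if neg.size:
            mn, mx = float(neg.min()), float(neg.max())
            # min_neg = edge nearest the trivial band; delta is the spread
            e_neg = [mx, mx - mn]
        else:
            e_neg = [None, None]
        edges[str(g)] = e_pos + e_neg
    if state is not None:
        state.per_gene_bins = edges
    return edges


def _side_bin(vals: np.ndarray, lo: float, delta: float) -> np.ndarray:
    """Equal-width bin index in 1..10 for magnitudes measured from ``lo``."""
    if delta <= 0:
        return np.ones(vals.shape, dtype=int)
    idx = 1 + np.floor((vals - lo) / (delta / 10.0))
    return np.clip(idx, 1, 10).astype(int)


def discretize(
    z: np.ndarray, gene_ids: Sequence[str], edges: dict[str, list]
) -> DiscretizedMatrix:
    """Map z values to signed bins using fitted per-gene edges.

    Trivial values (|z| < 1) map to 0. Values beyond the fitted training
    range clamp to the extreme bin (+-10 above the max, +-1 below the min or
    on a side that was empty in training).
    """
    z = np.asarray(z, dtype=float)
    out = np.zeros(z.shape, dtype=int)
    for j, g in enumerate(gene_ids):
        g = str(g)
        if g not in edges:
            raise KeyError(f"gene {g!r} has no fitted bin edges")
        min_pos, delta_pos, min_neg, delta_neg = edges[g]
        col = z[:, j]
        pm = col >= 1.0
        nm = col <= -1.0
        if np.any(pm):
            if min_pos is None:
                out[pm, j] = 1  # side unseen in training: nearest bin
            else:
                out[pm, j] = _side_bin(col[pm], min_pos, delta_pos)
        if np.any(nm):
            if min_neg is None:
                out[nm, j] = -1
            else:
                out[nm, j] = -_side_bin(-col[nm], -min_neg, delta_neg)
    return DiscretizedMatrix(out, [str(g) for g in gene_ids])


def encode_counts(D: DiscretizedMatrix, encoding: str) -> EncodedCorpus:
    """Turn signed bins into non-negative gene-word counts.

    Enc_A uses one word per gene with count |b| (over- and under-expression
    are conflated). Enc_B uses two words per gene: bin +k becomes k counts
    of OVER-gene, bin -k becomes k counts of UNDER-gene.
    """
    b = D.values
    if encoding == ENC_A:
        vocab = list(D.gene_ids)
        counts = np.abs(b)
    elif encoding == ENC_B:
        vocab = [f"OVER-{g}" for g in D.gene_ids] + [f"UNDER-{g}" for g in D.gene_ids]
        counts = np.concatenate([np.clip(b, 0, None), np.clip(-b, 0, None)], axis=1)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return EncodedCorpus(encoding, vocab, counts.astype(int))


# ---------------------------------------------------------------------------
# variational LDA


def _dirichlet_expectation(arr: np.ndarray) -> np.ndarray:
    """E[log p] for rows of Dirichlet parameters."""
    return psi(arr) - psi(arr.sum(axis=-1, keepdims=True))


def init_topic_word(V: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Initial topic-word rows 1/V + delta, delta ~ U[0, 1/V^2], normalized.

    The near-uniform start with a small seeded jitter is what breaks the
    symmetry between topics.
    """
    beta = 1.0 / V + rng.uniform(0.0, 1.0 / V**2, size=(K, V))
    return beta / beta.sum(axis=1, keepdims=True)


def _estep(
    counts: np.ndarray,
    beta: np.ndarray,
    alpha: float,
    gamma: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch variational inference for all documents at once.

    phi_dvk is kept implicit (phi ∝ beta_kv * exp(psi(gamma_dk))); returns
    the document-topic Dirichlet parameters gamma and the per-word phi
    normalizers needed for sufficient statistics and the bound.
    """
    n, V = counts.shape
    K = beta.shape[0]
    if gamma is None:
        gamma = np.full((n, K), alpha + counts.sum(axis=1, keepdims=True) / K)
    phinorm = None
    for _ in range(max_iter):
        expElogtheta = np.exp(_dirichlet_expectation(gamma))
        phinorm = expElogtheta @ beta + 1e-300
        gamma_new = alpha + expElogtheta * ((counts / phinorm) @ beta.T)
        change = np.abs(gamma_new - gamma).mean(axis=1).max()
        gamma = gamma_new
        if change < tol:
            break
    expElogtheta = np.exp(_dirichlet_expectation(gamma))
    phinorm = expElogtheta @ beta + 1e-300
    return gamma, phinorm


def _elbo(counts: np.ndarray, gamma: np.ndarray, beta: np.ndarray, alpha: float) -> float:
    """Variational lower bound with point topic-word parameters beta.

    The word, z-entropy and z-prior terms collapse to
    sum_dv c_dv log(sum_k exp(Elogtheta_dk) beta_kv) at the optimal phi.
    """
    n = counts.shape[0]
    K = beta.shape[0]
    Elogtheta = _dirichlet_expectation(gamma)
    phinorm = np.exp(Elogtheta) @ beta + 1e-300
    score = float(np.sum(counts * np.log(phinorm)))
    score += float(np.sum((alpha - gamma) * Elogtheta))
    score += float(np.sum(gammaln(gamma)) - np.sum(gammaln(gamma.sum(axis=1))))
    score += n * float(gammaln(K * alpha) - K * gammaln(alpha))
    return score


def _alpha_objective(alpha: float, ss: float, n: int, K: int) -> float:
    return n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1.0) * ss


def _update_alpha(alpha: float, gamma: np.ndarray, max_iter: int = 20) -> float:
    """Safeguarded Newton step for the symmetric document-topic prior.

    Maximizes the alpha-dependent part of the bound; the step is halved
    until the bound does not decrease, so EM stays monotone.
    """
    n, K = gamma.shape
    ss = float(np.sum(_dirichlet_expectation(gamma)))
    cur = _alpha_objective(alpha, ss, n, K)
    for _ in range(max_iter):
        g = n * K * (psi(K * alpha) - psi(alpha)) + ss
        h = n * K * (K * polygamma(1, K * alpha) - polygamma(1, alpha))
        if h == 0:
            break
        step = g / h
        new = alpha - step
        tries = 0
        while (not np.isfinite(new) or new <= 1e-8 or
               _alpha_objective(new, ss, n, K) < cur) and tries < 30:
            step /= 2.0
            new = alpha - step
            tries += 1
        if tries >= 30 or abs(new - alpha) < 1e-10:
            break
        alpha = float(new)
        cur = _alpha_objective(alpha, ss, n, K)
    return float(min(max(alpha, 1e-8), 1e3))


def _fit_lda_once(
    counts: np.ndarray,
    K: int,
    alpha: float,
    seed: int,
    max_em_iter: int,
    em_tol: float,
    estimate_alpha: bool,
    alpha_burnin: int,
    estep_tol: float = 1e-6,
    estep_max_iter: int = 100,
) -> tuple[np.ndarray, float, list[float]]:
    n, V = counts.shape
    rng = np.random.default_rng(seed)
    beta = init_topic_word(V, K, rng)
    gamma = None
    history: list[float] = []
    for it in range(max_em_iter):
        gamma, phinorm = _estep(counts, beta, alpha, gamma=gamma,
                                max_iter=estep_max_iter, tol=estep_tol)
        expElogtheta = np.exp(_dirichlet_expectation(gamma))
        sstats = ((counts / phinorm).T @ expElogtheta).T * beta
        beta = sstats + 1e-12  # floor keeps held-out words finite
        beta = beta / beta.sum(axis=1, keepdims=True)
        # alpha is held fixed during a burn-in: estimating it on the
        # near-symmetric early iterations is unstable
        if estimate_alpha and it >= alpha_burnin:
            alpha = _update_alpha(alpha, gamma)
        bound = _elbo(counts, gamma, beta, alpha)
        history.append(bound)
        if it > alpha_burnin:
            prev = history[-2]
            if abs(bound - prev) / (abs(prev) + 1e-12) < em_tol:
                break
    return beta, alpha, history


def fit_lda(
    corpus: EncodedCorpus,
    K: int,
    alpha: float = 0.1,
    seed: int | None = 0,
    max_em_iter: int = 500,
    em_tol: float = 1e-7,
    estimate_alpha: bool = True,
    alpha_burnin: int = 25,
    n_restarts: int = 4,
    estep_tol: float = 1e-6,
    estep_max_iter: int = 100,
) -> TopicBasis:
    """Fit LDA by batch variational EM (Blei-style).

    Topic-word rows are point parameters initialized at 1/V plus a small
    seeded uniform jitter (which breaks the initial symmetry between
    topics); the symmetric document-topic prior starts at ``alpha`` and is
    re-estimated during EM after a burn-in. EM is restarted
    ``n_restarts`` times from different jitters and the solution with the
    best variational bound is kept (the bound reliably separates mixed-
    topic local optima from the global one). Returns the topic-word matrix
    with rows normalized to probability vectors.
    """
    counts = np.asarray(corpus.counts, dtype=float)
    n, V = counts.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n == 0 or counts.sum() == 0:
        raise ValueError("corpus is empty")
    if K > n:
        logger.warning("K=%d exceeds the number of documents (%d)", K, n)
    seeds = np.random.SeedSequence(seed if seed is not None else 0).generate_state(
        max(1, n_restarts)
    ) % (2**31)
    best = None
    for s in seeds:
        beta, a, history = _fit_lda_once(
            counts, K, alpha, int(s), max_em_iter, em_tol, estimate_alpha,
            alpha_burnin, estep_tol, estep_max_iter,
        )
        if best is None or history[-1] > best[2][-1]:
            best = (beta, a, history)
    beta, a, history = best
    return TopicBasis(
        K=K,
        beta_bar=beta,
        alpha=float(a),
        encoding=corpus.encoding,
        vocabulary=list(corpus.vocabulary),
        elbo_history=history,
    )


def infer_loadings(
    counts: np.ndarray, basis: TopicBasis, normalized: bool = True
) -> np.ndarray:
    """Variational posterior topic loadings for one or more documents.

    With ``normalized=True`` (the downstream default) rows are the posterior
    mean topic proportions gamma / sum(gamma); otherwise the raw Dirichlet
    parameters gamma are returned. An empty document yields the prior
    (uniform proportions under the symmetric alpha).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[1] != len(basis.vocabulary):
        raise ValueError(
            f"document has {counts.shape[1]} words, basis vocabulary has "
            f"{len(basis.vocabulary)}"
        )
    gamma, _ = _estep(counts, basis.beta_bar, basis.alpha)
    if normalized:
        return gamma / gamma.sum(axis=1, keepdims=True)
    return gamma


def heldout_likelihood(corpus: EncodedCorpus, basis: TopicBasis) -> float:
    """Average per-document predictive log-likelihood under the basis.

    Each document is scored as sum_v c_v log(theta_bar^T beta_bar[:, v])
    with theta_bar the inferred posterior-mean topic proportions; an empty
    document scores 0 (empty product).
    """
    counts = np.asarray(corpus.counts, dtype=float)
    if counts.shape[0] == 0:
        return 0.0
    theta = infer_loadings(counts, basis, normalized=True)
    word_prob = theta @ basis.beta_bar + 1e-300
    ll = np.sum(counts * np.log(word_prob), axis=1)
    return float(ll.mean())


# ---------------------------------------------------------------------------
# encoding / K selection (internal cross-validation)


def stratified_folds(
    event: np.ndarray, n_folds: int, seed: int | None
) -> list[np.ndarray]:
    """Event-status-stratified fold assignment; sizes differ by at most 1."""
    event = np.asarray(event, dtype=int)
    rng = np.random.default_rng(seed)
    assign = np.empty(len(event), dtype=int)
    start = 0
    for grp in (np.where(event == 1)[0], np.where(event == 0)[0]):
        grp = grp[rng.permutation(len(grp))]
        assign[grp] = (start + np.arange(len(grp))) % n_folds
        start += len(grp)
    return [np.where(assign == f)[0] for f in range(n_folds)]


def select_basis(
    z: np.ndarray,
    gene_ids: Sequence[str],
    clinical: np.ndarray,
    labels: SurvivalLabels,
    K_grid: Sequence[int] = DEFAULT_K_GRID,
    encodings: Sequence[str] = (ENC_A, ENC_B),
    n_folds: int = 5,
    seed: int | None = 0,
    alpha: float = 0.1,
    cox_ridge: float = 0.1,
    edges: dict[str, list] | None = None,
    lda_restarts: int = 2,
    lda_max_iter: int = 300,
    lda_tol: float = 1e-6,
) -> tuple[SelectionResult, TopicBasis]:
    """Search for the best encoding t* and topic count K* by internal CV.

    The z matrix is discretized once (edges fitted here unless supplied),
    encoded under each candidate encoding, and then, for every
    (encoding, K, fold): LDA is fitted on the in-fold 4/5, the held-out
    fifth is projected, a Cox model on [loadings, clinical] is fitted and
    the held-out concordance and held-out likelihood recorded. The encoding
    with the best mean concordance wins; K_hat is the likelihood-optimal K
    for that encoding, and the candidate set is every K <= K_hat whose mean
    likelihood is within one fold-SD of K_hat's. Among candidates, K* is
    the *smallest* K whose mean concordance is essentially the best --
    within one fold-SD of the best candidate's (held-out likelihood keeps
    creeping up with superfluous topics, while concordance plateaus at the
    true dimensionality, so an exact argmax would resolve what is really a
    tie by noise). The final basis is refitted on all patients at (t*, K*)
    with the fully polished EM settings.
    """
    from .survival_models import fit_cox
    from .evaluation import concordance

    clinical = np.asarray(clinical, dtype=float)
    if edges is None:
        edges = fit_discretizer(z, gene_ids)
    D = discretize(z, gene_ids, edges)
    corpus_by_encoding = {enc: encode_counts(D, enc) for enc in encodings}
    folds = stratified_folds(labels.event, n_folds, seed)
    all_idx = np.arange(len(labels.time))
    c_tab: dict[tuple[str, int], list[float]] = {}
    l_tab: dict[tuple[str, int], list[float]] = {}
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    fit_seeds = ss.generate_state(len(corpus_by_encoding) * len(K_grid) * n_folds) % (2**31)
    si = 0
    for enc, corpus in corpus_by_encoding.items():
        for K in K_grid:
            key = (enc, int(K))
            c_tab[key] = []
            l_tab[key] = []
            for f, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(all_idx, test_idx)
                basis = fit_lda(corpus.subset(train_idx), K, alpha=alpha,
                                seed=int(fit_seeds[si]), n_restarts=lda_restarts,
                                max_em_iter=lda_max_iter, em_tol=lda_tol,
                                estep_tol=1e-4, estep_max_iter=30)
                si += 1
                theta_tr = infer_loadings(corpus.counts[train_idx], basis)
                theta_te = infer_loadings(corpus.counts[test_idx], basis)
                Xtr = np.column_stack([theta_tr, clinical[train_idx]])
                Xte = np.column_stack([theta_te, clinical[test_idx]])
                model = fit_cox(Xtr, labels.subset(train_idx), lam=cox_ridge)
                risk = Xte @ model.coef
                try:
                    ci = concordance(risk, labels.subset(test_idx))
                    c_tab[key].append(float(ci))
                except ValueError:
                    logger.warning("fold %d has no comparable pairs; excluded", f)
                l_tab[key].append(
                    heldout_likelihood(corpus.subset(test_idx), basis)
                )
    c_bar = {k: float(np.mean(v)) for k, v in c_tab.items() if v}
    l_bar = {k: float(np.mean(v)) for k, v in l_tab.items()}
    # t*: encoding of the best mean concordance over the whole grid
    t_star = max(c_bar, key=lambda k: c_bar[k])[0]
    ks = sorted({k[1] for k in l_bar if k[0] == t_star})
    K_hat = max(ks, key=lambda K: (l_bar[(t_star, K)], -K))
    sd_hat = float(np.std(l_tab[(t_star, K_hat)], ddof=1)) if len(
        l_tab[(t_star, K_hat)]) > 1 else 0.0
    candidates = [
        K for K in ks
        if K <= K_hat and l_bar[(t_star, K)] >= l_bar[(t_star, K_hat)] - sd_hat
        and (t_star, K) in c_bar
    ]
    if not candidates:
        candidates = [K_hat]
    best_c = max(c_bar[(t_star, K)] for K in candidates)
    K_best_c = min(K for K in candidates if c_bar[(t_star, K)] == best_c)
    c_folds = c_tab[(t_star, K_best_c)]
    sd_c = float(np.std(c_folds, ddof=1)) if len(c_folds) > 1 else 0.0
    K_star = min(K for K in candidates if c_bar[(t_star, K)] >= best_c - sd_c)
    logger.info("selected encoding=%s K*=%d (K_hat=%d)", t_star, K_star, K_hat)
    final_seed = int(ss.generate_state(1)[0] % (2**31))
    final = fit_lda(corpus_by_encoding[t_star], K_star, alpha=alpha, seed=final_seed)
    result = SelectionResult(
        encoding=t_star,
        K=int(K_star),
        K_hat=int(K_hat),
        mean_concordance=c_bar,
        mean_likelihood=l_bar,
        fold_concordance=c_tab,
        fold_likelihood=l_tab,
    )
    return result, final
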