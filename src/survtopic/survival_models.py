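"""Survival learners: Cox partial likelihood (plain and ridge) and MTLR.

All three learners consume an arbitrary feature matrix (topic loadings,
principal-component scores, clinical covariates, or any mix) with
right-censored labels, and can emit both a per-patient survival curve and a
scalar risk score.

Cox maximizes the log partial likelihood (Breslow handling of tied event
times) optionally minus a ridge penalty; individual curves come from the
Kalbfleisch-Prentice baseline survival estimator, S(t|x) = S0(t)^exp(x'w).

MTLR (multi-task logistic regression) places m time points on the quantiles
of the observed times (m = floor(sqrt(n)) by default) and learns one
logistic threshold model per time point, jointly, with an L2 penalty on the
non-intercept weights. The model yields a full probability mass function
over the m+1 time intervals for each patient; censored patients contribute
the exact marginal likelihood over all death intervals consistent with
survival past their censoring time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

from .io_preprocess import SurvivalLabels

logger = logging.getLogger("survtopic")

__all__ = [
    "SurvivalCurve",
    "CoxModel",
    "MTLRModel",
    "ConvergenceError",
    "cox_partial_loglik",
    "fit_cox",
    "cox_survival_curve",
    "build_time_grid",
    "mtlr_objective",
    "mtlr_gradient",
    "fit_mtlr",
    "mtlr_survival_curve",
    "risk_from_curve",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SurvivalCurve:
    """Non-increasing survival probabilities starting at P(D >= 0) = 1.

    Between grid points the curve is evaluated by linear interpolation;
    beyond the last point it is held at its final value.
    """

    times: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.times.shape != self.probs.shape or self.times.ndim != 1:
            raise ValueError("times and probs must be matching 1-D arrays")
        if self.times[0] != 0.0 or abs(self.probs[0] - 1.0) > 1e-9:
            raise ValueError("curve must start at (t=0, P=1)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.diff(self.probs) > 1e-9):
            raise ValueError("survival curve must be non-increasing")

    def probability(self, t) -> np.ndarray | float:
        """P(D >= t), linearly interpolated; held flat beyond the grid."""
        return np.interp(t, self.times, self.probs)


# ---------------------------------------------------------------------------
# Cox


@dataclass
class CoxModel:
    coef: np.ndarray
    lam: float
    baseline_times: np.ndarray | None = None
    baseline_surv: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def risk_score(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor x'w (log relative hazard)."""
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "lam": float(self.lam),
            "baseline_times": None if self.baseline_times is None
            else self.baseline_times.tolist(),
            "baseline_surv": None if self.baseline_surv is None
            else self.baseline_surv.tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d) -> "CoxModel":
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            lam=d["lam"],
            baseline_times=None if d["baseline_times"] is None
            else np.asarray(d["baseline_times"], dtype=float),
            baseline_surv=None if d["baseline_surv"] is None
            else np.asarray(d["baseline_surv"], dtype=float),
            feature_names=list(d["feature_names"]),
        )


def _risk_set_stats(W, X, time, event, need_hess: bool):
    """Log partial likelihood, gradient and (optionally) Hessian.

    Risk sets use the convention y_k >= y_i (a patient is at risk at their
    own event time); tied event times share the full risk set (Breslow).
    Computed with reverse-cumulative sums over time-sorted patients.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending time
    Xs, ts, ds = X[order], time[order], event[order]
    eta = Xs @ W
    m = eta.max() if n else 0.0
    w = np.exp(eta - m)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2 = None
    if need_hess:
        S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    # risk set of patient i (sorted desc) = indices 0..j where j is the last
    # position with the same time as i (ties share the set)
    last_tie = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        last_tie[i:j + 1] = j
        i = j + 1
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if need_hess else None
    ev = np.where(ds == 1)[0]
    for i in ev:
        j = last_tie[i]
        s0 = S0[j]
        mu = S1[j] / s0
        ll += eta[i] - (np.log(s0) + m)
        grad += Xs[i] - mu
        if need_hess:
            hess -= S2[j] / s0 - np.outer(mu, mu)
    return ll, grad, hess


def cox_partial_loglik(W, X, labels: SurvivalLabels) -> float:
    """Log partial likelihood: sum over events of eta_i - log sum_{R(y_i)} e^eta."""
    ll, _, _ = _risk_set_stats(W, X, labels.time, labels.event, need_hess=False)
    return float(ll)


def fit_cox(
    X,
    labels: SurvivalLabels,
    lam: float = 0.0,
    feature_names: list[str] | None = None,
    fit_baseline: bool = True,
    max_iter: int = 100,
    gtol: float = 1e-8,
) -> CoxModel:
    """Maximize the (ridge-penalized) log partial likelihood by Newton steps.

    The objective is log PL(W) - lam * ||W||^2. With lam = 0 and separable
    data the MLE diverges; this is detected and reported with advice to use
    a ridge penalty.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if lam < 0:
        raise ValueError("ridge weight must be >= 0")
    if lam == 0 and labels.event.sum() == 0:
        raise ValueError("all patients censored; need lam > 0")
    W = np.zeros(p)
    time, event = labels.time, labels.event
    for _ in range(max_iter):
        ll, grad, hess = _risk_set_stats(W, X, time, event, need_hess=True)
        grad = grad - 2.0 * lam * W
        hess = hess - 2.0 * lam * np.eye(p)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < gtol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = grad  # fall back to gradient ascent direction
        # backtracking on the penalized objective
        obj = ll - lam * float(W @ W)
        t_step = 1.0
        for _ in range(40):
            Wn = W + t_step * step
            lln, _, _ = _risk_set_stats(Wn, X, time, event, need_hess=False)
            if lln - lam * float(Wn @ Wn) > obj - 1e-12:
                break
            t_step /= 2.0
        W = W + t_step * step
        if lam == 0 and np.linalg.norm(W) > 1e3:
            raise ConvergenceError(
                "Cox fit diverging (likely separable data); refit with lam > 0"
            )
    else:
        if gnorm > 1e-4:
            if lam == 0:
                raise ConvergenceError(
                    f"Cox fit did not converge (|grad|={gnorm:.2e}); try lam > 0"
                )
            logger.warning("Cox fit stopped at |grad|=%.2e", gnorm)
    if lam == 0:
        eta = X @ W
        if eta.size and float(eta.max() - eta.min()) > 100.0:
            # the partial likelihood is monotone (separable data): the
            # "optimum" found is just where the gradient underflows
            raise ConvergenceError(
                "Cox fit diverged: a covariate perfectly separates the event "
                "order (monotone likelihood); refit with lam > 0"
            )
    model = CoxModel(coef=W, lam=float(lam),
                     feature_names=feature_names or [f"x{j}" for j in range(p)])
    if fit_baseline:
        _fit_kp_baseline(model, X, labels)
    return model


def _fit_kp_baseline(model: CoxModel, X: np.ndarray, labels: SurvivalLabels) -> None:
    """Kalbfleisch-Prentice baseline survival on the training data.

    At each distinct event time the discrete survival factor alpha_j solves
    sum_{i in D_j} e_i / (1 - alpha_j^{e_i}) = sum_{k in R_j} e_k with
    e = exp(x'w); with w = 0 this reduces to the Kaplan-Meier factor
    1 - d_j / n_j.
    """
    eta = np.asarray(X, dtype=float) @ model.coef
    e = np.exp(eta - eta.mean())  # centered for numerical stability
    scale = np.exp(eta.mean())
    time, event = labels.time, labels.event
    ev_times = np.unique(time[event == 1])
    alphas = []
    for t in ev_times:
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        s_risk = float(e[at_risk].sum())
        e_d = e[dead]
        if len(e_d) == 1 and abs(e_d[0] - s_risk) < 1e-12:
            a = 0.0
        elif len(e_d) == 1:
            a = float((1.0 - e_d[0] / s_risk) ** (1.0 / e_d[0]))
        else:
            def f(a):
                return float(np.sum(e_d / (1.0 - a ** e_d)) - s_risk)
            lo, hi = 1e-12, 1.0 - 1e-12
            if f(hi) > 0:  # everyone at risk dies; survival drops to 0
                a = 0.0
            else:
                a = brentq(f, lo, hi, xtol=1e-12)
        alphas.append(a)
    # alpha solved on the centered scale: S0(t) = prod alpha_j^(1/scale_adj)
    # -- the KP equations above used e centered by mean(eta); undo so the
    # stored baseline corresponds to x'w = 0 exactly.
    s0 = np.cumprod(np.power(np.asarray(alphas), 1.0 / scale))
    model.baseline_times = ev_times
    model.baseline_surv = s0


def cox_survival_curve(model: CoxModel, x) -> SurvivalCurve:
    """Individual curve S(t|x) = S0(t)^exp(x'w) from the KP baseline."""
    if model.baseline_times is None:
        raise ValueError("model has no fitted baseline")
    hr = float(np.exp(np.asarray(x, dtype=float) @ model.coef))
    ev_times = model.baseline_times.copy()
    if len(ev_times) and ev_times[0] == 0.0:
        # a death recorded at day 0: nudge so the curve still starts at 1
        ev_times[0] = ev_times[1] / 2.0 if len(ev_times) > 1 else 0.5
    probs = np.concatenate([[1.0], model.baseline_surv**hr])
    times = np.concatenate([[0.0], ev_times])
    return SurvivalCurve(times, np.clip(probs, 0.0, 1.0))


# ---------------------------------------------------------------------------
# MTLR


@dataclass
class MTLRModel:
    grid: np.ndarray  # t_1 < ... < t_m (t_0 = 0 implicit)
    W: np.ndarray  # m x (r+1); last column is the intercept b
    C: float
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape[0] != len(self.grid):
            raise ValueError("weight rows must match the time grid")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("weights must be finite")

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "W": self.W.tolist(),
            "C": float(self.C),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d) -> "MTLRModel":
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            W=np.asarray(d["W"], dtype=float),
            C=d["C"],
            feature_names=list(d["feature_names"]),
        )


def build_time_grid(labels: SurvivalLabels, m: int | None = None) -> np.ndarray:
    """m evenly spaced quantiles of the observed (event or censor) times.

    m defaults to floor(sqrt(n)). Quantile levels are i/(m+1), i = 1..m;
    duplicates and non-positive points are dropped (with a warning if the
    grid shrinks).
    """
    times = np.asarray(labels.time, dtype=float)
    n = len(times)
    if m is None:
        m = int(np.floor(np.sqrt(n)))
    m = max(1, m)
    qs = np.quantile(times, [(i + 1) / (m + 1) for i in range(m)])
    grid = np.unique(qs)
    grid = grid[grid > 0]
    if len(grid) < m:
        logger.warning("time grid shrank from %d to %d points", m, len(grid))
    if len(grid) == 0:
        raise ValueError("no positive time points available for the grid")
    return grid


def _interval_scores(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """F[i, k] = f_W(x_i, k) = sum_{l > k} (w_l' x_i + b_l), k = 0..m."""
    m = W.shape[0]
    s = X @ W[:, :-1].T + W[:, -1]  # n x m
    cs = np.cumsum(s[:, ::-1], axis=1)[:, ::-1]  # cs[:, j] = sum_{l >= j+1}
    return np.concatenate([cs, np.zeros((X.shape[0], 1))], axis=1)


def _death_interval(grid: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Index k of the interval [t_k, t_{k+1}) containing death time d."""
    return np.searchsorted(grid, d, side="left")


def _censor_first_interval(grid: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Smallest interval index consistent with survival past censor time c."""
    return np.searchsorted(grid, c, side="right")


def _objective_core(W, X, labels, grid, C):
    m = len(grid)
    F = _interval_scores(W, X)  # n x (m+1)
    logZ = logsumexp(F, axis=1)
    event = labels.event.astype(bool)
    data = np.empty(len(labels.time))
    k_death = _death_interval(grid, labels.time[event])
    data[event] = F[event, k_death]
    cens_idx = np.where(~event)[0]
    kappa = _censor_first_interval(grid, labels.time[cens_idx])
    for pos, (i, k0) in enumerate(zip(cens_idx, kappa)):
        data[i] = logsumexp(F[i, k0:])
    penalty = 0.5 * C * float(np.sum(W[:, :-1] ** 2))
    obj = penalty - float(np.sum(data - logZ))
    return obj, F, logZ, k_death, cens_idx, kappa


def mtlr_objective(W, X, labels: SurvivalLabels, grid, C: float) -> float:
    """Regularized negative log-likelihood of the MTLR model.

    Uncensored patients contribute the exact interval term; a patient
    censored at c contributes the log of the summed scores of every death
    interval consistent with death after c (full marginalization over the
    label vectors), normalized by the same partition function. The penalty
    (C/2) sum_j ||w_j||^2 excludes the intercepts.
    """
    W = np.asarray(W, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid = np.asarray(grid, dtype=float)
    obj, *_ = _objective_core(W, X, labels, grid, C)
    return obj


def _value_and_grad(W, X, labels: SurvivalLabels, grid, C: float):
    n = X.shape[0]
    m = len(grid)
    obj, F, logZ, k_death, cens_idx, kappa = _objective_core(W, X, labels, grid, C)
    P = np.exp(F - logZ[:, None])  # n x (m+1)
    # d(-loglik)/d s_l = P(k < l) - E_data[I(k < l)], l = 1..m
    cumP = np.cumsum(P, axis=1)[:, :m]
    cum_data = np.zeros((n, m))
    event = labels.event.astype(bool)
    ev_rows = np.where(event)[0]
    # uncensored: I[k_i < l] for l = 1..m  <=> column index l-1 >= k_i
    for i, k in zip(ev_rows, k_death):
        cum_data[i, k:] = 1.0
    for i, k0 in zip(cens_idx, kappa):
        q = np.exp(F[i, k0:] - logsumexp(F[i, k0:]))
        cq = np.cumsum(q)
        # Q(k < l) = sum of q over consistent k < l
        full = np.zeros(m + 1)
        full[k0:] = cq
        cum_data[i] = full[:m]
    G_s = cumP - cum_data  # n x m
    grad_w = G_s.T @ X + C * W[:, :-1]
    grad_b = G_s.sum(axis=0)
    return obj, np.column_stack([grad_w, grad_b])


def mtlr_gradient(W, X, labels: SurvivalLabels, grid, C: float) -> np.ndarray:
    """Analytic gradient of :func:`mtlr_objective` with respect to W."""
    W = np.asarray(W, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid = np.asarray(grid, dtype=float)
    _, g = _value_and_grad(W, X, labels, grid, C)
    return g


def _fit_mtlr_single(X, labels, grid, C, maxiter=2000, x0=None) -> np.ndarray:
    n, r = X.shape
    m = len(grid)

    def fun(flat):
        W = flat.reshape(m, r + 1)
        f, g = _value_and_grad(W, X, labels, grid, C)
        return f, g.ravel()

    res = minimize(
        fun,
        np.zeros(m * (r + 1)) if x0 is None else np.asarray(x0, dtype=float).ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        logger.warning(
            "MTLR fit stopped early (%s); |grad|=%.2e", res.message,
            float(np.linalg.norm(res.jac)),
        )
    return res.x.reshape(m, r + 1)


def fit_mtlr(
    X,
    labels: SurvivalLabels,
    C_grid=(0.01, 0.1, 1.0, 10.0),
    grid=None,
    seed: int | None = 0,
    n_folds: int = 3,
    feature_names: list[str] | None = None,
) -> MTLRModel:
    """Fit MTLR from W = 0 by quasi-Newton; C chosen by internal CV.

    The convex objective makes the optimum independent of the start; the
    seed only controls the fold assignment of the C-selection CV (held-out
    concordance of the curve-derived risk scores; ties prefer the larger,
    more regularized C).
    """
    from .dlda import stratified_folds
    from .evaluation import concordance

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if grid is None:
        grid = build_time_grid(labels)
    grid = np.asarray(grid, dtype=float)
    C_grid = list(C_grid)
    if not C_grid:
        raise ValueError("C grid must be nonempty")
    best_C = C_grid[0]
    if len(C_grid) > 1:
        folds = stratified_folds(labels.event, n_folds, seed)
        all_idx = np.arange(len(labels.time))
        scores = {}
        for C in C_grid:
            cis = []
            for test_idx in folds:
                train_idx = np.setdiff1d(all_idx, test_idx)
                Wf = _fit_mtlr_single(X[train_idx], labels.subset(train_idx), grid, C)
                mod = MTLRModel(grid=grid, W=Wf, C=C)
                risks = np.array(
                    [risk_from_curve(mtlr_survival_curve(mod, x)) for x in X[test_idx]]
                )
                try:
                    cis.append(concordance(risks, labels.subset(test_idx)))
                except ValueError:
                    pass
            scores[C] = float(np.mean(cis)) if cis else -np.inf
        best = max(scores.values())
        best_C = max(C for C in C_grid if scores[C] == best)
        logger.info("MTLR C selected by CV: %g (CI=%.4f)", best_C, best)
    W = _fit_mtlr_single(X, labels, grid, best_C)
    return MTLRModel(grid=grid, W=W, C=float(best_C),
                     feature_names=feature_names or [f"x{j}" for j in range(X.shape[1])])


def mtlr_survival_curve(model: MTLRModel, x) -> SurvivalCurve:
    """Survival curve from the interval PMF: P(D >= t_j) = sum_{k >= j} p_k."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    F = _interval_scores(model.W, x)[0]
    p = np.exp(F - logsumexp(F))
    # S(t_j) = sum_{k >= j} p_k for j = 0..m (reverse cumulative sum)
    surv = np.cumsum(p[::-1])[::-1]
    times = np.concatenate([[0.0], model.grid])
    probs = np.clip(surv, 0.0, 1.0)
    probs[0] = 1.0
    probs = np.minimum.accumulate(probs)
    return SurvivalCurve(times, probs)


def risk_from_curve(curve: SurvivalCurve) -> float:
    """Risk score = negative expected survival time (area under the curve
    up to its last grid point, trapezoidal rule)."""
    return float(-np.trapezoid(curve.probs, curve.times))
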