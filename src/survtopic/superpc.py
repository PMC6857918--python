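"""Supervised principal components (SuperPC+).

PCA is run on the full filtered, globally standardized expression matrix
(centering only; the data are already on one global scale), and components
are then screened by the p-value of a univariate Cox fit of each component
score against survival. The p-value threshold eta is chosen by internal
cross-validation on held-out concordance of a Cox model over the selected
components. This differs from classic SuperPC, which screens individual
genes before the PCA; screening whole components avoids selecting many
mutually correlated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.decomposition import PCA

from .io_preprocess import SurvivalLabels

logger = logging.getLogger("survtopic")

__all__ = ["PCBasis", "fit_superpc", "project_superpc"]

DEFAULT_ETA_GRID = (5e-4, 5e-3, 5e-2)


@dataclass
class PCBasis:
    components: np.ndarray  # k x p orthonormal directions
    mean: np.ndarray  # centering vector over genes
    pvalues: np.ndarray  # per-component univariate Cox Wald p-values
    selected: np.ndarray  # indices of retained components
    eta: float
    gene_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "components": self.components.tolist(),
            "mean": self.mean.tolist(),
            "pvalues": self.pvalues.tolist(),
            "selected": self.selected.tolist(),
            "eta": float(self.eta),
            "gene_ids": list(self.gene_ids),
        }

    @classmethod
    def from_dict(cls, d) -> "PCBasis":
        return cls(
            components=np.asarray(d["components"], dtype=float),
            mean=np.asarray(d["mean"], dtype=float),
            pvalues=np.asarray(d["pvalues"], dtype=float),
            selected=np.asarray(d["selected"], dtype=int),
            eta=d["eta"],
            gene_ids=list(d["gene_ids"]),
        )


def _univariate_cox_pvalue(score: np.ndarray, labels: SurvivalLabels) -> float:
    """Wald p-value of a one-covariate Cox fit (asymptotically equivalent
    to the score test)."""
    from .survival_models import _risk_set_stats, fit_cox, ConvergenceError

    x = (score - score.mean())
    sd = x.std()
    if sd == 0:
        return np.nan
    x = (x / sd)[:, None]
    try:
        model = fit_cox(x, labels, lam=0.0, fit_baseline=False)
    except (ConvergenceError, ValueError):
        return np.nan
    _, _, hess = _risk_set_stats(model.coef, x, labels.time, labels.event, True)
    info = -hess[0, 0]
    if info <= 0:
        return np.nan
    z = model.coef[0] * np.sqrt(info)
    return float(2.0 * norm.sf(abs(z)))


def fit_superpc(
    z: np.ndarray,
    labels: SurvivalLabels,
    eta_grid=DEFAULT_ETA_GRID,
    n_folds: int = 5,
    seed: int | None = 0,
    gene_ids: list[str] | None = None,
) -> PCBasis:
    """Fit the PCA basis and choose the Cox p-value threshold eta by CV.

    If no component passes any candidate eta, the single best-p component
    is retained as a fallback (logged at WARNING).
    """
    from .dlda import stratified_folds
    from .evaluation import concordance
    from .survival_models import fit_cox

    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if n < 2:
        raise ValueError("need at least 2 patients")
    pca = PCA(n_components=min(n, p), svd_solver="full")
    scores = pca.fit_transform(z)
    # drop numerically null components
    sv = pca.singular_values_
    keep = sv > sv[0] * max(n, p) * np.finfo(float).eps
    components = pca.components_[keep]
    scores = scores[:, keep]
    pvals = np.array(
        [_univariate_cox_pvalue(scores[:, j], labels) for j in range(scores.shape[1])]
    )
    folds = stratified_folds(labels.event, n_folds, seed)
    all_idx = np.arange(n)
    best_eta, best_ci = None, -np.inf
    for eta in sorted(eta_grid):
        sel = np.where(pvals < eta)[0]
        if sel.size == 0:
            continue
        cis = []
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            try:
                model = fit_cox(scores[train_idx][:, sel],
                                labels.subset(train_idx), lam=1e-6,
                                fit_baseline=False)
                risk = scores[test_idx][:, sel] @ model.coef
                cis.append(concordance(risk, labels.subset(test_idx)))
            except (ValueError, RuntimeError):
                continue
        if cis and np.mean(cis) > best_ci:
            best_ci = float(np.mean(cis))
            best_eta = float(eta)
    if best_eta is None:
        logger.warning("no component passed any eta; falling back to best-p component")
        finite = np.where(np.isfinite(pvals))[0]
        if finite.size == 0:
            raise ValueError("no component has a defined Cox p-value")
        j = finite[np.argmin(pvals[finite])]
        selected = np.array([j])
        best_eta = float(np.nextafter(pvals[j], np.inf))
    else:
        selected = np.where(pvals < best_eta)[0]
        logger.info("SuperPC+: eta=%g retains %d components (CI=%.4f)",
                    best_eta, selected.size, best_ci)
    return PCBasis(
        components=components,
        mean=pca.mean_,
        pvalues=pvals,
        selected=selected,
        eta=best_eta,
        gene_ids=gene_ids or [],
    )


def project_superpc(z: np.ndarray, basis: PCBasis) -> np.ndarray:
    """Center and project onto the selected components."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != basis.components.shape[1]:
        raise ValueError(
            f"gene set mismatch: {z.shape[1]} genes vs basis {basis.components.shape[1]}"
        )
    return (z - basis.mean) @ basis.components[basis.selected].T
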