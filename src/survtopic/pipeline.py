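"""Train/predict orchestration and the serialized model bundle.

``lsm_train`` runs the full learning pipeline: preprocessing, basis
computation for each requested feature group (cancer topics and/or
supervised principal components), feature assembly with clinical
covariates, and the survival learner. ``usm_predict`` replays the frozen
pipeline on novel patients without any training data, returning a survival
curve and a risk score per patient. The whole fitted state round-trips
through a single versioned JSON bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dlda import (
    TopicBasis,
    discretize,
    encode_counts,
    fit_discretizer,
    infer_loadings,
    select_basis,
    stratified_folds,
    DEFAULT_K_GRID,
    ENC_A,
    ENC_B,
)
from .evaluation import concordance
from .io_preprocess import (
    ClinicalTable,
    ExpressionMatrix,
    PreprocessState,
    SurvivalLabels,
    apply_preprocess,
    filter_invariant_genes,
    normalize_expression,
    prepare_clinical,
)
from .superpc import DEFAULT_ETA_GRID, PCBasis, fit_superpc, project_superpc
from .survival_models import (
    CoxModel,
    MTLRModel,
    SurvivalCurve,
    cox_survival_curve,
    fit_cox,
    fit_mtlr,
    mtlr_survival_curve,
    risk_from_curve,
)

logger = logging.getLogger("survtopic")

BUNDLE_VERSION = "1"
FEATURE_GROUPS = ("clinical", "dlda", "pca")
LEARNERS = ("cox", "rcox", "mtlr")

__all__ = ["ModelBundle", "lsm_train", "usm_predict", "save_bundle", "load_bundle"]


@dataclass
class ModelBundle:
    """Everything needed to predict for a novel patient."""

    version: str
    state: PreprocessState
    learner: str
    model: CoxModel | MTLRModel
    feature_groups: tuple[str, ...]
    feature_names: list[str]
    topic_basis: TopicBasis | None = None
    pc_basis: PCBasis | None = None
    config: dict = field(default_factory=dict)
    # columnwise standardization of the assembled design matrix (fitted on
    # training data; conditions the regularized learners)
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        for g in self.feature_groups:
            if g not in FEATURE_GROUPS:
                raise ValueError(f"unknown feature group {g!r}")
        if ("dlda" in self.feature_groups) != (self.topic_basis is not None):
            raise ValueError("dlda flag inconsistent with stored topic basis")
        if ("pca" in self.feature_groups) != (self.pc_basis is not None):
            raise ValueError("pca flag inconsistent with stored PC basis")


def _align(expr, clinical, labels):
    ids = list(expr.patient_ids)
    for name, other in (("clinical", clinical.patient_ids), ("labels", labels.patient_ids)):
        missing = sorted(set(ids) - set(other))
        extra = sorted(set(other) - set(ids))
        if missing or extra:
            raise ValueError(
                f"patient ID mismatch with {name} table: "
                f"missing={missing[:5]}{'...' if len(missing) > 5 else ''} "
                f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
    clinical = ClinicalTable(clinical.data.loc[ids], clinical.schema)
    pos = {p: i for i, p in enumerate(labels.patient_ids)}
    order = np.array([pos[p] for p in ids])
    labels = SurvivalLabels(ids, labels.time[order], labels.event[order])
    return clinical, labels


def lsm_train(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    labels: SurvivalLabels,
    features: tuple[str, ...] = ("clinical", "dlda"),
    learner: str = "mtlr",
    seed: int = 0,
    config: dict | None = None,
) -> ModelBundle:
    """Learn the full survival model (the LSM pipeline).

    ``features`` selects the groups entering the design matrix (order:
    clinical, PC scores, topic loadings). ``config`` can override the
    search grids: ``log2``, ``K_grid``, ``encodings``, ``n_folds``,
    ``lda_alpha``, ``eta_grid``, ``C_grid``, ``rcox_lambda_grid``,
    ``cox_lambda``, ``exclude_clinical`` (feature names to drop).
    """
    cfg = dict(config or {})
    features = tuple(features)
    for g in features:
        if g not in FEATURE_GROUPS:
            raise ValueError(f"unknown feature group {g!r}")
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}")
    clinical, labels = _align(expr, clinical, labels)

    exclude = set(cfg.get("exclude_clinical", ()))
    schema = {f: k for f, k in clinical.schema.items() if f not in exclude}
    clinical = ClinicalTable(clinical.data, schema)

    Xc, state = prepare_clinical(clinical)
    logger.info("clinical design matrix: %s", Xc.shape)
    z_all, mu, sd = normalize_expression(expr, log2_flag=bool(cfg.get("log2", False)))
    keep = filter_invariant_genes(z_all)
    state.global_mean, state.global_sd = mu, sd
    state.log2_applied = bool(cfg.get("log2", False))
    state.gene_ids = list(expr.gene_ids)
    state.retained_gene_ids = [expr.gene_ids[j] for j in keep]
    z = z_all[:, keep]
    logger.info("expression: %d/%d genes retained after invariance filter",
                len(keep), len(expr.gene_ids))

    blocks, names = [], []
    if "clinical" in features:
        blocks.append(Xc)
        names.extend(state.clinical_columns)

    pc_basis = None
    if "pca" in features:
        pc_basis = fit_superpc(
            z, labels,
            eta_grid=cfg.get("eta_grid", DEFAULT_ETA_GRID),
            n_folds=cfg.get("n_folds", 5), seed=seed,
            gene_ids=state.retained_gene_ids,
        )
        scores = project_superpc(z, pc_basis)
        blocks.append(scores)
        names.extend(f"PC{int(j) + 1}" for j in pc_basis.selected)
        logger.info("SuperPC+: %d components selected", scores.shape[1])

    topic_basis = None
    selection = None
    if "dlda" in features:
        fit_discretizer(z, state.retained_gene_ids, state)
        selection, topic_basis = select_basis(
            z, state.retained_gene_ids, Xc, labels,
            K_grid=cfg.get("K_grid", DEFAULT_K_GRID),
            encodings=cfg.get("encodings", (ENC_A, ENC_B)),
            n_folds=cfg.get("n_folds", 5),
            seed=seed,
            alpha=cfg.get("lda_alpha", 0.1),
            edges=state.per_gene_bins,
        )
        D = discretize(z, state.retained_gene_ids, state.per_gene_bins)
        corpus = encode_counts(D, topic_basis.encoding)
        theta = infer_loadings(corpus.counts, topic_basis)
        blocks.append(theta)
        names.extend(f"topic{k + 1}" for k in range(topic_basis.K))
        logger.info("dLDA: encoding=%s K=%d", topic_basis.encoding, topic_basis.K)

    if not blocks:
        raise ValueError("no feature groups requested")
    X = np.column_stack(blocks)
    feat_mean = X.mean(axis=0)
    feat_sd = X.std(axis=0)
    feat_sd[feat_sd == 0] = 1.0
    X = (X - feat_mean) / feat_sd
    logger.info("training design matrix: %s, learner=%s", X.shape, learner)

    if learner == "cox":
        model = fit_cox(X, labels, lam=float(cfg.get("cox_lambda", 0.0)),
                        feature_names=names)
    elif learner == "rcox":
        lam_grid = cfg.get("rcox_lambda_grid", (0.01, 0.1, 1.0, 10.0))
        model = _fit_rcox_cv(X, labels, lam_grid, cfg.get("n_folds", 5), seed, names)
    else:
        model = fit_mtlr(X, labels, C_grid=cfg.get("C_grid", (0.01, 0.1, 1.0, 10.0)),
                         seed=seed, n_folds=cfg.get("n_folds", 5),
                         feature_names=names)

    bundle = ModelBundle(
        version=BUNDLE_VERSION,
        state=state,
        learner=learner,
        model=model,
        feature_groups=features,
        feature_names=names,
        topic_basis=topic_basis,
        pc_basis=pc_basis,
        config={k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        feature_mean=feat_mean,
        feature_sd=feat_sd,
    )
    return bundle


def _fit_rcox_cv(X, labels, lam_grid, n_folds, seed, names):
    """Ridge Cox with the penalty weight chosen by held-out concordance."""
    folds = stratified_folds(labels.event, n_folds, seed)
    all_idx = np.arange(len(labels.time))
    scores = {}
    for lam in lam_grid:
        cis = []
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            try:
                m = fit_cox(X[train_idx], labels.subset(train_idx), lam=lam,
                            fit_baseline=False)
                cis.append(concordance(X[test_idx] @ m.coef, labels.subset(test_idx)))
            except (ValueError, RuntimeError):
                continue
        scores[lam] = float(np.mean(cis)) if cis else -np.inf
    best = max(scores.values())
    lam = max(l for l in lam_grid if scores[l] == best)
    logger.info("ridge Cox: lambda=%g (CI=%.4f)", lam, best)
    return fit_cox(X, labels, lam=lam, feature_names=names)


def _assemble_features(expr, clinical, bundle):
    z, Xc = apply_preprocess(expr, clinical, bundle.state)
    blocks = []
    if "clinical" in bundle.feature_groups:
        blocks.append(Xc)
    if "pca" in bundle.feature_groups:
        blocks.append(project_superpc(z, bundle.pc_basis))
    if "dlda" in bundle.feature_groups:
        D = discretize(z, bundle.state.retained_gene_ids, bundle.state.per_gene_bins)
        corpus = encode_counts(D, bundle.topic_basis.encoding)
        blocks.append(infer_loadings(corpus.counts, bundle.topic_basis))
    X = np.column_stack(blocks)
    if bundle.feature_mean is not None:
        X = (X - bundle.feature_mean) / bundle.feature_sd
    return X


def usm_predict(
    expr: ExpressionMatrix,
    clinical: ClinicalTable | None,
    bundle: ModelBundle,
) -> tuple[list[SurvivalCurve], pd.DataFrame]:
    """Predict survival curves and risk scores for novel patients (USM).

    Returns one curve per patient and a table with patient_id and risk
    (negative expected survival time from the curve).
    """
    X = _assemble_features(expr, clinical, bundle)
    if X.shape[1] != len(bundle.feature_names):
        raise ValueError("assembled features do not match the trained model schema")
    curves = []
    for x in X:
        if bundle.learner == "mtlr":
            curves.append(mtlr_survival_curve(bundle.model, x))
        else:
            curves.append(cox_survival_curve(bundle.model, x))
    risks = np.array([risk_from_curve(c) for c in curves])
    table = pd.DataFrame({"patient_id": expr.patient_ids, "risk": risks})
    return curves, table


# ---------------------------------------------------------------------------
# serialization


def _bundle_to_dict(bundle: ModelBundle) -> dict:
    return {
        "version": bundle.version,
        "state": bundle.state.to_dict(),
        "learner": bundle.learner,
        "model": bundle.model.to_dict(),
        "feature_groups": list(bundle.feature_groups),
        "feature_names": list(bundle.feature_names),
        "topic_basis": None if bundle.topic_basis is None else bundle.topic_basis.to_dict(),
        "pc_basis": None if bundle.pc_basis is None else bundle.pc_basis.to_dict(),
        "config": bundle.config,
        "feature_mean": None if bundle.feature_mean is None
        else bundle.feature_mean.tolist(),
        "feature_sd": None if bundle.feature_sd is None else bundle.feature_sd.tolist(),
    }


def save_bundle(bundle: ModelBundle, path) -> None:
    """Write the bundle as deterministic JSON (identical fits give
    byte-identical files)."""
    with open(path, "w") as fh:
        json.dump(_bundle_to_dict(bundle), fh, sort_keys=True, separators=(",", ":"))


def load_bundle(path) -> ModelBundle:
    """Read and validate a bundle; truncated or foreign files raise cleanly."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"bundle file is corrupt or truncated: {e}") from e
    if not isinstance(d, dict) or "version" not in d:
        raise ValueError("not a survtopic model bundle")
    if d["version"] != BUNDLE_VERSION:
        raise ValueError(
            f"bundle version {d['version']!r} not supported (expected {BUNDLE_VERSION!r})"
        )
    learner = d["learner"]
    model_cls = MTLRModel if learner == "mtlr" else CoxModel
    return ModelBundle(
        version=d["version"],
        state=PreprocessState.from_dict(d["state"]),
        learner=learner,
        model=model_cls.from_dict(d["model"]),
        feature_groups=tuple(d["feature_groups"]),
        feature_names=list(d["feature_names"]),
        topic_basis=None if d["topic_basis"] is None
        else TopicBasis.from_dict(d["topic_basis"]),
        pc_basis=None if d["pc_basis"] is None else PCBasis.from_dict(d["pc_basis"]),
        config=d.get("config", {}),
        feature_mean=None if d.get("feature_mean") is None
        else np.asarray(d["feature_mean"], dtype=float),
        feature_sd=None if d.get("feature_sd") is None
        else np.asarray(d["feature_sd"], dtype=float),
    )
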