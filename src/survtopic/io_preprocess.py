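"""Input tables and preprocessing.

Reads the three input tables (expression, clinical, survival labels) and
implements the training-time preprocessing plus its frozen replay for novel
patients:

* clinical features: mean/mode imputation and one-hot encoding of
  categoricals (one column per level);
* expression: optional log2, then a *global* z-score over all n x p entries
  (a single mean and standard deviation, not per-gene), followed by removal
  of genes whose standardized values never leave [-1, +1];
* the reusable state (``PreprocessState``) records everything needed to
  apply the identical transform to a patient never seen during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("survtopic")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "SurvivalLabels",
    "PreprocessState",
    "prepare_clinical",
    "apply_clinical",
    "normalize_expression",
    "filter_invariant_genes",
    "apply_preprocess",
    "read_expression",
    "read_clinical",
    "read_labels",
]


class PreprocessError(ValueError):
    """Raised for invalid or inconsistent preprocessing inputs."""


@dataclass
class ExpressionMatrix:
    """Patients x genes real-valued expression matrix.

    ``values[i, j]`` is the (log) expression of gene ``gene_ids[j]`` for
    patient ``patient_ids[i]``. Missing entries are not supported.
    """

    patient_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.patient_ids) != n or len(self.gene_ids) != p:
            raise PreprocessError(
                f"dimension mismatch: {n} x {p} values for "
                f"{len(self.patient_ids)} patients, {len(self.gene_ids)} genes"
            )
        if len(set(self.patient_ids)) != n:
            raise PreprocessError("patient_ids are not unique")
        if len(set(self.gene_ids)) != p:
            raise PreprocessError("gene_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise PreprocessError(
                "expression matrix contains missing or non-finite entries; "
                "complete matrices are required"
            )


@dataclass
class ClinicalTable:
    """Mixed-type clinical covariates with a declared schema.

    ``schema`` maps each feature name to ``"numeric"`` or ``"categorical"``.
    Missing values (NaN / empty) are allowed and handled by imputation.
    """

    data: pd.DataFrame
    schema: dict[str, str]

    def __post_init__(self) -> None:
        for feat, kind in self.schema.items():
            if kind not in ("numeric", "categorical"):
                raise PreprocessError(f"unknown type {kind!r} for feature {feat!r}")
            if feat not in self.data.columns:
                raise PreprocessError(f"schema feature {feat!r} missing from table")

    @property
    def patient_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]


@dataclass
class SurvivalLabels:
    """Right-censored survival labels: time in days and event indicator."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or len(self.patient_ids) != len(self.time):
            raise PreprocessError("labels: inconsistent lengths")
        if np.any(self.time < 0):
            raise PreprocessError("survival times must be >= 0")
        if not np.all(np.isin(self.event, [0, 1])):
            raise PreprocessError("event indicator must be 0 or 1")

    def subset(self, idx: np.ndarray) -> "SurvivalLabels":
        idx = np.asarray(idx)
        return SurvivalLabels(
            [self.patient_ids[i] for i in idx], self.time[idx], self.event[idx]
        )


@dataclass
class PreprocessState:
    """Frozen preprocessing state (the reusable "Omega" object).

    Everything a prediction-time pipeline needs to replay training-time
    preprocessing on a novel patient: the global mean/sd, the retained gene
    list, clinical imputation values and level orders, and (once fitted by
    the discretizer) the per-gene bin edges.
    """

    global_mean: float = 0.0
    global_sd: float = 1.0
    log2_applied: bool = False
    gene_ids: list[str] = field(default_factory=list)
    retained_gene_ids: list[str] = field(default_factory=list)
    clinical_features: list[str] = field(default_factory=list)
    clinical_schema: dict[str, str] = field(default_factory=dict)
    clinical_impute_values: dict[str, object] = field(default_factory=dict)
    category_levels: dict[str, list[str]] = field(default_factory=dict)
    clinical_columns: list[str] = field(default_factory=list)
    # gene -> [min_pos, delta_pos, min_neg, delta_neg]; None marks an absent side
    per_gene_bins: dict[str, list] = field(default_factory=dict)

    @property
    def retained_index(self) -> np.ndarray:
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in self.retained_gene_ids], dtype=int)

    def to_dict(self) -> dict:
        return {
            "global_mean": float(self.global_mean),
            "global_sd": float(self.global_sd),
            "log2_applied": bool(self.log2_applied),
            "gene_ids": list(self.gene_ids),
            "retained_gene_ids": list(self.retained_gene_ids),
            "clinical_features": list(self.clinical_features),
            "clinical_schema": dict(self.clinical_schema),
            "clinical_impute_values": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else str(v))
                for k, v in self.clinical_impute_values.items()
            },
            "category_levels": {k: list(v) for k, v in self.category_levels.items()},
            "clinical_columns": list(self.clinical_columns),
            "per_gene_bins": {
                g: [None if e is None else float(e) for e in edges]
                for g, edges in self.per_gene_bins.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PreprocessState":
        return cls(**{k: d[k] for k in d})


def prepare_clinical(table: ClinicalTable) -> tuple[np.ndarray, PreprocessState]:
    """Impute and encode the clinical table; return design matrix and state.

    Numeric features are mean-imputed. Categorical features are mode-imputed
    (ties broken by sorted level order for determinism) and one-hot encoded
    with one binary column per observed level.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    state = PreprocessState(
        clinical_features=list(table.schema.keys()),
        clinical_schema=dict(table.schema),
    )
    n = len(table.data)
    if n < 1:
        raise PreprocessError("clinical table has no patients")
    for feat, kind in table.schema.items():
        col = table.data[feat]
        if kind == "numeric":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            observed = vals[np.isfinite(vals)]
            if observed.size == 0:
                raise PreprocessError(f"feature {feat!r} has no observed values")
            fill = float(observed.mean())
            vals = np.where(np.isfinite(vals), vals, fill)
            state.clinical_impute_values[feat] = fill
            cols.append(vals)
            names.append(feat)
        else:
            raw = col.astype("object")
            mask = raw.notna() & (raw.astype(str).str.len() > 0)
            observed = raw[mask].astype(str)
            if observed.size == 0:
                raise PreprocessError(f"feature {feat!r} has no observed values")
            counts = observed.value_counts()
            top = counts.max()
            mode = sorted(counts[counts == top].index)[0]
            state.clinical_impute_values[feat] = mode
            filled = np.where(mask, raw.astype(str), mode)
            levels = sorted(set(filled))
            state.category_levels[feat] = levels
            for lev in levels:
                cols.append((filled == lev).astype(float))
                names.append(f"{feat}={lev}")
    state.clinical_columns = names
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, state


def apply_clinical(table: ClinicalTable, state: PreprocessState) -> np.ndarray:
    """Replay the stored clinical transform on novel patients.

    Uses the *training* imputation values and level orders. A category level
    never seen in training yields an all-zero one-hot block for that feature
    (logged at WARNING).
    """
    cols: list[np.ndarray] = []
    for feat in state.clinical_features:
        kind = state.clinical_schema[feat]
        if feat not in table.data.columns:
            raise PreprocessError(f"clinical feature {feat!r} missing at predict time")
        col = table.data[feat]
        if kind == "numeric":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            vals = np.where(np.isfinite(vals), vals, state.clinical_impute_values[feat])
            cols.append(vals)
        else:
            raw = col.astype("object")
            mask = raw.notna() & (raw.astype(str).str.len() > 0)
            filled = np.where(mask, raw.astype(str), str(state.clinical_impute_values[feat]))
            levels = state.category_levels[feat]
            unseen = sorted(set(filled) - set(levels))
            if unseen:
                logger.warning(
                    "feature %r: unseen level(s) %s -> all-zero encoding", feat, unseen
                )
            for lev in levels:
                cols.append((filled == lev).astype(float))
    n = len(table.data)
    return np.column_stack(cols) if cols else np.empty((n, 0))


def normalize_expression(
    X: ExpressionMatrix, log2_flag: bool = False
) -> tuple[np.ndarray, float, float]:
    """Global z-score of the expression matrix.

    A single mean and standard deviation are computed over all ``n*p``
    entries (denominator ``n*p - 1``); per-gene scaling would erase the
    between-gene variability the downstream invariant-gene filter relies on.
    """
    vals = X.values
    if log2_flag:
        if np.any(vals <= 0):
            raise PreprocessError("log2 transform requested but matrix has entries <= 0")
        vals = np.log2(vals)
    mu = float(vals.mean())
    denom = vals.size - 1
    if denom <= 0:
        raise PreprocessError("need at least two expression entries")
    sd = float(np.sqrt(np.sum((vals - mu) ** 2) / denom))
    if sd <= 0:
        raise PreprocessError("expression matrix is constant (sigma = 0)")
    return (vals - mu) / sd, mu, sd


def filter_invariant_genes(z: np.ndarray) -> np.ndarray:
    """Indices of genes retained: those with at least one |z| > 1.

    A gene whose standardized values all lie inside the closed band
    [-1, +1] carries no non-trivial signal and is dropped.
    """
    z = np.asarray(z, dtype=float)
    keep = np.where(np.abs(z).max(axis=0) > 1.0)[0]
    if keep.size == 0:
        raise PreprocessError("all genes are invariant; no features left")
    return keep


def apply_preprocess(
    expr: ExpressionMatrix, clinical: ClinicalTable | None, state: PreprocessState
) -> tuple[np.ndarray, np.ndarray]:
    """PreProcess for novel patients: stored transform only, no re-fitting.

    Returns the z matrix restricted to the retained training genes and the
    clinical design matrix, both in training column order.
    """
    missing = set(state.gene_ids) - set(expr.gene_ids)
    extra = set(expr.gene_ids) - set(state.gene_ids)
    if missing or extra:
        raise PreprocessError(
            f"gene set mismatch: {len(missing)} training genes absent, "
            f"{len(extra)} unknown genes present"
        )
    order = {g: j for j, g in enumerate(expr.gene_ids)}
    cols = np.array([order[g] for g in state.gene_ids], dtype=int)
    vals = expr.values[:, cols]
    if state.log2_applied:
        if np.any(vals <= 0):
            raise PreprocessError("log2 transform stored but matrix has entries <= 0")
        vals = np.log2(vals)
    z = (vals - state.global_mean) / state.global_sd
    z = z[:, state.retained_index]
    if clinical is not None:
        xc = apply_clinical(clinical, state)
    else:
        xc = np.empty((len(expr.patient_ids), 0))
    return z, xc


# ---------------------------------------------------------------------------
# file readers (TSV expression, CSV clinical + schema, CSV labels)


def read_expression(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a TSV expression table (first column IDs, header = other axis).

    On-disk orientation may be genes-as-rows; pass ``transpose=True`` to get
    the canonical patients x genes form.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    return ExpressionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)
    )


def read_clinical(path, schema_path) -> ClinicalTable:
    """Read a clinical CSV plus its schema file (columns: feature,type)."""
    schema_df = pd.read_csv(schema_path)
    schema = dict(zip(schema_df.iloc[:, 0].astype(str), schema_df.iloc[:, 1].astype(str)))
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df, schema)


def read_labels(path) -> SurvivalLabels:
    """Read a labels CSV with columns patient_id,time,event."""
    df = pd.read_csv(path)
    return SurvivalLabels(
        df["patient_id"].astype(str).tolist(),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
    )
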