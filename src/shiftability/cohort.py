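"""Paired-cohort handling: treatment-induced changes and response classification.

The central quantity is the per-patient, per-gene treatment-induced expression
change: the log2 fold change between on-treatment and pre-treatment tumor
expression (a subtraction on the log2 scale). For cohorts without paired
biopsies, the deviation of each sample from the cohort population baseline
serves as a surrogate for that change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, ValueKind

log = logging.getLogger(__name__)

__all__ = [
    "PairedCohort",
    "log2_transform",
    "merge_biopsies",
    "treatment_induced_changes",
    "baseline_relative_changes",
    "pca_response_score",
    "roc_auc",
    "immunity_association",
]

RESPONDER = "responder"
NON_RESPONDER = "non-responder"


@dataclass
class PairedCohort:
    """Matched pre/on-treatment expression with a known binary response per patient."""

    pre: ExpressionMatrix
    post: ExpressionMatrix
    response: pd.Series  # patient_id -> "responder" / "non-responder"

    def __post_init__(self) -> None:
        if self.pre.gene_ids != self.post.gene_ids:
            raise ValueError("pre and post matrices must share identical gene ids")
        if self.pre.sample_ids != self.post.sample_ids:
            raise ValueError("pre and post columns must be patient-aligned")
        patients = self.pre.sample_ids
        missing = set(patients) - set(self.response.index)
        if missing:
            raise ValueError(f"patients without response label: {sorted(missing)[:5]}")
        self.response = self.response.loc[patients].astype(str)
        bad = set(self.response) - {RESPONDER, NON_RESPONDER}
        if bad:
            raise ValueError(f"unknown response label(s): {sorted(bad)}")

    @property
    def patients(self) -> list[str]:
        return self.pre.sample_ids

    @property
    def labels(self) -> np.ndarray:
        """Binary labels, 1 = responder."""
        return (self.response.to_numpy() == RESPONDER).astype(int)


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) for raw (linear-scale) input; pseudocount 1 keeps zeros at zero."""
    if (expr.values < 0).any():
        raise ValueError("raw expression must be non-negative")
    return ExpressionMatrix(np.log2(expr.data + pseudocount), ValueKind.LOG2_EXPRESSION)


def merge_biopsies(expr: ExpressionMatrix, sample_to_patient: dict[str, str]) -> ExpressionMatrix:
    """Average multiple biopsies of the same patient-timepoint into one column.

    ``sample_to_patient`` must cover every column; singleton groups pass
    through unchanged. Output columns are ordered by first appearance of each
    group in the input.
    """
    missing = set(expr.sample_ids) - set(sample_to_patient)
    if missing:
        raise ValueError(f"sample(s) not covered by mapping: {sorted(missing)[:5]}")
    order: list[str] = []
    groups: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        p = sample_to_patient[s]
        if p not in groups:
            groups[p] = []
            order.append(p)
        groups[p].append(s)
    merged = pd.DataFrame({p: expr.data[groups[p]].mean(axis=1) for p in order})
    return ExpressionMatrix(merged, expr.value_kind)


def treatment_induced_changes(cohort: PairedCohort) -> ExpressionMatrix:
    """Per-patient log2 fold change: post minus pre on the log2 scale."""
    if cohort.pre.value_kind is not ValueKind.LOG2_EXPRESSION:
        raise ValueError(f"expected log2_expression input, got {cohort.pre.value_kind.value}")
    delta = cohort.post.data - cohort.pre.data
    return ExpressionMatrix(delta, ValueKind.DELTA_LOG2FC, provenance="paired")


def baseline_relative_changes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Surrogate change for unpaired cohorts: deviation from the cohort baseline.

    The baseline is the gene-wise arithmetic mean across samples (median via
    ``statistic="median"`` if preferred upstream).
    """
    if expr.shape[1] < 2:
        raise ValueError("baseline undefined for a single sample")
    delta = expr.data.sub(expr.data.mean(axis=1), axis=0)
    return ExpressionMatrix(delta, ValueKind.DELTA_LOG2FC, provenance="baseline_surrogate")


def pca_response_score(
    delta: ExpressionMatrix, labels: np.ndarray | None = None
) -> pd.Series:
    """Response score = projection onto PC1 of the patient x gene matrix.

    Genes are centered and scaled to unit variance; zero-variance genes are
    dropped with a log entry. The PC1 sign is oriented so the ROC AUC against
    ``labels`` is >= 0.5 when labels are given; otherwise the loading of the
    lexicographically first retained gene is made non-negative (determinism).
    """
    from sklearn.decomposition import PCA

    X = delta.data.T  # patients x genes
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patients for PCA")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("pca_response_score: %d zero-variance gene(s) dropped", n_dropped)
    X = X.loc[:, keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())[:, 0]
    if labels is not None:
        if roc_auc(labels, scores) < 0.5:
            scores = -scores
    else:
        first = np.argsort(X.columns)[0]
        if pca.components_[0, first] < 0:
            scores = -scores
    return pd.Series(scores, index=X.index, name="response_score")


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve: the tie-adjusted Mann-Whitney U / (n1 * n0)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def immunity_association(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation between e.g. signature expression change and an immune covariate.

    Returns (r, two-sided p); p-value underflow is floored at 1e-300 so a
    significant association never reports exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(max(p, 1e-300))
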