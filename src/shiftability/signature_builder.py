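"""Bootstrapped feature selection and cross-validated construction of R/S signatures.

Genes whose treatment-induced expression change separates non-responders from
responders are selected by stratified bootstrap resampling: in each of
``n_boot`` resamples, a two-sided Student's t test compares the per-patient
change between response groups; a gene with p < alpha is a hit, directed R
(resistance) when its mean change is higher in non-responders and S
(sensitivity) when higher in responders. The hit frequency over bootstraps is
the gene's DEG selection score, per direction. Candidate signatures R_i / S_j
take the top i% / j% of positively scoring genes; a grid of (i, j) choices is
evaluated by 3-fold cross-validated AUC of the per-patient RS score, core
signatures are the intersection of the three folds' candidates, and the final
(i, j) balances signature sizes against held-out performance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import roc_auc
from .data_io import ExpressionMatrix
from .enrichment import RankedList, rank_genes, rs_score

log = logging.getLogger(__name__)

__all__ = [
    "DEGSelectionScores",
    "GeneSignature",
    "CVResult",
    "bootstrap_deg_selection",
    "candidate_signatures",
    "cross_validate_signatures",
    "evaluate_signature",
]

DEFAULT_GRID = [(i, j) for i in range(5, 55, 5) for j in range(5, 55, 5)]


@dataclass
class DEGSelectionScores:
    """Per-gene bootstrap hit fractions, per direction (multiples of 1/n_boot)."""

    table: pd.DataFrame  # index gene, columns hit_fraction_R / hit_fraction_S
    n_boot: int
    alpha: float

    def __post_init__(self) -> None:
        frac = self.table[["hit_fraction_R", "hit_fraction_S"]]
        if ((frac < 0) | (frac > 1)).any().any():
            raise ValueError("hit fractions must lie in [0, 1]")
        if (frac.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("a gene cannot be both an R and an S hit in one bootstrap")

    @property
    def hit_fraction_R(self) -> pd.Series:
        return self.table["hit_fraction_R"]

    @property
    def hit_fraction_S(self) -> pd.Series:
        return self.table["hit_fraction_S"]


@dataclass(frozen=True)
class GeneSignature:
    name: str
    direction: str  # "R" or "S"
    genes: frozenset[str]
    selection_percent: float

    def __post_init__(self) -> None:
        if self.direction not in ("R", "S"):
            raise ValueError("direction must be 'R' or 'S'")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CVResult:
    grid: pd.DataFrame  # columns i, j, cv_auc, leaveout_auc, size_R, size_S
    chosen_i: float
    chosen_j: float
    fold_candidates: list[dict]  # per fold: {"R": GeneSignature, "S": GeneSignature}
    core_R: GeneSignature
    core_S: GeneSignature
    leaveout_auc: float
    core_fallback_used: bool = False
    leaveout_patients: list[str] = field(default_factory=list)

    @property
    def cv_auc(self) -> float:
        row = self.grid[(self.grid.i == self.chosen_i) & (self.grid.j == self.chosen_j)]
        return float(row.cv_auc.iloc[0])


# ---------------------------------------------------------------------------
# Bootstrap DEG selection


def _t_test_matrix(x: np.ndarray, y: np.ndarray, equal_var: bool) -> np.ndarray:
    """Two-sided t test p-values per row (gene); zero pooled variance -> p = 1."""
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    if equal_var:
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        denom = np.sqrt(pooled * (1 / nx + 1 / ny))
        df = np.full(len(mx), nx + ny - 2, dtype=float)
    else:
        sem2x, sem2y = vx / nx, vy / ny
        denom = np.sqrt(sem2x + sem2y)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (sem2x + sem2y) ** 2 / (
                sem2x**2 / (nx - 1) + sem2y**2 / (ny - 1)
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mx - my) / denom
    p = 2 * stats.t.sf(np.abs(t), df)
    p[~np.isfinite(t)] = 1.0  # degenerate rows (zero variance) are never hits
    return p


def bootstrap_deg_selection(
    delta: ExpressionMatrix,
    labels,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    equal_var: bool = True,
) -> DEGSelectionScores:
    """DEG selection scores from stratified bootstrap t tests on the delta matrix.

    ``labels`` is a binary vector per patient column (1 = responder). Each
    bootstrap resamples each response stratum with replacement to its original
    size (patients are the resampling unit); a draw whose stratum collapses to
    fewer than 2 distinct patients is redrawn (at most 10 attempts).
    """
    labels = np.asarray(labels).astype(int)
    if labels.shape[0] != delta.shape[1]:
        raise ValueError("labels must align with delta columns (patients)")
    resp = np.where(labels == 1)[0]
    nonr = np.where(labels == 0)[0]
    if len(resp) < 3 or len(nonr) < 3:
        raise ValueError("each response class needs at least 3 patients")
    values = delta.values
    rng = np.random.default_rng(seed)
    hits_R = np.zeros(delta.shape[0], dtype=np.int64)
    hits_S = np.zeros(delta.shape[0], dtype=np.int64)
    for _ in range(n_boot):
        for _attempt in range(10):
            bs_resp = rng.choice(resp, size=len(resp), replace=True)
            bs_nonr = rng.choice(nonr, size=len(nonr), replace=True)
            if len(set(bs_resp)) >= 2 and len(set(bs_nonr)) >= 2:
                break
        else:
            raise RuntimeError("bootstrap stratum collapsed to <2 distinct patients 10 times")
        x_nonr = values[:, bs_nonr]
        x_resp = values[:, bs_resp]
        p = _t_test_matrix(x_nonr, x_resp, equal_var)
        hit = p < alpha
        higher_in_nonr = x_nonr.mean(axis=1) > x_resp.mean(axis=1)
        hits_R += hit & higher_in_nonr
        hits_S += hit & ~higher_in_nonr
    table = pd.DataFrame(
        {"hit_fraction_R": hits_R / n_boot, "hit_fraction_S": hits_S / n_boot},
        index=delta.data.index,
    )
    return DEGSelectionScores(table, n_boot=n_boot, alpha=alpha)


# ---------------------------------------------------------------------------
# Candidate signatures


def _top_percent(fractions: pd.Series, percent: float, name: str, direction: str) -> GeneSignature:
    positive = fractions[fractions > 0]
    if positive.empty:
        raise ValueError(f"no gene has a positive {direction} hit fraction")
    count = math.ceil(len(positive) * percent / 100.0)
    ordered = positive.sort_values(ascending=False, kind="mergesort")
    threshold = ordered.iloc[count - 1]
    genes = frozenset(positive.index[positive >= threshold])  # boundary ties included
    return GeneSignature(name, direction, genes, percent)


def candidate_signatures(
    scores: DEGSelectionScores, i: float, j: float
) -> tuple[GeneSignature, GeneSignature]:
    """Top-i% R signature and top-j% S signature of the positively scoring genes."""
    sig_R = _top_percent(scores.hit_fraction_R, i, f"R_{i:g}", "R")
    sig_S = _top_percent(scores.hit_fraction_S, j, f"S_{j:g}", "S")
    return sig_R, sig_S


# ---------------------------------------------------------------------------
# Scoring helpers


def _patient_ranked_lists(delta: ExpressionMatrix, columns) -> dict[str, RankedList]:
    return {c: rank_genes(delta.data[c]) for c in columns}


def _rs_scores(
    ranked: dict[str, RankedList], genes_R: frozenset[str], genes_S: frozenset[str]
) -> np.ndarray:
    return np.array([rs_score(r, genes_R, genes_S) for r in ranked.values()])


def evaluate_signature(
    delta: ExpressionMatrix, labels, sig_R: GeneSignature, sig_S: GeneSignature
) -> float:
    """AUC of per-patient RS scores (ES mode) against the response labels."""
    from .enrichment import check_overlap

    labels = np.asarray(labels).astype(int)
    ranked = _patient_ranked_lists(delta, delta.sample_ids)
    first = next(iter(ranked.values()))
    check_overlap(first, sig_R.genes)
    check_overlap(first, sig_S.genes)
    scores = _rs_scores(ranked, sig_R.genes, sig_S.genes)
    return roc_auc(labels, scores)


# ---------------------------------------------------------------------------
# Cross-validation


def _stratified_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Indices of a stratified held-out split of the given fraction."""
    held = []
    for cls in (0, 1):
        idx = np.where(labels == cls)[0]
        n_held = max(2, round(len(idx) * fraction))
        held.extend(rng.choice(idx, size=n_held, replace=False))
    held = np.sort(np.asarray(held))
    rest = np.setdiff1d(np.arange(len(labels)), held)
    return rest, held


def cross_validate_signatures(
    delta: ExpressionMatrix,
    labels,
    grid: list[tuple[float, float]] | None = None,
    n_folds: int = 3,
    leaveout_fraction: float = 0.25,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> CVResult:
    """Grid-search (i, j) by stratified 3-fold CV of RS-score AUC.

    A stratified leave-out split is held back first; within the remainder,
    each fold's training portion yields bootstrap DEG scores and candidate
    (R_i, S_j) signatures, scored on the fold's test patients (ES-mode RS).
    Core signatures intersect the three folds' candidates; the chosen (i, j)
    maximizes mean(cv AUC, leave-out AUC) among grid points whose core sizes
    satisfy min/max >= 0.5, ties broken toward smaller signatures. An empty
    core intersection falls back to genes shared by at least 2 of 3 folds
    (flagged in the result).
    """
    from sklearn.model_selection import StratifiedKFold

    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    labels = np.asarray(labels).astype(int)
    patients = np.asarray(delta.sample_ids, dtype=object)
    rng = np.random.default_rng(seed)

    train_idx, held_idx = _stratified_split(labels, leaveout_fraction, rng)
    inner_labels = labels[train_idx]
    if min(np.bincount(inner_labels, minlength=2)) < 2 * n_folds:
        raise ValueError("not enough patients per class for stratified folds")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    i_values = sorted({ij[0] for ij in grid})
    j_values = sorted({ij[1] for ij in grid})

    fold_sets_R: list[dict[float, GeneSignature]] = []
    fold_sets_S: list[dict[float, GeneSignature]] = []
    fold_aucs: list[dict[tuple[float, float], float]] = []
    ranked_all = _patient_ranked_lists(delta, delta.sample_ids)

    for fold_no, (tr, te) in enumerate(skf.split(train_idx, inner_labels)):
        tr_idx, te_idx = train_idx[tr], train_idx[te]
        sub = ExpressionMatrix(delta.data.iloc[:, tr_idx], delta.value_kind)
        scores = bootstrap_deg_selection(
            sub, labels[tr_idx], n_boot=n_boot, alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        sigs_R = {i: _top_percent(scores.hit_fraction_R, i, f"R_{i:g}", "R") for i in i_values}
        sigs_S = {j: _top_percent(scores.hit_fraction_S, j, f"S_{j:g}", "S") for j in j_values}
        fold_sets_R.append(sigs_R)
        fold_sets_S.append(sigs_S)
        # per test patient, per single signature, one ES; RS combines them
        te_ranked = {patients[p]: ranked_all[patients[p]] for p in te_idx}
        from .enrichment import prerank_es

        es_R = {i: np.array([prerank_es(r, sigs_R[i].genes) for r in te_ranked.values()])
                for i in i_values}
        es_S = {j: np.array([prerank_es(r, sigs_S[j].genes) for r in te_ranked.values()])
                for j in j_values}
        aucs = {}
        for i, j in grid:
            aucs[(i, j)] = roc_auc(labels[te_idx], es_S[j] - es_R[i])
        fold_aucs.append(aucs)
        log.debug("fold %d scored (%d grid points)", fold_no, len(grid))

    # core signatures and leave-out AUC per grid point
    held_ranked = {patients[p]: ranked_all[patients[p]] for p in held_idx}
    from .enrichment import prerank_es

    rows = []
    core_cache: dict[tuple[float, float], tuple[frozenset, frozenset, bool]] = {}
    es_core_R: dict[float, np.ndarray | None] = {}
    es_core_S: dict[float, np.ndarray | None] = {}
    core_R_sets: dict[float, tuple[frozenset, bool]] = {}
    core_S_sets: dict[float, tuple[frozenset, bool]] = {}

    def _core(per_fold: list[frozenset]) -> tuple[frozenset, bool]:
        inter = frozenset.intersection(*per_fold)
        if inter:
            return inter, False
        counts: dict[str, int] = {}
        for s in per_fold:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        union2 = frozenset(g for g, c in counts.items() if c >= 2)
        return union2, True

    for i in i_values:
        core, fb = _core([fold_sets_R[f][i].genes for f in range(n_folds)])
        core_R_sets[i] = (core, fb)
        es_core_R[i] = (
            np.array([prerank_es(r, core) for r in held_ranked.values()]) if core else None
        )
    for j in j_values:
        core, fb = _core([fold_sets_S[f][j].genes for f in range(n_folds)])
        core_S_sets[j] = (core, fb)
        es_core_S[j] = (
            np.array([prerank_es(r, core) for r in held_ranked.values()]) if core else None
        )

    for i, j in grid:
        cv_auc = float(np.mean([fold_aucs[f][(i, j)] for f in range(n_folds)]))
        core_R, fb_R = core_R_sets[i]
        core_S, fb_S = core_S_sets[j]
        if es_core_R[i] is not None and es_core_S[j] is not None:
            lo_auc = roc_auc(labels[held_idx], es_core_S[j] - es_core_R[i])
        else:
            lo_auc = np.nan
        rows.append(
            dict(i=i, j=j, cv_auc=cv_auc, leaveout_auc=lo_auc,
                 size_R=len(core_R), size_S=len(core_S), fallback=fb_R or fb_S)
        )
        core_cache[(i, j)] = (core_R, core_S, fb_R or fb_S)
    grid_df = pd.DataFrame(rows)

    # selection: balance constraint, then mean(cv, leave-out), ties toward small
    valid = grid_df[
        (grid_df.size_R > 0) & (grid_df.size_S > 0)
        & (grid_df[["size_R", "size_S"]].min(axis=1)
           / grid_df[["size_R", "size_S"]].max(axis=1) >= 0.5)
        & grid_df.leaveout_auc.notna()
    ]
    if valid.empty:
        log.warning("no grid point satisfies the size-balance constraint; relaxing it")
        valid = grid_df[(grid_df.size_R > 0) & (grid_df.size_S > 0)
                        & grid_df.leaveout_auc.notna()]
    if valid.empty:
        raise ValueError("every grid point produced an empty core signature")
    objective = (valid.cv_auc + valid.leaveout_auc) / 2
    best = valid.loc[
        valid.assign(obj=objective, tot=valid.size_R + valid.size_S)
        .sort_values(["obj", "tot", "i", "j"], ascending=[False, True, True, True])
        .index[0]
    ]
    chosen_i, chosen_j = best.i, best.j
    core_R_genes, core_S_genes, fallback = core_cache[(chosen_i, chosen_j)]
    if fallback:
        log.warning("empty 3-fold core intersection at (%g, %g); used 2-of-3 union",
                    chosen_i, chosen_j)
    core_R = GeneSignature(f"core_R_{chosen_i:g}", "R", core_R_genes, float(chosen_i))
    core_S = GeneSignature(f"core_S_{chosen_j:g}", "S", core_S_genes, float(chosen_j))

    fold_candidates = [
        {"R": fold_sets_R[f][chosen_i], "S": fold_sets_S[f][chosen_j]} for f in range(n_folds)
    ]
    return CVResult(
        grid=grid_df,
        chosen_i=float(chosen_i),
        chosen_j=float(chosen_j),
        fold_candidates=fold_candidates,
        core_R=core_R,
        core_S=core_S,
        leaveout_auc=float(best.leaveout_auc),
        core_fallback_used=bool(fallback),
        leaveout_patients=[str(patients[p]) for p in held_idx],
    )
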