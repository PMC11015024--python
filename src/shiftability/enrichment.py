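"""Pre-ranked GSEA enrichment engine and single-sample (ssGSEA) scoring.

This is the computational core shared by patient RS scoring, the perturbation
shift-ability screen, and mechanism-cluster annotation. The enrichment score
(ES) is the weighted Kolmogorov-Smirnov running-sum statistic on a descending
ranked gene list: walking down the list, a hit increments the running sum by
its |score|^weight share of the total hit mass, a miss decrements it by
1/(N - |S|); the ES is the extreme deviation, with its sign. The normalized
enrichment score (NES) divides the ES by the mean of same-sign ES values from
random gene sets of the same effective size (gene-set permutation, the only
null available for pre-ranked input).

Implementation notes: the running sum changes slope only at hit positions, so
the ES is computed from the sorted hit positions in O(|S|) instead of walking
all N positions; the permutation null is vectorized over all draws at once.
Null position draws are a pure function of (seed, N, set size, n_perm), so
signatures of equal effective size within one run share draws automatically
and results are independent of evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "InsufficientOverlapError",
    "rank_genes",
    "prerank_es",
    "prerank_nes",
    "rs_score",
    "ssgsea_score",
]

#: default overlap floor: a signature must keep >= MIN_OVERLAP_GENES members and
#: >= MIN_OVERLAP_FRACTION of itself after intersection with the ranked universe
MIN_OVERLAP_GENES = 15
MIN_OVERLAP_FRACTION = 0.5


class InsufficientOverlapError(ValueError):
    """A gene set retains too few members in the ranked universe to be scored."""


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    nominal_p: float
    n_perm: int
    set_size_used: int


class RankedList:
    """A gene list ranked by score, descending; ties broken by ascending gene id.

    The deterministic tie order makes every downstream statistic a pure
    function of its inputs.
    """

    __slots__ = ("genes", "scores", "_pos")

    def __init__(self, genes: Iterable[str], scores: Iterable[float]):
        genes = np.asarray(list(genes), dtype=object)
        scores = np.asarray(list(scores), dtype=float)
        if len(genes) != len(scores):
            raise ValueError("genes and scores must have equal length")
        if len(genes) < 2:
            raise ValueError("a ranked list needs at least 2 genes")
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids in a ranked list must be unique")
        if not np.isfinite(scores).all():
            raise ValueError("ranked scores must be finite")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing")
        self.genes = genes
        self.scores = scores
        self._pos = {g: i for i, g in enumerate(genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, gene_set: Iterable[str]) -> np.ndarray:
        """Sorted 0-based positions of the set members present in the list."""
        pos = sorted(self._pos[g] for g in gene_set if g in self._pos)
        return np.asarray(pos, dtype=np.intp)


def rank_genes(delta_column: Mapping[str, float] | pd.Series) -> RankedList:
    """Build a descending RankedList from per-gene scores.

    Genes with non-finite scores are excluded with a warning; ties are ordered
    by ascending gene id.
    """
    s = pd.Series(delta_column, dtype=float)
    finite = np.isfinite(s.to_numpy())
    if not finite.all():
        log.warning("rank_genes: %d gene(s) with non-finite scores excluded", int((~finite).sum()))
        s = s[finite]
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return RankedList(order, s.loc[order].to_numpy())


# ---------------------------------------------------------------------------
# ES from hit positions


def _hit_weights(abs_w: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Normalized hit increments; uniform fallback when the hit mass is zero."""
    w = abs_w[positions]
    total = w.sum(axis=-1, keepdims=True)
    k = positions.shape[-1]
    uniform = np.full_like(w, 1.0 / k)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, w / np.where(total > 0, total, 1.0), uniform)
    return out

def _es_from_positions(abs_w: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """ES for one or many sets given sorted hit positions (last axis = hits)."""
    positions = np.atleast_2d(positions)
    k = positions.shape[1]
    miss_step = 1.0 / (n - k)
    w_norm = _hit_weights(abs_w, positions)
    cum = np.cumsum(w_norm, axis=1)
    i = np.arange(1, k + 1)
    # running value just after the i-th hit, and just before it
    after = cum - (positions + 1 - i) * miss_step
    before = (cum - w_norm) - (positions - (i - 1)) * miss_step
    pos_ex = after.max(axis=1)
    neg_ex = np.minimum(before.min(axis=1), 0.0)
    # the positive extreme wins ties (to 1e-12): exact ties between the two
    # extremes are generic (e.g. a contiguous hit block centered in the list)
    # and must not be decided by rounding noise
    es = np.where(pos_ex + neg_ex >= -1e-12, pos_ex, neg_ex)
    return es


def prerank_es(ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0) -> float:
    """Weighted KS enrichment score of ``gene_set`` on the ranked list.

    Requires a non-empty intersection that does not cover the whole list
    (otherwise the miss denominator is zero). |ES| <= 1 always.
    """
    positions = ranked.positions(gene_set)
    n = len(ranked)
    if len(positions) == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if len(positions) >= n:
        raise ValueError("gene set covers the whole ranked list; miss denominator is zero")
    abs_w = np.abs(ranked.scores) ** weight
    return float(_es_from_positions(abs_w, positions, n)[0])


# ---------------------------------------------------------------------------
# Permutation null and NES

_DRAW_CACHE: dict[tuple, np.ndarray] = {}
_DRAW_CACHE_MAX = 64


def _null_position_draws(n: int, k: int, n_perm: int, seed: int) -> np.ndarray:
    """(n_perm, k) sorted position draws without replacement from range(n).

    A pure function of its arguments: the rng is seeded with the full key, so
    any caller with the same (seed, universe size, set size, n_perm) sees the
    identical draws, cached or not.
    """
    key = (n, k, n_perm, seed)
    hit = _DRAW_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng([seed, n, k, n_perm])
    idx = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
    idx.sort(axis=1)
    if len(_DRAW_CACHE) >= _DRAW_CACHE_MAX:
        _DRAW_CACHE.clear()
    _DRAW_CACHE[key] = idx
    return idx


def prerank_nes(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """ES, NES and nominal p against a random-gene-set permutation null.

    NES = ES / |mean of same-sign null ES|; nominal p is the fraction of
    same-sign null ES at least as extreme, with a +1 pseudocount on numerator
    and denominator. Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    positions = ranked.positions(gene_set)
    n = len(ranked)
    if len(positions) == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if len(positions) >= n:
        raise ValueError("gene set covers the whole ranked list")
    k = len(positions)
    abs_w = np.abs(ranked.scores) ** weight
    es = float(_es_from_positions(abs_w, positions, n)[0])
    if es == 0.0:
        return EnrichmentResult(0.0, 0.0, 1.0, n_perm, k)
    draws = _null_position_draws(n, k, n_perm, seed)
    null_es = _es_from_positions(abs_w, draws, n)
    same_sign = null_es > 0 if es > 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        raise ValueError(
            f"no same-sign null draws for ES={es:.4g} (k={k}, n_perm={n_perm}); "
            "NES undefined — increase n_perm"
        )
    null_same = null_es[same_sign]
    nes = es / abs(null_same.mean())
    p = (1 + int((np.abs(null_same) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(es, float(nes), float(p), n_perm, k)


def check_overlap(
    ranked: RankedList,
    gene_set: Iterable[str],
    min_genes: int = MIN_OVERLAP_GENES,
    min_fraction: float = MIN_OVERLAP_FRACTION,
) -> None:
    """Raise :class:`InsufficientOverlapError` if a signature thins out too much."""
    gene_set = set(gene_set)
    k = len(ranked.positions(gene_set))
    if k < min_genes or (len(gene_set) > 0 and k / len(gene_set) < min_fraction):
        raise InsufficientOverlapError(
            f"signature retains {k}/{len(gene_set)} genes in the ranked universe "
            f"(floor: >= {min_genes} genes and >= {min_fraction:.0%})"
        )


def rs_score(
    ranked: RankedList,
    sig_R: Iterable[str],
    sig_S: Iterable[str],
    use_nes: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> float:
    """RS score: enrichment of the sensitivity signature minus the resistance one.

    ES mode (default, used for patient scoring) needs no permutations; NES
    mode normalizes both terms against their permutation nulls.
    """
    if use_nes:
        e_s = prerank_nes(ranked, sig_S, n_perm, seed, weight).nes
        e_r = prerank_nes(ranked, sig_R, n_perm, seed, weight).nes
    else:
        e_s = prerank_es(ranked, sig_S, weight)
        e_r = prerank_es(ranked, sig_R, weight)
    return float(e_s - e_r)


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea_score(
    expr_column: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    exponent: float = 0.25,
) -> float:
    """Single-sample enrichment of a gene set in one expression column.

    Genes are sorted descending by expression (ties by gene id); the gene at
    descending position i carries rank N - i. The score integrates the
    difference between the rank-weighted in-set ECDF and the uniform
    out-of-set ECDF over all positions, normalized by the value the same
    weights would attain with the set packed at the top of the list — hence
    it lies in [-1, 1] and depends on the expression values only through
    their ordering.
    """
    s = pd.Series(expr_column, dtype=float)
    if s.nunique() < 2:
        raise ValueError("ssGSEA undefined: all expression values equal")
    gene_set = set(gene_set)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    n = len(order)
    in_set = np.fromiter((g in gene_set for g in order), dtype=bool, count=n)
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the expression column")
    if k == n:
        raise ValueError("gene set covers every expressed gene")
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene has rank N
    w = ranks**exponent

    def integrated(mask: np.ndarray) -> float:
        hit = np.where(mask, w, 0.0)
        p_in = np.cumsum(hit) / hit.sum()
        p_out = np.cumsum(~mask) / (n - k)
        return float(np.sum(p_in - p_out))

    ideal = np.zeros(n, dtype=bool)
    ideal[:k] = True
    return integrated(in_set) / integrated(ideal)
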