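"""Mechanism clustering of R-to-S shifting compounds.

Each compound's experiments are collapsed to a consensus expression-change
vector: per gene, an indicator of +1 (differential value > 1), -1 (< -1) or 0
(otherwise), summed across the compound's experiments. Compounds are then
clustered hierarchically (Ward linkage on 1 - Pearson correlation between
consensus vectors), the dendrogram is cut at a fixed height, and each
cluster's mechanism is annotated by pre-ranked GSEA of its median consensus
signature against a gene-set collection with Benjamini-Hochberg FDR control.

Pairing Ward linkage with a correlation distance is an approximation — Ward is
defined for squared Euclidean distances; ``linkage_space="euclidean"`` runs
Ward on the raw consensus vectors instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import GeneSetCollection
from .enrichment import (
    InsufficientOverlapError,
    RankedList,
    check_overlap,
    prerank_nes,
    rank_genes,
)

log = logging.getLogger(__name__)

__all__ = [
    "ConsensusVector",
    "ClusterAssignment",
    "consensus_signature",
    "consensus_matrix",
    "cluster_compounds",
    "cluster_ranked_signature",
    "annotate_cluster",
]

DEFAULT_CUT_HEIGHT = 12.0
ANNOTATION_N_PERM = 1000


@dataclass
class ConsensusVector:
    """Per-gene summed {-1, 0, +1} indicators across one compound's experiments."""

    values: pd.Series  # gene -> integer consensus
    n_experiments: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, np.round(v)):
            raise ValueError("consensus values must be integers")
        if np.abs(v).max(initial=0) > self.n_experiments:
            raise ValueError("|consensus| cannot exceed the number of experiments")
        self.values = self.values.astype(int)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # compound -> cluster label (contiguous from 1)
    linkage: np.ndarray
    cut_height: float
    excluded: list[str]
    fallback_k2: bool = False


def _indicator(values: np.ndarray) -> np.ndarray:
    """Odd indicator map with strict thresholds: >1 -> +1, <-1 -> -1, else 0."""
    return (values > 1).astype(int) - (values < -1).astype(int)


def consensus_signature(profiles: pd.DataFrame) -> ConsensusVector:
    """Consensus vector of one compound: indicators summed across its experiment columns."""
    if profiles.shape[1] < 1:
        raise ValueError("need at least one experiment column")
    consensus = _indicator(profiles.to_numpy()).sum(axis=1)
    return ConsensusVector(pd.Series(consensus, index=profiles.index), profiles.shape[1])


def consensus_matrix(matrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Compound x gene consensus matrix from a perturbation matrix and its metadata."""
    meta = meta.set_index("experiment_id")
    out = {}
    for pert_id, grp in meta.groupby("pert_id", sort=True):
        cols = [c for c in matrix.sample_ids if c in set(grp.index)]
        out[pert_id] = consensus_signature(matrix.data[cols]).values
    return pd.DataFrame(out).T


def cluster_compounds(
    consensus: pd.DataFrame,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    linkage_space: str = "correlation",
) -> ClusterAssignment:
    """Ward clustering of compounds (rows) by their consensus vectors.

    Distance is 1 - Pearson r between consensus vectors (or Euclidean on the
    raw vectors with ``linkage_space="euclidean"``). Clusters are the groups
    below ``cut_height``; if the cut leaves a single cluster, fall back to
    k = 2 with a logged notice. Zero-variance compounds are excluded with a
    warning. Labels are contiguous from 1, ordered by first appearance.
    """
    if linkage_space not in ("correlation", "euclidean"):
        raise ValueError(f"unknown linkage_space {linkage_space!r}")
    variances = consensus.var(axis=1)
    excluded = list(consensus.index[variances == 0])
    if excluded:
        log.warning("%d compound(s) with zero-variance consensus excluded: %s",
                    len(excluded), excluded[:5])
    kept = consensus.loc[variances > 0]
    if kept.shape[0] == 0:
        raise ValueError("no compound has a nonzero-variance consensus vector")
    if kept.shape[0] == 1:
        log.warning("single compound after exclusions; returning one singleton cluster")
        return ClusterAssignment(
            pd.Series([1], index=kept.index), np.empty((0, 4)), cut_height, excluded
        )
    X = kept.to_numpy(dtype=float)
    if linkage_space == "correlation":
        corr = np.corrcoef(X)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    else:
        Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    fallback = False
    if len(np.unique(raw)) == 1 and kept.shape[0] >= 2:
        log.info("cut at %g yields one cluster; falling back to k = 2", cut_height)
        raw = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        fallback = True
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return ClusterAssignment(
        pd.Series(labels, index=kept.index, name="cluster"),
        Z, cut_height, excluded, fallback_k2=fallback,
    )


def cluster_ranked_signature(members: list[ConsensusVector]) -> RankedList:
    """Gene-wise median of a cluster's member consensus vectors, ranked descending.

    An even member count takes the arithmetic midpoint of the two central values.
    """
    if not members:
        raise ValueError("need at least one member")
    stacked = pd.concat([m.values for m in members], axis=1)
    if stacked.isna().any().any():
        raise ValueError("members must share the same gene universe")
    return rank_genes(stacked.median(axis=1))


def annotate_cluster(
    cluster_signature: RankedList,
    gene_sets: GeneSetCollection,
    n_perm: int = ANNOTATION_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA of every gene set against the cluster's median signature.

    Sets failing the overlap floor are skipped; nominal p-values are corrected
    by Benjamini-Hochberg across the tested sets; rows sorted by NES descending.
    """
    from statsmodels.stats.multitest import multipletests

    if len(gene_sets) == 0:
        raise ValueError("gene-set collection is empty")
    rows = []
    for name in sorted(gene_sets.sets):
        genes = gene_sets[name]
        try:
            check_overlap(cluster_signature, genes)
        except InsufficientOverlapError as exc:
            log.info("set %r skipped: %s", name, exc)
            continue
        res = prerank_nes(cluster_signature, genes, n_perm=n_perm, seed=seed)
        rows.append(
            {"set": name, "es": res.es, "nes": res.nes, "nominal_p": res.nominal_p,
             "set_size_used": res.set_size_used}
        )
    if not rows:
        raise ValueError("every gene set failed the overlap floor")
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["nominal_p"], method="fdr_bh")[1]
    return table.sort_values("nes", ascending=False).reset_index(drop=True)
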