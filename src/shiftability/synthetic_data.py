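"""Synthetic inputs with known ground truth for every stage of the pipeline.

Three generators emulate the statistical structure of the real inputs at desk
scale: a paired pre/on-treatment cohort with planted response-separating
genes, a level-5-like z-score perturbation matrix with planted R-to-S
shifting experiments, and compound profiles drawn from shared mechanism
templates. Gaussian noise is used throughout — the real quantities are
z-scores and log-ratios, for which a Gaussian is the natural desk-scale
stand-in. All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NON_RESPONDER, RESPONDER, PairedCohort
from .data_io import ExpressionMatrix, ValueKind, validate_metadata

log = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "PerturbationSpec",
    "simulate_cohort",
    "simulate_perturbations",
    "simulate_mechanism_matrix",
]

_CELL_LINES = ["A375", "MCF7", "PC3", "HT29", "HA1E"]


@dataclass(frozen=True)
class CohortSpec:
    """Paired-cohort generator parameters.

    ``effect_size`` is the between-group mean shift of the treatment-induced
    change, in units of its within-group standard deviation (``noise_sd``).
    """

    n_genes: int = 5000
    n_planted_R: int = 200
    n_planted_S: int = 200
    n_responders: int = 20
    n_nonresponders: int = 20
    effect_size: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_planted_R, self.n_planted_S,
               self.n_responders, self.n_nonresponders) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_planted_R + self.n_planted_S > self.n_genes:
            raise ValueError("planted sets must fit disjointly in the gene universe")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class PerturbationSpec:
    """Level-5-like perturbation-matrix generator parameters.

    Planted experiments add ``+planted_magnitude`` to the planted-up (S-like)
    genes and ``-planted_magnitude`` to the planted-down (R-like) genes on top
    of the N(0, background_sd) background. ``low_tas_fraction`` of experiments
    draw a TAS below 0.4 to exercise the quality filter (0 by default: the
    screening design assumes retained experiments).
    """

    n_genes: int = 5000
    n_null_experiments: int = 100
    n_planted_experiments: int = 10
    n_planted_genes: int = 100  # per direction, when explicit sets are not given
    planted_up: frozenset[str] | None = None
    planted_down: frozenset[str] | None = None
    planted_magnitude: float = 2.0
    background_sd: float = 1.0
    n_cell_lines: int = 3
    low_tas_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_magnitude < 0 or self.background_sd <= 0:
            raise ValueError("planted_magnitude >= 0 and background_sd > 0 required")
        if self.planted_up is not None and self.planted_down is not None:
            if set(self.planted_up) & set(self.planted_down):
                raise ValueError("planted_up and planted_down must be disjoint")
        if not 0 <= self.low_tas_fraction <= 1:
            raise ValueError("low_tas_fraction must lie in [0, 1]")
        if self.n_cell_lines < 1 or self.n_cell_lines > len(_CELL_LINES):
            raise ValueError(f"n_cell_lines must be in [1, {len(_CELL_LINES)}]")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> tuple[PairedCohort, dict]:
    """Paired cohort with planted R/S genes.

    Pre-treatment expression ~ N(8, 1) per gene/sample on the log2 scale; the
    on-treatment value adds N(0, noise_sd). Planted R genes get an extra
    ``effect_size * noise_sd`` on-treatment shift in non-responders, planted S
    genes the same shift in responders. Returns the cohort and the truth
    (planted gene lists).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    planted = rng.choice(spec.n_genes, size=spec.n_planted_R + spec.n_planted_S, replace=False)
    planted_R = sorted(genes[i] for i in planted[: spec.n_planted_R])
    planted_S = sorted(genes[i] for i in planted[spec.n_planted_R:])

    patients = [f"R{i:03d}" for i in range(1, spec.n_responders + 1)] + [
        f"N{i:03d}" for i in range(1, spec.n_nonresponders + 1)
    ]
    is_resp = np.array([p.startswith("R") for p in patients])
    n_pat = len(patients)

    pre = rng.normal(8.0, 1.0, size=(spec.n_genes, n_pat))
    post = pre + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_pat))
    shift = spec.effect_size * spec.noise_sd
    r_rows = [genes.index(g) for g in planted_R]
    s_rows = [genes.index(g) for g in planted_S]
    post[np.ix_(r_rows, np.where(~is_resp)[0])] += shift
    post[np.ix_(s_rows, np.where(is_resp)[0])] += shift

    pre_m = ExpressionMatrix(pd.DataFrame(pre, index=genes, columns=patients),
                             ValueKind.LOG2_EXPRESSION)
    post_m = ExpressionMatrix(pd.DataFrame(post, index=genes, columns=patients),
                              ValueKind.LOG2_EXPRESSION)
    response = pd.Series(
        [RESPONDER if r else NON_RESPONDER for r in is_resp], index=patients, name="response"
    )
    cohort = PairedCohort(pre=pre_m, post=post_m, response=response)
    return cohort, {"planted_R": planted_R, "planted_S": planted_S}


def simulate_perturbations(
    spec: PerturbationSpec = PerturbationSpec(),
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Level-5-like z-score matrix with planted R-to-S shifting experiments.

    Metadata rows alternate shRNA and compound perturbagens over round-robin
    cell lines; planted shRNA experiments target a planted-down gene so the
    knockdown-success check is exercised with a consistent truth. Returns the
    matrix, metadata, and the truth (planted experiment ids and gene sets).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    if spec.planted_up is None or spec.planted_down is None:
        chosen = rng.choice(spec.n_genes, size=2 * spec.n_planted_genes, replace=False)
        planted_up = sorted(genes[i] for i in chosen[: spec.n_planted_genes])
        planted_down = sorted(genes[i] for i in chosen[spec.n_planted_genes:])
    else:
        planted_up = sorted(spec.planted_up)
        planted_down = sorted(spec.planted_down)
    up_rows = [genes.index(g) for g in planted_up]
    down_rows = [genes.index(g) for g in planted_down]

    n_total = spec.n_null_experiments + spec.n_planted_experiments
    values = rng.normal(0.0, spec.background_sd, size=(spec.n_genes, n_total))
    null_ids = [f"NULL{i:04d}" for i in range(1, spec.n_null_experiments + 1)]
    planted_ids = [f"SHIFT{i:04d}" for i in range(1, spec.n_planted_experiments + 1)]
    exp_ids = null_ids + planted_ids
    for col in range(spec.n_null_experiments, n_total):
        values[up_rows, col] += spec.planted_magnitude
        values[down_rows, col] -= spec.planted_magnitude

    tas = rng.uniform(0.4, 1.0, size=n_total)
    n_low = int(round(spec.low_tas_fraction * n_total))
    if n_low:
        low_idx = rng.choice(n_total, size=n_low, replace=False)
        tas[low_idx] = rng.uniform(0.0, 0.4 - 1e-9, size=n_low)

    cell_lines = _CELL_LINES[: spec.n_cell_lines]
    meta_rows = []
    for idx, exp_id in enumerate(exp_ids):
        is_shrna = idx % 2 == 0
        planted = exp_id.startswith("SHIFT")
        if is_shrna:
            target = (planted_down[idx % len(planted_down)] if planted
                      else genes[int(rng.integers(spec.n_genes))])
        else:
            target = None
        meta_rows.append(
            {
                "experiment_id": exp_id,
                "pert_id": f"pert_{exp_id}",
                "pert_type": "shRNA" if is_shrna else "compound",
                "target": target,
                "cell_line": cell_lines[idx % len(cell_lines)],
                "dose": None if is_shrna else "10 uM",
                "tas": tas[idx],
            }
        )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=exp_ids), ValueKind.LEVEL5_ZSCORE
    )
    meta = validate_metadata(pd.DataFrame(meta_rows))
    truth = {
        "shifting_experiments": planted_ids,
        "planted_up": planted_up,
        "planted_down": planted_down,
    }
    return matrix, meta, truth


def simulate_mechanism_matrix(
    n_compounds_per_template: int = 10,
    templates: list[dict[str, float]] | None = None,
    noise_sd: float = 0.5,
    n_genes: int = 2000,
    n_experiments_per_compound: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Compound profiles drawn from shared mechanism templates.

    Each template is a gene -> signed value map (defaults: two disjoint
    templates of 100 genes at +2 and 100 at -2 each); every experiment of a
    compound is its template plus N(0, noise_sd). Returns the profile matrix,
    experiment metadata (compound = pert_id), and the truth labels
    (compound -> template index).
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    if templates is None:
        if n_genes < 400:
            raise ValueError("default templates need at least 400 genes")
        templates = [
            {**{g: 2.0 for g in genes[0:100]}, **{g: -2.0 for g in genes[100:200]}},
            {**{g: 2.0 for g in genes[200:300]}, **{g: -2.0 for g in genes[300:400]}},
        ]
    signed_sets = [set(t) for t in templates]
    for a in range(len(signed_sets)):
        for b in range(a + 1, len(signed_sets)):
            if signed_sets[a] & signed_sets[b]:
                raise ValueError("templates must be disjoint in their signed gene sets")

    gene_index = {g: i for i, g in enumerate(genes)}
    columns, col_names, meta_rows, truth = [], [], [], {}
    for t_idx, template in enumerate(templates):
        base = np.zeros(n_genes)
        for g, v in template.items():
            base[gene_index[g]] = v
        for c in range(1, n_compounds_per_template + 1):
            compound = f"cpd_T{t_idx + 1}_{c:02d}"
            truth[compound] = t_idx + 1
            for e in range(1, n_experiments_per_compound + 1):
                exp_id = f"{compound}_exp{e}"
                columns.append(base + rng.normal(0.0, noise_sd, size=n_genes))
                col_names.append(exp_id)
                meta_rows.append(
                    {"experiment_id": exp_id, "pert_id": compound,
                     "pert_type": "compound", "target": None,
                     "cell_line": _CELL_LINES[0], "dose": "10 uM", "tas": 1.0}
                )
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(columns), index=genes, columns=col_names),
        ValueKind.LEVEL5_ZSCORE,
    )
    meta = validate_metadata(pd.DataFrame(meta_rows))
    return matrix, meta, {"labels": truth, "templates": templates}
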