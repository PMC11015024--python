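"""Shift-ability scoring of perturbation transcriptomes and screen integration.

For a perturbation p with a level-5-like differential-expression profile, the
shift ability is

    shift_ability(p) = dNES = NES_S - NES_R

the difference between the normalized enrichment of the sensitivity (S) and
resistance (R) signatures in p's descending-ranked profile. A large positive
value means p suppresses the resistance program while inducing the sensitivity
program — shifting the cell toward an anti-PD-1-sensitive expression state.
Significance is called either against a fixed threshold (>= 3.5, inclusive;
used for compound screens) or against an empirical per-cell-line null of
scored experiments (mean + k.sd, leave-one-perturbagen-out; the default for
shRNA screens, whose null the data themselves provide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, validate_metadata
from .enrichment import (
    InsufficientOverlapError,
    check_overlap,
    prerank_nes,
    rank_genes,
)

log = logging.getLogger(__name__)

__all__ = [
    "ShiftResult",
    "ScreenTable",
    "compute_shift_ability",
    "knockdown_success",
    "call_significant",
    "screen_perturbations",
    "integrate_screens",
]

FIXED_THRESHOLD = 3.5  # compound-screen significance cut, inclusive
KD_THRESHOLD = -1.0  # level-5 z-score at/below which a knockdown counts as successful


@dataclass(frozen=True)
class ShiftResult:
    experiment_id: str
    es_R: float
    es_S: float
    nes_R: float
    nes_S: float
    shift_ability: float  # always nes_S - nes_R
    significant: bool | None = None
    mode: str | None = None  # fixed_threshold / empirical_null
    insufficient_overlap: bool = False
    metadata: Mapping | None = None

    def __post_init__(self) -> None:
        if not self.insufficient_overlap:
            if self.shift_ability != self.nes_S - self.nes_R:
                raise ValueError("shift_ability must equal nes_S - nes_R exactly")


@dataclass
class ScreenTable:
    """One ShiftResult row per retained experiment, plus per-perturbagen aggregates."""

    rows: pd.DataFrame  # experiment_id, pert_id, pert_type, target, cell_line, tas,
    # es_R, es_S, nes_R, nes_S, shift_ability, significant, mode, insufficient_overlap

    def aggregates(self) -> pd.DataFrame:
        """Per (pert_id, cell_line): n_experiments, fraction significant, any-significant.

        A perturbagen shows R-to-S shifting in a cell line iff at least one of
        its experiments there is significant. Overlap-flagged rows are excluded.
        """
        ok = self.rows[~self.rows["insufficient_overlap"]]
        if ok.empty:
            return pd.DataFrame(
                columns=["pert_id", "cell_line", "n_experiments",
                         "n_significant", "fraction_significant", "any_significant"]
            )
        grouped = ok.groupby(["pert_id", "cell_line"], sort=True)
        out = grouped.agg(
            n_experiments=("experiment_id", "size"),
            n_significant=("significant", "sum"),
        ).reset_index()
        out["n_significant"] = out["n_significant"].astype(int)
        out["fraction_significant"] = out["n_significant"] / out["n_experiments"]
        out["any_significant"] = out["n_significant"] >= 1
        return out


def compute_shift_ability(
    profile_column: Mapping[str, float] | pd.Series,
    sig_R: Iterable[str],
    sig_S: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    experiment_id: str = "",
    metadata: Mapping | None = None,
) -> ShiftResult:
    """Shift ability of one perturbation profile: NES_S - NES_R on its ranked genes.

    A signature failing the overlap floor yields a flagged row (excluded from
    aggregates) rather than a score.
    """
    ranked = rank_genes(profile_column)
    try:
        check_overlap(ranked, sig_R)
        check_overlap(ranked, sig_S)
    except InsufficientOverlapError as exc:
        log.warning("experiment %s: %s", experiment_id or "<anon>", exc)
        return ShiftResult(experiment_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                           insufficient_overlap=True, metadata=metadata)
    res_R = prerank_nes(ranked, sig_R, n_perm=n_perm, seed=seed)
    res_S = prerank_nes(ranked, sig_S, n_perm=n_perm, seed=seed)
    return ShiftResult(
        experiment_id=experiment_id,
        es_R=res_R.es,
        es_S=res_S.es,
        nes_R=res_R.nes,
        nes_S=res_S.nes,
        shift_ability=res_S.nes - res_R.nes,
        metadata=metadata,
    )


def knockdown_success(
    profile_column: Mapping[str, float] | pd.Series,
    target_gene: str,
    kd_threshold: float = KD_THRESHOLD,
) -> bool:
    """True iff the shRNA's target gene is itself suppressed (value <= threshold, inclusive)."""
    s = pd.Series(profile_column, dtype=float)
    if target_gene not in s.index:
        raise KeyError(f"target gene {target_gene!r} absent from the profile")
    return bool(s[target_gene] <= kd_threshold)


def call_significant(
    results: list[ShiftResult],
    mode: str = "fixed_threshold",
    fixed_threshold: float = FIXED_THRESHOLD,
    null_scores: Iterable[float] | None = None,
    k_sd: float = 2.0,
    null_pert_types: tuple[str, ...] | None = None,
    min_null: int = 30,
) -> list[ShiftResult]:
    """Flag significant R-to-S shifts.

    fixed_threshold: significant iff shift_ability >= threshold (inclusive).
    empirical_null: significant iff shift_ability >= mean + k_sd * sd of a null
    of scored experiments from the same cell line, excluding every experiment
    of the perturbagen under test (leave-one-perturbagen-out); restrict the
    null to given perturbagen types via ``null_pert_types`` (e.g. ``("shRNA",)``).
    An explicit ``null_scores`` vector overrides the per-cell-line construction.
    """
    if mode not in ("fixed_threshold", "empirical_null"):
        raise ValueError(f"unknown mode {mode!r}")
    scored = [r for r in results if not r.insufficient_overlap]

    if mode == "fixed_threshold":
        return [
            replace(r, significant=(r.shift_ability >= fixed_threshold), mode=mode)
            if not r.insufficient_overlap else r
            for r in results
        ]

    if null_scores is not None:
        null = np.asarray(list(null_scores), dtype=float)
        if len(null) < min_null:
            raise ValueError(f"empirical mode needs >= {min_null} null scores, got {len(null)}")
        cut = null.mean() + k_sd * null.std(ddof=1)
        return [
            replace(r, significant=(r.shift_ability >= cut), mode=mode)
            if not r.insufficient_overlap else r
            for r in results
        ]

    def _meta(r: ShiftResult, key: str):
        return (r.metadata or {}).get(key)

    out = []
    for r in results:
        if r.insufficient_overlap:
            out.append(r)
            continue
        null = [
            o.shift_ability
            for o in scored
            if _meta(o, "cell_line") == _meta(r, "cell_line")
            and _meta(o, "pert_id") != _meta(r, "pert_id")
            and (null_pert_types is None or _meta(o, "pert_type") in null_pert_types)
        ]
        if len(null) < min_null:
            raise ValueError(
                f"cell line {_meta(r, 'cell_line')!r}: only {len(null)} null scores "
                f"(need >= {min_null}) for experiment {r.experiment_id}"
            )
        null = np.asarray(null)
        cut = null.mean() + k_sd * null.std(ddof=1)
        out.append(replace(r, significant=(r.shift_ability >= cut), mode="empirical_null"))
    return out


def screen_perturbations(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    sig_R: Iterable[str],
    sig_S: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "fixed_threshold",
    fixed_threshold: float = FIXED_THRESHOLD,
    k_sd: float = 2.0,
    null_pert_types: tuple[str, ...] | None = None,
) -> ScreenTable:
    """Score every experiment column of a (pre-filtered) perturbation matrix.

    Deterministic under a fixed seed: null draws depend only on (seed, gene
    universe size, effective signature size, n_perm), so every experiment of
    one run shares them.
    """
    meta = validate_metadata(meta).set_index("experiment_id", drop=False)
    missing = set(matrix.sample_ids) - set(meta.index)
    if missing:
        raise ValueError(f"experiments without metadata: {sorted(missing)[:5]}")
    sig_R, sig_S = set(sig_R), set(sig_S)
    results = []
    for n_done, exp_id in enumerate(matrix.sample_ids, 1):
        results.append(
            compute_shift_ability(
                matrix.data[exp_id], sig_R, sig_S, n_perm=n_perm, seed=seed,
                experiment_id=exp_id, metadata=meta.loc[exp_id].to_dict(),
            )
        )
        if n_done % 500 == 0:
            log.info("screened %d/%d experiments", n_done, matrix.shape[1])
    if not results:
        log.warning("screen produced no rows")
    results = call_significant(
        results, mode=mode, fixed_threshold=fixed_threshold, k_sd=k_sd,
        null_pert_types=null_pert_types,
    )
    rows = pd.DataFrame(
        [
            {
                "experiment_id": r.experiment_id,
                "pert_id": (r.metadata or {}).get("pert_id"),
                "pert_type": (r.metadata or {}).get("pert_type"),
                "target": (r.metadata or {}).get("target"),
                "cell_line": (r.metadata or {}).get("cell_line"),
                "tas": (r.metadata or {}).get("tas"),
                "es_R": r.es_R,
                "es_S": r.es_S,
                "nes_R": r.nes_R,
                "nes_S": r.nes_S,
                "shift_ability": r.shift_ability,
                # direction bookkeeping: the perturbation suppresses the R
                # program iff NES_R < 0 and induces the S program iff NES_S > 0
                "suppresses_R": bool(r.nes_R < 0),
                "induces_S": bool(r.nes_S > 0),
                "significant": r.significant,
                "mode": r.mode,
                "insufficient_overlap": r.insufficient_overlap,
            }
            for r in results
        ]
    )
    return ScreenTable(rows)


def integrate_screens(
    shrna_table: ScreenTable,
    compound_table: ScreenTable,
    compound_targets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Genes whose genetic and pharmacological inhibition shift R-to-S consistently.

    A gene is a consistent synergy target iff some cell line has both (a) a
    significant shRNA experiment targeting it and (b) a significant experiment
    of a compound annotated to it. Returns one evidence row per supporting
    (gene, cell line, shRNA experiment, compound experiment) triple.
    """
    sh = shrna_table.rows
    sh = sh[(sh["pert_type"] == "shRNA") & (sh["significant"] == True)  # noqa: E712
            & ~sh["insufficient_overlap"]]
    cp = compound_table.rows
    cp = cp[(cp["pert_type"] == "compound") & (cp["significant"] == True)  # noqa: E712
            & ~cp["insufficient_overlap"]]

    target_to_compounds: dict[str, set[str]] = {}
    for compound, genes in compound_targets.items():
        for g in genes:
            target_to_compounds.setdefault(g, set()).add(compound)
    unannotated = set(cp["pert_id"]) - set(compound_targets)
    if unannotated:
        log.info("%d significant compound(s) lack target annotation; skipped", len(unannotated))

    evidence = []
    for (gene, cell_line), sh_grp in sh.groupby(["target", "cell_line"]):
        compounds = target_to_compounds.get(gene, set())
        cp_grp = cp[(cp["pert_id"].isin(compounds)) & (cp["cell_line"] == cell_line)]
        if cp_grp.empty:
            continue
        for _, sh_row in sh_grp.iterrows():
            for _, cp_row in cp_grp.iterrows():
                evidence.append(
                    {
                        "gene": gene,
                        "cell_line": cell_line,
                        "shrna_experiment": sh_row["experiment_id"],
                        "compound": cp_row["pert_id"],
                        "compound_experiment": cp_row["experiment_id"],
                    }
                )
    return pd.DataFrame(
        evidence,
        columns=["gene", "cell_line", "shrna_experiment", "compound", "compound_experiment"],
    )
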