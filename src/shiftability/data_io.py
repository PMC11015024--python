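"""Readers/writers for the formats the pipeline touches, and perturbation filters.

The interchange formats are deliberately boring: GCT 1.3 text for expression and
differential matrices (the carrier used for Connectivity-Map level-5 z-score
profiles), GMT for gene sets, and TSV for cohort expression/clinical tables.
Gene and sample identifiers are opaque, case-sensitive strings; no aliasing or
identifier updating is ever attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ValueKind",
    "ExpressionMatrix",
    "GeneSetCollection",
    "METADATA_COLUMNS",
    "read_gct",
    "write_gct",
    "read_gctx",
    "read_gmt",
    "write_gmt",
    "read_cohort_tables",
    "filter_perturbations",
    "validate_metadata",
]


class ValueKind(str, Enum):
    """What the numbers in an :class:`ExpressionMatrix` mean."""

    LOG2_EXPRESSION = "log2_expression"
    LEVEL5_ZSCORE = "level5_zscore"
    DELTA_LOG2FC = "delta_log2fc"


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression, level-5 z-scores, or deltas.

    Wraps a pandas DataFrame (index = gene ids, columns = sample ids) and
    enforces the integrity the downstream statistics assume: unique ids, no
    missing values, and a declared value kind.
    """

    data: pd.DataFrame
    value_kind: ValueKind = ValueKind.LOG2_EXPRESSION
    #: for delta matrices: how the per-column changes were obtained
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.value_kind = ValueKind(self.value_kind)
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        dup_g = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_g):
            raise ValueError(f"duplicate gene id(s): {list(dup_g)[:5]}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_s):
            raise ValueError(f"duplicate sample id(s): {list(dup_s)[:5]}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values after load")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]


#: canonical per-experiment metadata schema (one row per matrix column)
METADATA_COLUMNS = ["experiment_id", "pert_id", "pert_type", "target", "cell_line", "dose", "tas"]

# column-header aliases seen in CMAP-style GCT files
_META_ALIASES = {
    "pert_id": "pert_id",
    "pert_iname": "pert_id",
    "pert_type": "pert_type",
    "target": "target",
    "cmap_name": "target",
    "cell_line": "cell_line",
    "cell_iname": "cell_line",
    "dose": "dose",
    "pert_idose": "dose",
    "tas": "tas",
}

_PERT_TYPE_ALIASES = {
    "trt_sh": "shRNA",
    "trt_sh.cgs": "shRNA",
    "shrna": "shRNA",
    "shRNA": "shRNA",
    "trt_cp": "compound",
    "compound": "compound",
}


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a perturbation-metadata table.

    Requires unique ``experiment_id``; ``tas`` in [0, 1]; shRNA rows must carry
    a gene-identifier target.
    """
    meta = meta.copy()
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    if meta["experiment_id"].duplicated().any():
        dups = meta.loc[meta["experiment_id"].duplicated(), "experiment_id"].tolist()
        raise ValueError(f"duplicate experiment id(s): {dups[:5]}")
    meta["pert_type"] = meta["pert_type"].map(lambda v: _PERT_TYPE_ALIASES.get(str(v), v))
    tas = pd.to_numeric(meta["tas"], errors="coerce")
    if tas.isna().any():
        log.warning("%d experiments lack a TAS value; treating as 1.0", int(tas.isna().sum()))
        tas = tas.fillna(1.0)
    if ((tas < 0) | (tas > 1)).any():
        raise ValueError("tas values must lie in [0, 1]")
    meta["tas"] = tas
    sh = meta["pert_type"] == "shRNA"
    missing_target = sh & (meta["target"].isna() | (meta["target"].astype(str) == ""))
    if missing_target.any():
        bad = meta.loc[missing_target, "experiment_id"].tolist()
        raise ValueError(f"shRNA experiment(s) without a gene target: {bad[:5]}")
    return meta[METADATA_COLUMNS]


# ---------------------------------------------------------------------------
# GCT 1.3


def read_gct(path: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read a GCT 1.3 text file into a matrix plus per-column metadata.

    Column-metadata header rows whose names match the CMAP-style fields
    (pert_id/pert_iname, pert_type, target, cell_line/cell_iname,
    dose/pert_idose, tas) are mapped onto the canonical metadata schema; a file
    without metadata rows yields a minimal table with experiment ids only.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"{path}: first line {version!r} is not a GCT version tag")
        dims = fh.readline().split()
        if len(dims) not in (2, 4) or not all(d.lstrip("-").isdigit() for d in dims):
            raise ValueError(f"{path}: malformed GCT dimension line {dims!r}")
        nrow, ncol = int(dims[0]), int(dims[1])
        nrmeta, ncmeta = (int(dims[2]), int(dims[3])) if len(dims) == 4 else (0, 0)
        body = pd.read_csv(fh, sep="\t", header=0, index_col=0, dtype=str)
    sample_ids = [str(c) for c in body.columns[nrmeta:]]
    col_meta_rows = body.iloc[:ncmeta, nrmeta:]
    data_block = body.iloc[ncmeta:, nrmeta:]
    gene_ids = [str(g) for g in data_block.index]
    if len(gene_ids) != nrow or len(sample_ids) != ncol:
        raise ValueError(
            f"{path}: dimension line promises {nrow}x{ncol}, "
            f"found {len(gene_ids)}x{len(sample_ids)}"
        )
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dup = next(g for g in gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample id(s)")
    values = data_block.astype(float)
    values.index = pd.Index(gene_ids, name="id")
    matrix = ExpressionMatrix(values, ValueKind.LEVEL5_ZSCORE)

    meta = pd.DataFrame({"experiment_id": sample_ids})
    for raw_name, row in col_meta_rows.iterrows():
        mapped = _META_ALIASES.get(str(raw_name))
        if mapped is not None:
            meta[mapped] = row.to_numpy()
        else:
            log.debug("GCT column-metadata field %r not mapped", raw_name)
    return matrix, validate_metadata(meta)


def write_gct(matrix: ExpressionMatrix, path: str | Path, meta: pd.DataFrame | None = None) -> None:
    """Write a matrix (and optional per-column metadata) as GCT 1.3 text."""
    path = Path(path)
    meta_fields = []
    if meta is not None:
        meta = validate_metadata(meta).set_index("experiment_id")
        meta = meta.loc[matrix.sample_ids]
        meta_fields = [c for c in meta.columns if meta[c].notna().any()]
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\t0\t{len(meta_fields)}\n")
        fh.write("id\t" + "\t".join(matrix.sample_ids) + "\n")
        for field_name in meta_fields:
            vals = ["" if pd.isna(v) else str(v) for v in meta[field_name]]
            fh.write(field_name + "\t" + "\t".join(vals) + "\n")
        matrix.data.to_csv(fh, sep="\t", header=False, float_format="%.6g")


def read_gctx(path: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read the HDF5-backed GCTX dialect (read-only path; same interface as GCT)."""
    import h5py

    with h5py.File(path, "r") as f:
        values = np.asarray(f["/0/DATA/0/matrix"])
        rows = [s.decode() if isinstance(s, bytes) else str(s) for s in f["/0/META/ROW/id"][:]]
        cols = [s.decode() if isinstance(s, bytes) else str(s) for s in f["/0/META/COL/id"][:]]
    if values.shape == (len(cols), len(rows)):  # GCTX stores column-major
        values = values.T
    df = pd.DataFrame(values, index=rows, columns=cols)
    matrix = ExpressionMatrix(df, ValueKind.LEVEL5_ZSCORE)
    meta = validate_metadata(pd.DataFrame({"experiment_id": cols}))
    return matrix, meta


# ---------------------------------------------------------------------------
# GMT


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty unique-member sets."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per set (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not genes:
                log.warning("%s:%d: set %r has no genes; skipped", path, lineno, name)
                continue
            uniq = frozenset(genes)
            if len(uniq) < len(genes):
                log.warning(
                    "%s:%d: %d duplicate gene(s) within set %r deduplicated",
                    path, lineno, len(genes) - len(uniq), name,
                )
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Cohort tables


def read_cohort_tables(
    expr_path: str | Path | tuple[str | Path, str | Path],
    clinical_path: str | Path,
    merge_biopsies: bool = False,
):
    """Read a paired pre/on-treatment cohort from TSV tables.

    ``expr_path`` is a genes x samples TSV (first column gene id), or a
    ``(pre_path, post_path)`` pair whose gene lists are intersected (dropped
    genes are logged). The clinical TSV maps sample_id to patient_id,
    timepoint (pre/post; "on" accepted as post) and response
    (responder/non-responder/unknown). Patients lacking either timepoint or
    with unknown response are dropped with a logged count. Multiple biopsies
    per patient-timepoint are an error unless ``merge_biopsies`` is set, in
    which case they are averaged gene-wise.
    """
    from .cohort import PairedCohort, merge_biopsies as _merge

    if isinstance(expr_path, tuple):
        a = pd.read_csv(expr_path[0], sep="\t", index_col=0)
        b = pd.read_csv(expr_path[1], sep="\t", index_col=0)
        common = a.index.intersection(b.index)
        dropped = (len(a.index) - len(common)) + (len(b.index) - len(common))
        if len(common) == 0:
            raise ValueError("pre/post expression files share no genes")
        if dropped:
            log.info("gene lists intersected across timepoint files; %d row(s) dropped", dropped)
        expr = pd.concat([a.loc[common], b.loc[common]], axis=1)
    else:
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)

    clin = pd.read_csv(clinical_path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "timepoint", "response"}
    if not required.issubset(clin.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    clin["timepoint"] = clin["timepoint"].str.lower().replace({"on": "post"})
    if not clin["timepoint"].isin(["pre", "post"]).all():
        raise ValueError("timepoint must be pre/post (or 'on')")
    clin["response"] = clin["response"].str.lower()

    unknown = clin.loc[~clin["response"].isin(["responder", "non-responder"]), "patient_id"]
    if len(unknown):
        log.info("%d patient(s) with unknown response excluded", unknown.nunique())
    clin = clin[clin["response"].isin(["responder", "non-responder"])]

    missing = set(clin["sample_id"]) - set(expr.columns)
    if missing:
        raise ValueError(f"clinical sample(s) absent from expression table: {sorted(missing)[:5]}")

    pre_cols: dict[str, list[str]] = {}
    post_cols: dict[str, list[str]] = {}
    response: dict[str, str] = {}
    for _, row in clin.iterrows():
        d = pre_cols if row["timepoint"] == "pre" else post_cols
        d.setdefault(row["patient_id"], []).append(row["sample_id"])
        response[row["patient_id"]] = row["response"]

    patients = sorted(p for p in response if pre_cols.get(p) and post_cols.get(p))
    n_dropped = len(response) - len(patients)
    if n_dropped:
        log.info("%d patient(s) lacking a pre or post sample excluded", n_dropped)
    if not patients:
        raise ValueError("no patient has both a pre and a post sample with known response")

    def build(side: Mapping[str, list[str]], kind: str) -> pd.DataFrame:
        cols = {}
        for p in patients:
            samples = side[p]
            if len(samples) > 1 and not merge_biopsies:
                raise ValueError(
                    f"patient {p!r} has {len(samples)} {kind} samples; "
                    "pass merge_biopsies=True to average them"
                )
            cols[p] = expr[samples].mean(axis=1)
        return pd.DataFrame(cols)

    pre = ExpressionMatrix(build(pre_cols, "pre"), ValueKind.LOG2_EXPRESSION)
    post = ExpressionMatrix(build(post_cols, "post"), ValueKind.LOG2_EXPRESSION)
    labels = pd.Series({p: response[p] for p in patients}, name="response")
    return PairedCohort(pre=pre, post=post, response=labels)


# ---------------------------------------------------------------------------
# Perturbation filters


def filter_perturbations(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    min_tas: float = 0.4,
    gene_space: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop low-TAS experiments and project onto a fixed gene space.

    TAS filtering is inclusive (an experiment at exactly ``min_tas`` is kept);
    output gene order follows ``gene_space``. Idempotent by construction.
    """
    if not 0 <= min_tas <= 1:
        raise ValueError("min_tas must lie in [0, 1]")
    meta = validate_metadata(meta)
    keep = meta["tas"] >= min_tas
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("TAS filter (>= %g): %d experiment(s) dropped", min_tas, n_dropped)
    kept_meta = meta[keep].reset_index(drop=True)
    kept_cols = [c for c in matrix.sample_ids if c in set(kept_meta["experiment_id"])]

    if gene_space is not None:
        if len(gene_space) == 0:
            raise ValueError("gene_space must be non-empty")
        present = [g for g in gene_space if g in matrix.data.index]
        n_missing = len(gene_space) - len(present)
        if n_missing:
            log.info("%d gene-space id(s) absent from the matrix", n_missing)
    else:
        present = matrix.gene_ids

    if not kept_cols or not present:
        raise ValueError(
            "no experiments/genes left after filtering; review min_tas and gene_space"
        )
    out = ExpressionMatrix(matrix.data.loc[present, kept_cols], matrix.value_kind)
    return out, kept_meta
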