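import numpy as np
import pandas as pd
import pytest

from shiftability import ExpressionMatrix, PairedCohort, ValueKind
from shiftability.enrichment import RankedList


@pytest.fixture
def four_gene_ranked() -> RankedList:
    """The hand-derived worked example: ES({g1}) = +1, ES({g4}) = -1."""
    return RankedList(["g1", "g2", "g3", "g4"], [2.0, 1.0, -1.0, -2.0])


@pytest.fixture
def tiny_cohort() -> PairedCohort:
    """8 patients x 20 genes; genes d0/d1 separate responders from non-responders."""
    rng = np.random.default_rng(42)
    genes = [f"d{i}" for i in range(20)]
    patients = [f"P{i}" for i in range(8)]
    labels = ["responder"] * 4 + ["non-responder"] * 4
    pre = rng.normal(8, 1, size=(20, 8))
    post = pre + rng.normal(0, 0.3, size=(20, 8))
    post[0, :4] += 3.0  # d0: S-like, up in responders
    post[1, 4:] += 3.0  # d1: R-like, up in non-responders
    make = lambda v: ExpressionMatrix(
        pd.DataFrame(v, index=genes, columns=patients), ValueKind.LOG2_EXPRESSION
    )
    return PairedCohort(
        pre=make(pre), post=make(post),
        response=pd.Series(labels, index=patients),
    )


@pytest.fixture
def gct_text() -> str:
    """2-gene x 2-sample GCT 1.3 fixture with CMAP-style column metadata."""
    return (
        "#1.3\n"
        "2\t2\t0\t4\n"
        "id\tE1\tE2\n"
        "pert_id\tcpdA\tshB\n"
        "pert_type\ttrt_cp\ttrt_sh\n"
        "target\t\tEGFR\n"
        "tas\t0.9\t0.5\n"
        "TP53\t1.5\t-0.5\n"
        "MYC\t-2.0\t0.25\n"
    )
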