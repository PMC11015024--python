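import numpy as np
import pandas as pd
import pytest

from shiftability import (
    ExpressionMatrix,
    ValueKind,
    filter_perturbations,
    read_cohort_tables,
    read_gct,
    read_gmt,
    write_gct,
)
from shiftability.data_io import validate_metadata


class TestGct:
    def test_small_fixture_parses(self, gct_text, tmp_path):
        p = tmp_path / "x.gct"
        p.write_text(gct_text)
        matrix, meta = read_gct(p)
        assert matrix.gene_ids == ["TP53", "MYC"]
        assert matrix.sample_ids == ["E1", "E2"]
        assert matrix.value_kind is ValueKind.LEVEL5_ZSCORE
        np.testing.assert_allclose(matrix.values, [[1.5, -0.5], [-2.0, 0.25]])
        assert list(meta["pert_type"]) == ["compound", "shRNA"]
        np.testing.assert_allclose(meta["tas"], [0.9, 0.5])

    def test_duplicate_gene_id_names_the_offender(self, tmp_path):
        p = tmp_path / "dup.gct"
        p.write_text("#1.3\n2\t1\t0\t0\nid\tS1\nTP53\t1\nTP53\t2\n")
        with pytest.raises(ValueError, match="TP53"):
            read_gct(p)

    def test_malformed_dimension_line(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("#1.3\ntwo\tsamples\nid\tS1\n")
        with pytest.raises(ValueError, match="dimension"):
            read_gct(p)

    def test_dimension_mismatch(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("#1.3\n3\t1\t0\t0\nid\tS1\nA\t1\nB\t2\n")
        with pytest.raises(ValueError, match="promises"):
            read_gct(p)

    def test_round_trip_preserves_values_and_ids(self, gct_text, tmp_path):
        p1, p2 = tmp_path / "a.gct", tmp_path / "b.gct"
        p1.write_text(gct_text)
        matrix, meta = read_gct(p1)
        write_gct(matrix, p2, meta)
        again, meta2 = read_gct(p2)
        assert again.gene_ids == matrix.gene_ids
        assert again.sample_ids == matrix.sample_ids
        np.testing.assert_allclose(again.values, matrix.values, atol=1e-6)
        assert list(meta2["pert_type"]) == list(meta["pert_type"])


class TestGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("SETA\tdesc\tg1\tg2\n")
        sets = read_gmt(p)
        assert sets["SETA"] == {"g1", "g2"}

    def test_duplicate_gene_deduplicated_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.gmt"
        p.write_text("SETA\tdesc\tg1\tg2\tg1\n")
        with caplog.at_level("WARNING"):
            sets = read_gmt(p)
        assert len(sets["SETA"]) == 2
        assert "deduplicated" in caplog.text

    def test_duplicate_set_name_is_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("SETA\td\tg1\nSETA\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_empty_gene_list_skipped(self, tmp_path, caplog):
        p = tmp_path / "s.gmt"
        p.write_text("EMPTY\td\t\nOK\td\tg1\n")
        with caplog.at_level("WARNING"):
            sets = read_gmt(p)
        assert list(sets.sets) == ["OK"]


class TestCohortTables:
    @staticmethod
    def _write(tmp_path, clinical_rows, genes=("gA", "gB"), samples=None):
        samples = samples or sorted({r[0] for r in clinical_rows})
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(8, 1, size=(len(genes), len(samples))),
            index=list(genes), columns=samples,
        )
        ep = tmp_path / "expr.tsv"
        expr.to_csv(ep, sep="\t")
        cp = tmp_path / "clin.tsv"
        pd.DataFrame(
            clinical_rows, columns=["sample_id", "patient_id", "timepoint", "response"]
        ).to_csv(cp, sep="\t", index=False)
        return ep, cp

    def test_patient_missing_post_excluded(self, tmp_path):
        rows = [
            ("s1", "P1", "pre", "responder"), ("s2", "P1", "post", "responder"),
            ("s3", "P2", "pre", "non-responder"), ("s4", "P2", "post", "non-responder"),
            ("s5", "P3", "pre", "responder"),
        ]
        cohort = read_cohort_tables(*self._write(tmp_path, rows))
        assert cohort.patients == ["P1", "P2"]

    def test_unknown_response_excluded(self, tmp_path):
        rows = [
            ("s1", "P1", "pre", "responder"), ("s2", "P1", "post", "responder"),
            ("s3", "P2", "pre", "unknown"), ("s4", "P2", "post", "unknown"),
            ("s5", "P3", "pre", "non-responder"), ("s6", "P3", "post", "non-responder"),
        ]
        cohort = read_cohort_tables(*self._write(tmp_path, rows))
        assert cohort.patients == ["P1", "P3"]

    def test_two_pre_samples_without_merge_directive_is_error(self, tmp_path):
        rows = [
            ("s1", "P1", "pre", "responder"), ("s1b", "P1", "pre", "responder"),
            ("s2", "P1", "post", "responder"),
            ("s3", "P2", "pre", "non-responder"), ("s4", "P2", "post", "non-responder"),
        ]
        ep, cp = self._write(tmp_path, rows)
        with pytest.raises(ValueError, match="merge_biopsies"):
            read_cohort_tables(ep, cp)
        cohort = read_cohort_tables(ep, cp, merge_biopsies=True)
        assert cohort.patients == ["P1", "P2"]

    def test_two_file_gene_mismatch_intersected(self, tmp_path):
        rng = np.random.default_rng(1)
        pre = pd.DataFrame(rng.normal(size=(3, 1)), index=["gA", "gB", "gC"], columns=["s1"])
        post = pd.DataFrame(rng.normal(size=(2, 1)), index=["gA", "gB"], columns=["s2"])
        pp, qp = tmp_path / "pre.tsv", tmp_path / "post.tsv"
        pre.to_csv(pp, sep="\t")
        post.to_csv(qp, sep="\t")
        cp = tmp_path / "clin.tsv"
        pd.DataFrame(
            [("s1", "P1", "pre", "responder"), ("s2", "P1", "post", "responder")],
            columns=["sample_id", "patient_id", "timepoint", "response"],
        ).to_csv(cp, sep="\t", index=False)
        cohort = read_cohort_tables((pp, qp), cp)
        assert cohort.pre.gene_ids == ["gA", "gB"]


class TestFilterPerturbations:
    @staticmethod
    def _matrix(tas_values):
        n = len(tas_values)
        ids = [f"E{i}" for i in range(n)]
        data = pd.DataFrame(
            np.arange(3 * n, dtype=float).reshape(3, n),
            index=["gA", "gB", "gC"], columns=ids,
        )
        meta = pd.DataFrame(
            {"experiment_id": ids, "pert_id": ids, "pert_type": "compound", "tas": tas_values}
        )
        return ExpressionMatrix(data, ValueKind.LEVEL5_ZSCORE), meta

    def test_threshold_is_inclusive(self):
        matrix, meta = self._matrix([0.3, 0.4, 0.5])
        out, kept = filter_perturbations(matrix, meta, min_tas=0.4)
        assert list(kept["experiment_id"]) == ["E1", "E2"]
        assert out.shape[1] == 2

    def test_min_tas_zero_keeps_all(self):
        matrix, meta = self._matrix([0.0, 0.2, 0.9])
        out, kept = filter_perturbations(matrix, meta, min_tas=0.0)
        assert out.shape[1] == 3

    def test_gene_space_projection_order_and_missing(self):
        matrix, meta = self._matrix([0.9, 0.9])
        out, _ = filter_perturbations(matrix, meta, 0.4, gene_space=["gC", "gA", "gZ"])
        assert out.gene_ids == ["gC", "gA"]  # gene_space order, missing id dropped

    def test_idempotent(self):
        matrix, meta = self._matrix([0.3, 0.5, 0.7])
        once = filter_perturbations(matrix, meta, 0.4, gene_space=["gB", "gA"])
        twice = filter_perturbations(once[0], once[1], 0.4, gene_space=["gB", "gA"])
        pd.testing.assert_frame_equal(once[0].data, twice[0].data)
        pd.testing.assert_frame_equal(once[1], twice[1])

    def test_empty_result_is_error(self):
        matrix, meta = self._matrix([0.1, 0.2])
        with pytest.raises(ValueError, match="review"):
            filter_perturbations(matrix, meta, min_tas=0.9)


class TestInvariants:
    def test_duplicate_sample_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s", "s"])
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(df, ValueKind.LOG2_EXPRESSION)

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(df, ValueKind.LOG2_EXPRESSION)

    def test_tas_out_of_range_rejected(self):
        meta = pd.DataFrame({"experiment_id": ["e"], "tas": [1.5]})
        with pytest.raises(ValueError, match="tas"):
            validate_metadata(meta)

    def test_shrna_requires_target(self):
        meta = pd.DataFrame(
            {"experiment_id": ["e"], "pert_type": ["shRNA"], "tas": [0.5]}
        )
        with pytest.raises(ValueError, match="target"):
            validate_metadata(meta)
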