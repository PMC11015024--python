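import numpy as np
import pandas as pd
import pytest

from shiftability import (
    call_significant,
    compute_shift_ability,
    integrate_screens,
    knockdown_success,
    screen_perturbations,
    simulate_perturbations,
)
from shiftability.shift_ability import ScreenTable, ShiftResult
from shiftability.synthetic_data import PerturbationSpec


def _profile(seed=0, n=200):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])


def _sigs(profile, k=20):
    order = profile.sort_values(ascending=False).index
    return set(order[-k:]), set(order[:k])  # (R-like bottom, S-like top)


class TestComputeShiftAbility:
    def test_identity_and_zero_for_identical_signatures(self):
        profile = _profile(1)
        sig, _ = _sigs(profile)
        res = compute_shift_ability(profile, sig, sig, n_perm=200, seed=1)
        assert res.shift_ability == res.nes_S - res.nes_R
        assert res.shift_ability == 0.0

    def test_signature_swap_negates(self):
        profile = _profile(2)
        sig_R, sig_S = _sigs(profile)
        fwd = compute_shift_ability(profile, sig_R, sig_S, n_perm=200, seed=2)
        rev = compute_shift_ability(profile, sig_S, sig_R, n_perm=200, seed=2)
        assert fwd.shift_ability == pytest.approx(-rev.shift_ability)

    def test_planted_shift_exceeds_matched_null(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i:03d}" for i in range(500)]
        sig_S = set(genes[:25])
        sig_R = set(genes[25:50])
        planted = pd.Series(rng.normal(size=500), index=genes)
        planted[list(sig_S)] += 2.0
        planted[list(sig_R)] -= 2.0
        obs = compute_shift_ability(planted, sig_R, sig_S, n_perm=200, seed=3)
        null = [
            compute_shift_ability(
                pd.Series(rng.normal(size=500), index=genes), sig_R, sig_S,
                n_perm=200, seed=3,
            ).shift_ability
            for _ in range(40)
        ]
        assert obs.shift_ability > np.quantile(null, 0.95)

    def test_insufficient_overlap_flagged_not_raised(self):
        profile = _profile(4, n=50)
        res = compute_shift_ability(profile, {"zz1", "zz2"}, set(profile.index[:20]),
                                    n_perm=200, seed=0)
        assert res.insufficient_overlap


class TestKnockdownSuccess:
    def test_strong_knockdown(self):
        assert knockdown_success(pd.Series({"A": -2.0, "B": 0.0}), "A")

    def test_upregulated_target_fails(self):
        assert not knockdown_success(pd.Series({"A": 0.5}), "A")

    def test_boundary_inclusive(self):
        assert knockdown_success(pd.Series({"A": -1.0}), "A")

    def test_absent_target_names_gene(self):
        with pytest.raises(KeyError, match="MYC"):
            knockdown_success(pd.Series({"A": -2.0}), "MYC")


def _result(shift, exp_id="e", cell_line="A375", pert_id=None, pert_type="shRNA"):
    return ShiftResult(
        experiment_id=exp_id, es_R=0.0, es_S=0.0, nes_R=0.0, nes_S=shift,
        shift_ability=shift,
        metadata={"cell_line": cell_line, "pert_id": pert_id or exp_id,
                  "pert_type": pert_type},
    )


class TestCallSignificant:
    def test_fixed_threshold_inclusive(self):
        results = call_significant(
            [_result(3.6, "a"), _result(3.5, "b"), _result(3.4, "c")],
            mode="fixed_threshold",
        )
        assert [r.significant for r in results] == [True, True, False]

    def test_empirical_with_explicit_null(self):
        rng = np.random.default_rng(0)
        null = rng.normal(0, 1, size=100)
        results = call_significant(
            [_result(5.0, "hot"), _result(0.5, "cold")],
            mode="empirical_null", null_scores=null,
        )
        assert results[0].significant and not results[1].significant

    def test_short_null_is_error(self):
        with pytest.raises(ValueError, match=">= 30"):
            call_significant([_result(5.0)], mode="empirical_null",
                             null_scores=np.zeros(10))

    def test_leave_one_perturbagen_out_null(self):
        rng = np.random.default_rng(1)
        rows = [_result(float(rng.normal()), f"e{i}", pert_id=f"p{i}") for i in range(40)]
        rows.append(_result(10.0, "hot", pert_id="hot"))
        out = call_significant(rows, mode="empirical_null")
        assert out[-1].significant

    def test_eq2_identity_on_rows(self):
        for r in [_result(1.0), _result(-2.5)]:
            assert r.shift_ability - (r.nes_S - r.nes_R) == 0.0


@pytest.fixture(scope="module")
def small_screen():
    spec = PerturbationSpec(
        n_genes=400, n_null_experiments=40, n_planted_experiments=5,
        n_planted_genes=25, seed=8, n_cell_lines=1,
    )
    matrix, meta, truth = simulate_perturbations(spec)
    table = screen_perturbations(
        matrix, meta, set(truth["planted_down"]), set(truth["planted_up"]),
        n_perm=200, seed=8, mode="empirical_null",
    )
    return table, truth


class TestScreen:
    def test_one_row_per_experiment(self, small_screen):
        table, _ = small_screen
        assert len(table.rows) == 45
        assert table.rows["experiment_id"].is_unique

    def test_planted_experiments_rank_top(self, small_screen):
        table, truth = small_screen
        top = set(table.rows.nlargest(5, "shift_ability")["experiment_id"])
        assert top == set(truth["shifting_experiments"])

    def test_aggregate_any_significant_rule(self):
        rows = pd.DataFrame(
            {
                "experiment_id": ["e1", "e2", "e3"],
                "pert_id": ["cpd", "cpd", "cpd"],
                "pert_type": ["compound"] * 3,
                "target": [None] * 3,
                "cell_line": ["A375"] * 3,
                "tas": [1.0] * 3,
                "es_R": 0.0, "es_S": 0.0, "nes_R": 0.0, "nes_S": 0.0,
                "shift_ability": [4.0, 1.0, 0.0],
                "significant": [True, False, False],
                "mode": "fixed_threshold",
                "insufficient_overlap": False,
            }
        )
        agg = ScreenTable(rows).aggregates()
        assert len(agg) == 1
        assert bool(agg.loc[0, "any_significant"])
        assert agg.loc[0, "fraction_significant"] == pytest.approx(1 / 3)

    def test_screen_deterministic(self):
        spec = PerturbationSpec(
            n_genes=300, n_null_experiments=10, n_planted_experiments=2,
            n_planted_genes=20, seed=9,
        )
        matrix, meta, truth = simulate_perturbations(spec)
        args = (matrix, meta, set(truth["planted_down"]), set(truth["planted_up"]))
        a = screen_perturbations(*args, n_perm=200, seed=4)
        b = screen_perturbations(*args, n_perm=200, seed=4)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_negated_profiles_negate_shift(self):
        """ES antisymmetry is exact; the NES-based score is antisymmetric up to
        the asymmetry of the same-sign permutation-null means."""
        spec = PerturbationSpec(
            n_genes=300, n_null_experiments=6, n_planted_experiments=2,
            n_planted_genes=20, seed=10,
        )
        matrix, meta, truth = simulate_perturbations(spec)
        sig_R, sig_S = set(truth["planted_down"]), set(truth["planted_up"])
        fwd = screen_perturbations(matrix, meta, sig_R, sig_S, n_perm=200, seed=5)
        neg_matrix = type(matrix)(-matrix.data, matrix.value_kind)
        rev = screen_perturbations(neg_matrix, meta, sig_R, sig_S, n_perm=200, seed=5)
        np.testing.assert_allclose(fwd.rows["es_S"], -rev.rows["es_S"], atol=1e-12)
        np.testing.assert_allclose(fwd.rows["es_R"], -rev.rows["es_R"], atol=1e-12)
        np.testing.assert_allclose(
            fwd.rows["shift_ability"], -rev.rows["shift_ability"], rtol=0.1, atol=0.05
        )


class TestIntegrateScreens:
    @staticmethod
    def _table(rows):
        cols = ["experiment_id", "pert_id", "pert_type", "target", "cell_line",
                "tas", "es_R", "es_S", "nes_R", "nes_S", "shift_ability",
                "significant", "mode", "insufficient_overlap"]
        df = pd.DataFrame(rows, columns=cols)
        return ScreenTable(df)

    def _sh(self, exp, gene, cell, sig):
        return [exp, f"sh_{gene}", "shRNA", gene, cell, 1.0,
                0, 0, 0, 0, 5.0 if sig else 0.0, sig, "empirical_null", False]

    def _cp(self, exp, cpd, cell, sig):
        return [exp, cpd, "compound", None, cell, 1.0,
                0, 0, 0, 0, 5.0 if sig else 0.0, sig, "fixed_threshold", False]

    def test_same_cell_line_evidence_retained(self):
        sh = self._table([self._sh("s1", "PAK4", "A375", True)])
        cp = self._table([self._cp("c1", "drugX", "A375", True)])
        out = integrate_screens(sh, cp, {"drugX": {"PAK4"}})
        assert list(out["gene"]) == ["PAK4"]
        assert list(out["cell_line"]) == ["A375"]

    def test_different_cell_lines_not_retained(self):
        sh = self._table([self._sh("s1", "PAK4", "A375", True)])
        cp = self._table([self._cp("c1", "drugX", "MCF7", True)])
        out = integrate_screens(sh, cp, {"drugX": {"PAK4"}})
        assert out.empty

    def test_gene_without_annotated_compound_not_retained(self):
        sh = self._table([self._sh("s1", "PAK4", "A375", True)])
        cp = self._table([self._cp("c1", "drugX", "A375", True)])
        out = integrate_screens(sh, cp, {"drugX": {"OTHER"}})
        assert out.empty
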