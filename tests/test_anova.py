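"""Two-way ANOVA against a least-squares oracle; BH-FDR; DEG selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import anova_oracle, bh_oracle
from rifnet.anova import add_fdr, bh_fdr, collapse_probes, select_degs, two_way_anova


def _design(n_cells):
    """Design with n_cells = (n_TH, n_TL, n_DH, n_DL) animals per cell."""
    rows, ids = [], []
    for (breed, alt), n in zip(
        [("Tibetan", "high"), ("Tibetan", "low"), ("Duroc", "high"), ("Duroc", "low")], n_cells
    ):
        for i in range(n):
            ids.append(f"{breed[0]}{alt[0]}{i}")
            rows.append((breed, alt))
    return pd.DataFrame(rows, columns=["breed", "altitude"], index=pd.Index(ids, name="sample"))


class TestTwoWayAnova:
    def test_constant_response_gives_p_one(self):
        design = _design((3, 3, 3, 3))
        table = two_way_anova(np.full((1, 12), 7.5), design)
        for eff in ("breed", "altitude", "interaction"):
            assert table[f"p_{eff}"].iloc[0] == 1.0
            assert table[f"F_{eff}"].iloc[0] == 0.0

    @pytest.mark.parametrize("cells", [(3, 3, 3, 3), (2, 4, 3, 5), (5, 2, 2, 6)])
    def test_matches_regression_oracle(self, cells):
        """F and p per effect equal the full-vs-reduced Type-II OLS oracle."""
        design = _design(cells)
        rng = np.random.default_rng(42)
        y = rng.normal(size=(5, sum(cells)))
        table = two_way_anova(y, design)
        for i in range(5):
            expected = anova_oracle(y[i], design)
            for eff in ("breed", "altitude", "interaction"):
                assert table[f"F_{eff}"].iloc[i] == pytest.approx(expected[eff][0], abs=1e-10)
                assert table[f"p_{eff}"].iloc[i] == pytest.approx(expected[eff][1], abs=1e-10)

    def test_planted_breed_effect_is_detected(self):
        design = _design((8, 8, 8, 8))
        rng = np.random.default_rng(0)
        shift = np.where(design["breed"] == "Tibetan", 2.0, 0.0)
        y = rng.normal(scale=0.5, size=(50, 32)) + shift
        table = two_way_anova(y, design)
        assert np.median(table["p_breed"]) < 1e-4

    def test_missing_level_and_tiny_design_error(self):
        design = _design((3, 3, 0, 0))  # Duroc absent entirely
        with pytest.raises(ValueError, match="levels"):
            two_way_anova(np.zeros((1, 6)), design)
        with pytest.raises(ValueError, match="degrees of freedom"):
            two_way_anova(np.zeros((1, 4)), _design((1, 1, 1, 1)))


class TestBhFdr:
    def test_hand_examples(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_formula_and_dominates_p(self, pvals):
        q = bh_fdr(pvals)
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-12).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)


class TestSelectDegs:
    def _table(self):
        return pd.DataFrame(
            {
                "p_breed": [1e-6, 1e-6, 0.5],
                "p_interaction": [1e-6, 0.5, 1e-6],
                "q_breed": [1e-5, 1e-5, 0.5],
                "q_interaction": [1e-5, 0.5, 1e-5],
            },
            index=["pa", "pb", "pc"],
        )

    def test_requires_both_effects(self):
        probes, _ = select_degs(self._table(), alpha=1e-4)
        assert probes == ["pa"]

    def test_gene_collapse(self):
        annot = pd.Series({"pa": "GENE1", "pb": "GENE1", "pc": "GENE2"})
        table = self._table()
        table.loc[:, ["q_breed", "q_interaction"]] = 1e-5
        probes, genes = select_degs(table, alpha=1e-4, annotation=annot)
        assert probes == ["pa", "pb", "pc"]
        assert genes == ["GENE1", "GENE2"]
        repr_map = collapse_probes(table, probes, annot)
        assert repr_map["GENE1"] == "pa"  # smaller max(p) wins

    def test_type_i_rate_under_global_null(self):
        """Per-effect rejection rate at alpha=0.05 sits in the binomial 99% band."""
        design = _design((3, 3, 3, 3))
        rng = np.random.default_rng(123)
        y = rng.normal(size=(5000, 12))
        table = two_way_anova(y, design)
        lo, hi = 0.05 - 2.576 * np.sqrt(0.05 * 0.95 / 5000), 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / 5000)
        for eff in ("breed", "altitude", "interaction"):
            rate = (table[f"p_{eff}"] < 0.05).mean()
            assert lo < rate < hi, f"{eff}: {rate:.4f} outside [{lo:.4f}, {hi:.4f}]"

    def test_add_fdr_q_columns_dominate_p(self, small_sim):
        _, (ds, truth, trs, annot) = small_sim
        table = add_fdr(two_way_anova(ds.expression, ds.design))
        for eff in ("breed", "altitude", "interaction"):
            assert (table[f"q_{eff}"] >= table[f"p_{eff}"] - 1e-12).all()
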