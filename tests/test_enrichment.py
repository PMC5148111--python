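"""Fold-enrichment arithmetic and the exact hypergeometric tail."""

import math

import numpy as np
import pytest

from oracles import hypergeom_tail_oracle
from rifnet.enrichment import enrich, expected_count

# Printed per-term reference/observed/expected values from the published
# over-representation table the arithmetic is checked against:
# (ref_count, count, expected, fold to 2 d.p.)
PUBLISHED_ROWS = {
    "metabolic process": (6594, 460, 350.07, 1.31),
    "primary metabolic process": (5592, 385, 296.87, 1.30),
    "catabolic process": (836, 74, 44.38, 1.67),
    "protein metabolic process": (2001, 146, 106.23, 1.37),
    "nitrogen compound metabolic process": (1982, 151, 105.22, 1.44),
    "locomotion": (153, 21, 8.12, 2.59),
    "mRNA processing": (241, 28, 12.79, 2.19),
    "catalytic activity": (5114, 376, 271.5, 1.38),
    "protein binding": (2719, 191, 144.35, 1.32),
    "hydrolase activity": (2175, 153, 115.47, 1.33),
    "CCKR signaling map": (169, 26, 8.97, 2.90),
    "Angiogenesis": (168, 22, 8.92, 2.47),
    "Wnt signaling pathway": (278, 30, 14.76, 2.03),
}


class TestExpectedCount:
    def test_saturated_and_empty_list(self):
        assert expected_count(40, 100, 100) == 40
        assert expected_count(40, 0, 100) == 0

    def test_list_fraction_transfer(self):
        """The list fraction implied by one term's expected count reproduces another's."""
        # 350.07/6594 list fraction, applied to a term with 5114 reference genes
        assert expected_count(5114, 350.07 * 100, 6594 * 100) == pytest.approx(271.5, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_count(200, 10, 100)
        with pytest.raises(ValueError):
            expected_count(10, 10, 0)


def _scenario(ref_count, count, list_frac_num=35007, list_frac_den=659400):
    """Construct universe/annotation/list realizing printed REF and Count at
    the published list fraction (35007/659400 = 0.05309...)."""
    universe = np.arange(list_frac_den)
    term_genes = set(range(ref_count))
    in_count = set(range(count))
    rest = [g for g in range(ref_count, list_frac_den)]
    gene_list = sorted(in_count | set(rest[: list_frac_num - count]))
    return gene_list, {"T": term_genes}, universe


class TestFoldEnrichment:
    @pytest.mark.parametrize("name", sorted(PUBLISHED_ROWS))
    def test_published_fold_values_to_two_decimals(self, name):
        ref, count, expected, fold = PUBLISHED_ROWS[name]
        gene_list, annotation, universe = _scenario(ref, count)
        row = enrich(gene_list, annotation, universe, over_only=False).iloc[0]
        assert row["expected"] == pytest.approx(expected, abs=0.005)
        assert round(row["fold"], 2) == fold

    def test_saturated_list_gives_fold_one(self):
        universe = [f"g{i}" for i in range(30)]
        annotation = {"t1": set(universe[:10]), "t2": set(universe[5:20])}
        table = enrich(universe, annotation, universe, over_only=False)
        assert (table["count"] == table["ref_count"]).all()
        assert np.allclose(table["fold"], 1.0)

    def test_stray_genes_rejected_and_empty_terms_skipped(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.raises(ValueError, match="not a subset"):
            enrich(["g1", "nope"], {"t": {"g1"}}, universe)
        table = enrich(["g1"], {"t": {"outside"}}, universe, over_only=False)
        assert len(table) == 0

    def test_bonferroni_and_direction_invariants(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(60)]
        annotation = {f"t{j}": set(rng.choice(universe, size=12, replace=False))
                      for j in range(6)}
        gene_list = list(rng.choice(universe, size=20, replace=False))
        table = enrich(gene_list, annotation, universe, over_only=False)
        m = len(table)
        np.testing.assert_allclose(
            table["p_bonferroni"], np.minimum(1.0, m * table["p_raw"]), atol=1e-12
        )
        over = table["fold"] > 1
        assert (table.loc[over, "direction"] == "+").all()
        assert (table.loc[table["fold"] < 1, "direction"] == "-").all()

    def test_hypergeometric_matches_enumeration_oracle(self):
        """Raw upper-tail p equals direct enumeration on universes ≤ 50 genes."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_total = int(rng.integers(10, 51))
            ref = int(rng.integers(1, n_total))
            n_list = int(rng.integers(1, n_total))
            universe = [f"g{i}" for i in range(n_total)]
            term = set(rng.choice(universe, size=ref, replace=False))
            genes = list(rng.choice(universe, size=n_list, replace=False))
            count = len(term & set(genes))
            row = enrich(genes, {"t": term}, universe, over_only=False).iloc[0]
            if count >= row["expected"]:
                expect = hypergeom_tail_oracle(count, n_total, ref, n_list)
                assert row["p_raw"] == pytest.approx(expect, rel=1e-9)
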