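"""Generator: seed determinism, planted structure, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rifnet.io import group_samples
from rifnet.simulate import (
    SimConfig,
    SimConfigError,
    simulate_dataset,
    truth_eval,
)
from rifnet import anova


def test_seed_determinism():
    cfg = SimConfig(n_genes=100, n_per_group=3, n_regulators=2, targets_per_regulator=4, seed=1)
    ds1, t1, trs1, an1 = simulate_dataset(cfg)
    ds2, t2, trs2, an2 = simulate_dataset(cfg)
    pd.testing.assert_frame_equal(ds1.expression, ds2.expression)
    pd.testing.assert_frame_equal(ds1.flags, ds2.flags)
    assert t1.to_dict() == t2.to_dict()
    assert trs1 == trs2


def test_no_planted_effects_gives_empty_truth_sets():
    cfg = SimConfig(n_genes=100, frac_de_breed=0.0, frac_de_interaction=0.0,
                    n_regulators=2, targets_per_regulator=4, seed=2)
    _, truth, _, _ = simulate_dataset(cfg)
    assert truth.de_breed_genes == set()
    assert truth.de_interaction_genes == set()


@pytest.mark.parametrize(
    "field,value",
    [
        ("frac_de_breed", 1.5),
        ("frac_absent", -0.1),
        ("wiring_r_group1", 1.2),
        ("n_genes", 0),
        ("noise_sd", -1.0),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = SimConfig(**{field: value})
    with pytest.raises(SimConfigError, match=field):
        cfg.validate()


def test_planted_breed_shift_recovered_from_matrix():
    """Group-mean difference of planted breed-DE genes averages near the effect."""
    cfg = SimConfig(
        n_genes=2000, probes_per_gene=1, n_per_group=10,
        effect_size_breed=2.0, noise_sd=0.5, frac_de_interaction=0.0,
        n_regulators=0, frac_absent=0.0, seed=7,
    )
    ds, truth, _, annot = simulate_dataset(cfg)
    tib = ds.design.index[ds.design["breed"] == "Tibetan"]
    dur = ds.design.index[ds.design["breed"] == "Duroc"]
    probes = annot.index[annot.isin(truth.de_breed_genes)]
    diffs = ds.expression.loc[probes, tib].mean(axis=1) - ds.expression.loc[probes, dur].mean(axis=1)
    # each diff has s.d. noise_sd*sqrt(2/20); the mean over k probes shrinks further
    se = cfg.noise_sd * np.sqrt(2 / 20) / np.sqrt(len(probes))
    assert abs(diffs.mean() - 2.0) < 3 * se


def test_absent_probe_fraction_and_flag_consistency():
    cfg = SimConfig(n_genes=2000, probes_per_gene=1, n_per_group=4,
                    frac_absent=0.2, n_regulators=0, seed=5)
    ds, truth, _, _ = simulate_dataset(cfg)
    all_absent = (ds.flags == "A").all(axis=1)
    frac = all_absent.mean()
    assert abs(frac - 0.2) < 0.02
    assert set(ds.flags.index[all_absent]) == truth.absent_probes
    # truth genes never sit on absent probes
    special = truth.de_breed_genes | truth.de_interaction_genes
    absent_genes = {p.rsplit("_", 1)[0] for p in truth.absent_probes}
    assert not (special & absent_genes)


def test_planted_wiring_correlations():
    """Empirical regulator-target correlations land near the configured wiring."""
    cfg = SimConfig(
        n_genes=500, probes_per_gene=1, n_per_group=20,
        n_regulators=5, targets_per_regulator=10,
        wiring_r_group1=0.9, wiring_r_group2=0.0,
        frac_absent=0.0, seed=13,
    )
    ds, truth, _, annot = simulate_dataset(cfg)
    th = group_samples(ds.design, "TH")
    dh = group_samples(ds.design, "DH")
    r1s, r2s = [], []
    for reg, targets in truth.regulator_targets.items():
        rp = annot.index[annot == reg][0]
        for t in targets:
            tp = annot.index[annot == t][0]
            r1s.append(np.corrcoef(ds.expression.loc[rp, th], ds.expression.loc[tp, th])[0, 1])
            r2s.append(np.corrcoef(ds.expression.loc[rp, dh], ds.expression.loc[tp, dh])[0, 1])
    assert abs(np.mean(r1s) - 0.9) < 0.1
    assert abs(np.mean(r2s) - 0.0) < 0.1


def test_null_simulation_pvalues_uniform():
    """With no planted effects the per-effect ANOVA p-values are ~U(0,1)."""
    cfg = SimConfig(
        n_genes=5000, probes_per_gene=1, n_per_group=3,
        frac_de_breed=0.0, frac_de_interaction=0.0,
        n_regulators=0, frac_absent=0.0, seed=17,
    )
    ds, _, _, _ = simulate_dataset(cfg)
    table = anova.two_way_anova(ds.expression, ds.design)
    for eff in ("breed", "altitude", "interaction"):
        ks = stats.kstest(table[f"p_{eff}"], "uniform")
        assert ks.pvalue > 0.01, f"p_{eff} not uniform (KS p={ks.pvalue:.3g})"


def test_truth_eval_counting():
    truth = {"a", "b", "c"}
    perfect = truth_eval(truth, truth)
    assert perfect.sensitivity == 1.0 and perfect.fdp == 0.0
    empty = truth_eval(set(), truth)
    assert empty.sensitivity == 0.0 and empty.fdp == 0.0
    # 9 calls, 1 outside truth
    big_truth = {f"g{i}" for i in range(8)}
    called = big_truth | {"extra"}
    rep = truth_eval(called, big_truth)
    assert rep.fdp == pytest.approx(1 / 9)
    assert rep.sensitivity == 1.0
    undefined = truth_eval({"a"}, set())
    assert undefined.sensitivity is None
    assert undefined.fdp == 1.0
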