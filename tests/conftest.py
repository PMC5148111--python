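import numpy as np
import pandas as pd
import pytest

from rifnet.io import Dataset
from rifnet.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated study shared across tests."""
    cfg = SimConfig(
        n_genes=300,
        probes_per_gene=2,
        n_per_group=8,
        n_regulators=3,
        n_null_regulators=12,
        targets_per_regulator=8,
        frac_absent=0.1,
        seed=11,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def tiny_dataset():
    """Hand-sized dataset: 3 probes × 8 samples, balanced 2×2 design."""
    samples = [f"s{i}" for i in range(8)]
    design = pd.DataFrame(
        {
            "breed": ["Tibetan"] * 4 + ["Duroc"] * 4,
            "altitude": ["high", "high", "low", "low"] * 2,
        },
        index=pd.Index(samples, name="sample"),
    )
    rng = np.random.default_rng(3)
    expr = pd.DataFrame(
        rng.normal(8, 1, size=(3, 8)),
        index=pd.Index(["p1", "p2", "p3"], name="probe"),
        columns=samples,
    )
    flags = pd.DataFrame("P", index=expr.index, columns=expr.columns)
    annot = pd.Series(["g1", "g1", "g2"], index=expr.index, name="gene")
    return Dataset(expression=expr, flags=flags, design=design, probe_annotation=annot)
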