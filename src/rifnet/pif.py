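"""Phenotype impact factor (PIF) for a two-group contrast.

PIF weights a probe's differential expression by its overall abundance:
with e1, e2 the group-mean log2 expression in the two contrasted groups,

    a   = (e1 + e2) / 2        (abundance)
    de  = e1 - e2              (differential expression)
    PIF = a * de

A highly abundant gene with moderate DE can out-score a scarce gene with
the same DE, which is the point of the weighting.

"Differential PIF" testing submits per-sample abundance-weighted values
w_ik = ybar_i * y_ik (ybar_i the probe grand mean) to the same two-way
ANOVA + BH machinery as the DEG test and applies the same selection rule.
Note that per-probe F statistics are invariant to a positive per-probe
rescaling, so this test selects exactly the DEG set; see the methods note
for discussion.
"""

from __future__ import annotations

import pandas as pd

from .anova import add_fdr, select_degs, two_way_anova
from .io import DatasetError, group_samples

__all__ = ["compute_pif", "differential_pif"]


def compute_pif(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    group1: str | tuple[str, str] = "TH",
    group2: str | tuple[str, str] = "DH",
) -> pd.DataFrame:
    """Per-probe abundance, differential expression and PIF.

    Returns a DataFrame with columns e1, e2, a, de, pif indexed by probe.
    Swapping the groups negates de and pif and leaves a unchanged.
    """
    s1 = group_samples(design, group1)
    s2 = group_samples(design, group2)
    if not s1 or not s2:
        raise DatasetError("both contrast groups must be non-empty")
    e1 = expression[s1].mean(axis=1)
    e2 = expression[s2].mean(axis=1)
    a = (e1 + e2) / 2.0
    de = e1 - e2
    return pd.DataFrame({"e1": e1, "e2": e2, "a": a, "de": de, "pif": a * de})


def differential_pif(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 1e-4,
    annotation: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Differential-PIF test over the full 2×2 design.

    Per-sample abundance-weighted values w_ik = ybar_i * y_ik are analysed
    with the same two-way ANOVA, BH-FDR and joint breed+interaction
    selection rule used for DEGs.

    Returns ``(weighted_anova_table, probe_list, gene_list)``.
    """
    grand = expression.mean(axis=1)
    weighted = expression.mul(grand, axis=0)
    table = add_fdr(two_way_anova(weighted, design))
    probes, genes = select_degs(table, alpha=alpha, annotation=annotation)
    return table, probes, genes
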