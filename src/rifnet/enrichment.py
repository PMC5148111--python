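"""Over-representation analysis with expected counts and fold enrichment.

For a gene list L drawn from a reference universe of N genes and a term
annotating REF of them with Count list members:

    Expected = REF * |L| / N
    fold     = Count / Expected

The raw p-value is the one-sided hypergeometric tail (upper tail for
over-representation; lower tail when Count < Expected).  Both Bonferroni
(min(1, m*p)) and BH-FDR adjustments are reported, with m the number of
tested terms.  The hypergeometric (Fisher) tail is exact at this scale;
the Expected/fold arithmetic is identical under the binomial
approximation some web tools use.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .anova import bh_fdr

__all__ = ["expected_count", "enrich"]


def expected_count(ref_count: float, list_size: float, ref_total: float) -> float:
    """Expected number of list genes annotated to a term.

    Expected = ref_count * list_size / ref_total.
    """
    if ref_total <= 0:
        raise ValueError("ref_total must be positive")
    if ref_count > ref_total:
        raise ValueError(f"ref_count {ref_count} exceeds ref_total {ref_total}")
    if list_size > ref_total:
        raise ValueError(f"list_size {list_size} exceeds ref_total {ref_total}")
    return ref_count * list_size / ref_total


def enrich(
    gene_list: Iterable[str],
    annotation: Mapping[str, set] | Mapping[str, tuple[str, set]],
    universe: Iterable[str],
    over_only: bool = True,
) -> pd.DataFrame:
    """Per-term over-/under-representation of a gene list.

    Parameters
    ----------
    gene_list : iterable
        Genes of interest; must be a subset of ``universe``.
    annotation : mapping
        term → gene set, or term → (description, gene set) as produced by
        :func:`rifnet.io.read_gmt`.  Annotated genes outside the universe
        are ignored; terms left with no reference gene are skipped.
    universe : iterable
        The reference gene universe.
    over_only : bool
        Restrict the returned rows to over-represented terms (default);
        both directions are always tested and adjusted together.

    Returns
    -------
    DataFrame sorted by raw p-value with columns term, name, ref_count,
    count, expected, fold, direction, p_raw, p_bonferroni, q_bh.
    """
    uni = set(universe)
    sel = set(gene_list)
    if not sel:
        raise ValueError("gene list is empty")
    stray = sorted(sel - uni)
    if stray:
        raise ValueError(f"gene list is not a subset of the universe: {stray[:10]}")
    n_total, n_list = len(uni), len(sel)

    rows = []
    for term in sorted(annotation):
        val = annotation[term]
        name, genes = val if isinstance(val, tuple) else (term, val)
        ref_genes = set(genes) & uni
        ref = len(ref_genes)
        if ref == 0:
            continue
        count = len(ref_genes & sel)
        expected = expected_count(ref, n_list, n_total)
        fold = count / expected
        if count >= expected:
            p_raw = float(stats.hypergeom.sf(count - 1, n_total, ref, n_list))
            direction = "+" if count > expected else "-"
        else:
            p_raw = float(stats.hypergeom.cdf(count, n_total, ref, n_list))
            direction = "-"
        rows.append((term, name, ref, count, expected, fold, direction, p_raw))

    out = pd.DataFrame(
        rows,
        columns=["term", "name", "ref_count", "count", "expected", "fold", "direction", "p_raw"],
    )
    m = len(out)
    if m:
        out["p_bonferroni"] = np.minimum(1.0, m * out["p_raw"])
        out["q_bh"] = bh_fdr(out["p_raw"].to_numpy())
    else:
        out["p_bonferroni"] = out["p_raw"]
        out["q_bh"] = out["p_raw"]
    if over_only:
        out = out[out["direction"] == "+"]
    return out.sort_values(["p_raw", "term"], ignore_index=True)
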