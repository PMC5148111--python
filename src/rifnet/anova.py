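"""Per-probe two-way factorial ANOVA with interaction and FDR control.

The model for one probe is

    y_ijk = mu + S_i + R_j + (S.R)_ij + e_ijk

with S the breed effect, R the altitude effect, their interaction, and iid
Gaussian error.  With two levels per factor each effect carries one degree
of freedom.  Sums of squares are Type II (sequential and Type II coincide
for the balanced case), F = MS_effect / MS_residual with the full-model
residual, and p-values come from the F distribution.

FDR control across probes is Benjamini–Hochberg, applied separately per
effect.  Differentially expressed probes are those significant for both
the breed main effect and the breed×altitude interaction: the contrast of
interest is breed difference that itself responds to altitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["two_way_anova", "bh_fdr", "add_fdr", "select_degs", "collapse_probes"]

EFFECTS = ("breed", "altitude", "interaction")


def _design_matrices(design: pd.DataFrame) -> dict[str, np.ndarray]:
    for col in ("breed", "altitude"):
        levels = sorted(design[col].unique())
        if len(levels) != 2:
            raise ValueError(
                f"factor {col!r} must have exactly 2 levels present, got {levels}"
            )
    b = (design["breed"] == sorted(design["breed"].unique())[0]).to_numpy(float)
    a = (design["altitude"] == sorted(design["altitude"].unique())[0]).to_numpy(float)
    one = np.ones_like(b)
    return {
        "b": np.column_stack([one, b]),
        "a": np.column_stack([one, a]),
        "ba": np.column_stack([one, b, a]),
        "full": np.column_stack([one, b, a, b * a]),
    }


def two_way_anova(y: pd.DataFrame | np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """Breed × altitude ANOVA for every probe at once.

    Parameters
    ----------
    y : DataFrame or ndarray, shape (n_probes, n_samples)
        log2 expression; columns must align with ``design`` rows (for a
        DataFrame the columns are checked against the design index).
    design : DataFrame
        Sample design with ``breed`` and ``altitude`` columns.

    Returns
    -------
    DataFrame with columns F_breed, F_altitude, F_interaction and the
    matching p_ columns, one row per probe.

    Notes
    -----
    Degenerate probes are guarded rather than propagated as NaN: with zero
    residual variance, p is exactly 0 for an effect with positive sum of
    squares and exactly 1 for an effect with none (a constant probe gets
    p = 1 for all three effects).
    """
    if isinstance(y, pd.DataFrame):
        if list(y.columns) != list(design.index):
            y = y.loc[:, design.index]
        index = y.index
        Y = y.to_numpy(dtype=float)
    else:
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[None, :]
        index = pd.RangeIndex(Y.shape[0])
    n = Y.shape[1]
    if n != len(design):
        raise ValueError("response columns do not match design rows")
    X = _design_matrices(design)
    df_res = n - X["full"].shape[1]
    if df_res < 1:
        raise ValueError(f"residual degrees of freedom {df_res} < 1")

    Yc = Y - Y.mean(axis=1, keepdims=True)
    tss = np.einsum("ij,ij->i", Yc, Yc)

    def rss(key: str) -> np.ndarray:
        q, _ = np.linalg.qr(X[key])
        proj = Yc @ q
        return np.maximum(tss - np.einsum("ij,ij->i", proj, proj), 0.0)

    rss_full = rss("full")
    rss_ba = rss("ba")
    ss = {
        "breed": np.maximum(rss("a") - rss_ba, 0.0),  # SS(S | R)
        "altitude": np.maximum(rss("b") - rss_ba, 0.0),  # SS(R | S)
        "interaction": np.maximum(rss_ba - rss_full, 0.0),  # SS(S.R | S, R)
    }

    tiny = 1e-12 * np.maximum(tss, 1.0)
    degenerate = rss_full <= tiny
    ms_res = rss_full / df_res
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for eff in EFFECTS:
            f = ss[eff] / ms_res
            p = stats.f.sf(f, 1, df_res)
            null_eff = ss[eff] <= tiny
            f = np.where(degenerate, np.where(null_eff, 0.0, np.inf), f)
            p = np.where(degenerate, np.where(null_eff, 1.0, 0.0), p)
            out[f"F_{eff}"] = f
            out[f"p_{eff}"] = p
    return pd.DataFrame(out, index=index)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, preserving input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_fdr(anova_table: pd.DataFrame) -> pd.DataFrame:
    """Append per-effect BH q-value columns to an ANOVA table."""
    out = anova_table.copy()
    for eff in EFFECTS:
        out[f"q_{eff}"] = bh_fdr(out[f"p_{eff}"].to_numpy())
    return out


def select_degs(
    anova_table: pd.DataFrame,
    alpha: float = 1e-4,
    annotation: pd.Series | None = None,
) -> tuple[list[str], list[str]]:
    """Probes significant for both breed and interaction at FDR < alpha.

    Returns ``(probe_list, gene_list)``; the gene list collapses the
    selected probes to distinct annotated symbols (empty when no
    annotation is supplied).  Both lists are sorted for determinism.
    """
    if "q_breed" not in anova_table:
        raise ValueError("q-values missing; call add_fdr first")
    mask = (anova_table["q_breed"] < alpha) & (anova_table["q_interaction"] < alpha)
    probes = sorted(anova_table.index[mask].astype(str))
    genes: list[str] = []
    if annotation is not None:
        genes = sorted({annotation[p] for p in probes if p in annotation.index and pd.notna(annotation[p])})
    return probes, genes


def collapse_probes(
    anova_table: pd.DataFrame, probes: list[str], annotation: pd.Series
) -> dict[str, str]:
    """Collapse probes to one representative probe per gene.

    The representative is the probe with the smallest
    ``max(p_breed, p_interaction)`` — the binding constraint of the joint
    selection rule — with lexicographic probe id as the deterministic
    tie-break.  Unannotated probes represent themselves.
    """
    score = anova_table[["p_breed", "p_interaction"]].max(axis=1)
    best: dict[str, tuple[float, str]] = {}
    for p in probes:
        gene = annotation.get(p) if annotation is not None else None
        key = gene if (gene is not None and pd.notna(gene)) else p
        cand = (float(score.get(p, np.inf)), p)
        if key not in best or cand < best[key]:
            best[key] = cand
    return {gene: probe for gene, (_, probe) in sorted(best.items())}
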