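"""Regulatory impact factor (RIF) scoring of transcriptional regulators.

RIF ranks candidate regulators (transcription factors, signaling
molecules, chromatin remodelers) by how their relationship to the
differentially expressed genes changes between two contrasted groups
(here the two breeds at high altitude).  For regulator j and DE gene i
with group-mean expressions e1_i, e2_i, abundance a_i = (e1+e2)/2,
differential expression de_i = e1-e2, and within-group regulator–gene
correlations r1_ij, r2_ij (differential wiring dw_ij = r1_ij - r2_ij):

    RIF1_j = 1/n_DE * sum_i a_i * de_i * dw_ij^2
    RIF2_j = 1/n_DE * sum_i (e1_i * r1_ij)^2 - (e2_i * r2_ij)^2

RIF1 flags regulators whose wiring to abundant, strongly DE genes changes
most; RIF2 flags regulators whose expression best predicts DE-gene
abundance in one group versus the other.  Raw scores are z-standardized
over all scored regulators (sample s.d., n-1) and the extremes (top-k
positive and negative, |z| > z_cut) are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import group_samples

__all__ = ["rif_from_stats", "score_regulators", "zscore", "top_regulators"]


def rif_from_stats(
    a: np.ndarray,
    de: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw RIF1/RIF2 from precomputed per-gene statistics.

    ``r1``/``r2`` have shape (n_regulators, n_de_genes); the per-gene
    vectors broadcast along rows.  Gene pairings with undefined
    correlation (NaN in r1 or r2) are excluded from that regulator's
    average; a regulator with no valid pairing gets NaN raw scores.

    Returns ``(rif1, rif2, n_valid_pairs)``.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    a, de, e1, e2 = (np.asarray(v, dtype=float) for v in (a, de, e1, e2))
    valid = np.isfinite(r1) & np.isfinite(r2)
    n_valid = valid.sum(axis=1)
    dw = np.where(valid, r1 - r2, 0.0)
    c1 = a[None, :] * de[None, :] * dw**2
    c2 = np.where(valid, (e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rif1 = np.where(n_valid > 0, c1.sum(axis=1) / np.maximum(n_valid, 1), np.nan)
        rif2 = np.where(n_valid > 0, c2.sum(axis=1) / np.maximum(n_valid, 1), np.nan)
    return rif1, rif2, n_valid


def _group_correlations(
    expression: pd.DataFrame, tr_probes: list[str], de_probes: list[str], samples: list[str]
) -> np.ndarray:
    """Pearson correlations TR × DE within one group; NaN where undefined."""
    n = len(samples)
    x_tr = expression.loc[tr_probes, samples].to_numpy(dtype=float)
    x_de = expression.loc[de_probes, samples].to_numpy(dtype=float)

    def standardize(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=1, keepdims=True)
        sd = xc.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = xc / sd
        z[np.broadcast_to(sd == 0, z.shape)] = np.nan
        return z

    z_tr, z_de = standardize(x_tr), standardize(x_de)
    return (z_tr @ z_de.T) / (n - 1)


def score_regulators(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    tr_probes: list[str],
    de_probes: list[str],
    group1: str | tuple[str, str] = "TH",
    group2: str | tuple[str, str] = "DH",
) -> pd.DataFrame:
    """RIF1/RIF2 scores and z-scores for every regulator probe.

    ``de_probes`` is the DE input set (typically one representative probe
    per DE gene); ``tr_probes`` are the regulator probes present in the
    filtered matrix.  Regulators with no valid DE pairing are reported
    unscored (NaN raw and z) rather than as 0.

    Returns a DataFrame indexed by regulator probe with columns
    rif1, rif2, z1, z2, n_pairs, scored.
    """
    if not tr_probes:
        raise ValueError("regulator probe list is empty")
    if not de_probes:
        raise ValueError("DE probe list is empty: RIF needs at least one DE gene")
    s1 = group_samples(design, group1)
    s2 = group_samples(design, group2)
    e1 = expression.loc[de_probes, s1].mean(axis=1).to_numpy()
    e2 = expression.loc[de_probes, s2].mean(axis=1).to_numpy()
    a = (e1 + e2) / 2.0
    de = e1 - e2
    r1 = _group_correlations(expression, tr_probes, de_probes, s1)
    r2 = _group_correlations(expression, tr_probes, de_probes, s2)
    rif1, rif2, n_valid = rif_from_stats(a, de, e1, e2, r1, r2)
    scored = n_valid > 0
    table = pd.DataFrame(
        {
            "rif1": rif1,
            "rif2": rif2,
            "z1": zscore_masked(rif1, scored),
            "z2": zscore_masked(rif2, scored),
            "n_pairs": n_valid,
            "scored": scored,
        },
        index=pd.Index(tr_probes, name="probe"),
    )
    return table


def zscore(values) -> np.ndarray:
    """Standardize with the sample s.d. (n-1) convention.

    Raises on fewer than 2 values or a zero-s.d. (degenerate) vector.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-standardization needs at least 2 scored values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate score vector: zero standard deviation")
    return (x - x.mean()) / sd


def zscore_masked(raw: np.ndarray, scored: np.ndarray) -> np.ndarray:
    """z-scores over the scored subset; unscored entries stay NaN."""
    out = np.full(raw.shape, np.nan)
    if scored.sum() >= 2:
        out[scored] = zscore(raw[scored])
    elif scored.any():
        raise ValueError("fewer than 2 scored regulators: cannot z-standardize")
    return out


def top_regulators(
    rif_table: pd.DataFrame, criterion: str = "rif1", k: int = 5
) -> tuple[list[str], list[str]]:
    """Top-k positive and top-k negative regulators by z-score.

    ``criterion`` is "rif1" or "rif2".  Ties are broken by descending
    |z| and then lexicographic probe id, so output order is deterministic.
    """
    col = {"rif1": "z1", "rif2": "z2"}.get(criterion)
    if col is None:
        raise ValueError(f"criterion must be 'rif1' or 'rif2', got {criterion!r}")
    z = rif_table[col].dropna()
    ordered = sorted(z.items(), key=lambda kv: (-abs(kv[1]), str(kv[0])))
    pos = [p for p, v in ordered if v > 0][:k]
    neg = [p for p, v in ordered if v < 0][:k]
    return pos, neg
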