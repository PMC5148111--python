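"""PCIT: partial-correlation-and-information-theory edge filtering.

For every trio of genes (x, y, z) the three first-order partial
correlations are compared with the raw correlations through the local
information-theoretic tolerance

    eps_xyz = 1/3 * (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz)

and the edge (x, y) is discarded as explained by some third gene z when

    |r_xy| < |eps_xyz * r_xz|   and   |r_xy| < |eps_xyz * r_yz|.

Edges surviving every trio test form the significance mask; a hard
absolute-correlation threshold (default |r| >= 0.95) is applied on top of
the mask to build the final edge set.

Numerical guards: correlations of exactly ±1 (inevitable with 2 samples
per group) are clamped to ±(1 - 1e-12) with a warning before any partial
correlation is formed, and tolerance ratio terms whose denominator
|r| < 1e-12 are excluded from that trio's average (the trio is skipped
entirely when all three terms are excluded).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "correlation_matrix",
    "partial_correlation",
    "pcit_filter",
    "threshold_edges",
]

CLAMP = 1.0 - 1e-12
DENOM_TOL = 1e-12


def correlation_matrix(expression: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Pearson correlations between probes within one sample group."""
    if len(samples) < 2:
        raise ValueError("correlation within a group needs at least 2 samples")
    x = expression[samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    return pd.DataFrame(c, index=expression.index, columns=expression.index)


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial correlation r_xy.z.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

    Inputs of magnitude 1 in the conditioning correlations leave the
    quantity undefined; callers are expected to clamp first.
    """
    r_xy, r_xz, r_yz = (np.asarray(v, dtype=float) for v in (r_xy, r_xz, r_yz))
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return (r_xy - r_xz * r_yz) / denom


def _clamp(corr: np.ndarray) -> np.ndarray:
    off = ~np.eye(corr.shape[0], dtype=bool)
    if np.any(np.abs(corr[off]) >= 1.0):
        warnings.warn(
            "off-diagonal correlations of magnitude 1 clamped to 1 - 1e-12; "
            "the group is too small for meaningful correlations"
        )
    out = corr.copy()
    out[off] = np.clip(corr[off], -CLAMP, CLAMP)
    np.fill_diagonal(out, 1.0)
    return out


def pcit_filter(corr: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Boolean significance mask over gene pairs (True = edge survives).

    The mask is symmetric with a False diagonal.  With fewer than 3 genes
    no trio exists; all edges survive with a warning.
    """
    c_in = corr.to_numpy(dtype=float) if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    n = c_in.shape[0]
    if c_in.shape != (n, n) or not np.allclose(c_in, c_in.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    off_diag = ~np.eye(n, dtype=bool)
    if n < 3:
        warnings.warn("fewer than 3 genes: PCIT cannot test any trio, all edges kept")
        return off_diag
    c = _clamp(c_in)
    a = np.abs(c)
    kill = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        for z in range(n):
            cz = c[:, z]  # r_xz as a function of x (and r_yz as a function of y)
            dz = np.sqrt(1.0 - cz**2)
            # r_xy.z over the (x, y) grid
            p1 = (c - np.outer(cz, cz)) / np.outer(dz, dz)
            common = np.sqrt(1.0 - c**2)
            # r_xz.y : partial of (x, z) given y, over the (x, y) grid
            p2 = (cz[:, None] - c * cz[None, :]) / (common * dz[None, :])
            # r_yz.x : partial of (y, z) given x, over the (x, y) grid
            p3 = (cz[None, :] - c * cz[:, None]) / (common * dz[:, None])
            v1 = a >= DENOM_TOL
            v2 = np.broadcast_to(np.abs(cz)[:, None] >= DENOM_TOL, (n, n))
            v3 = np.broadcast_to(np.abs(cz)[None, :] >= DENOM_TOL, (n, n))
            count = v1.astype(int) + v2.astype(int) + v3.astype(int)
            terms = (
                np.where(v1, p1 / np.where(v1, c, 1.0), 0.0)
                + np.where(v2, p2 / np.where(v2, cz[:, None], 1.0), 0.0)
                + np.where(v3, p3 / np.where(v3, cz[None, :], 1.0), 0.0)
            )
            eps = np.where(count > 0, terms / np.maximum(count, 1), np.nan)
            tol = np.abs(eps)
            kz = (a < tol * np.abs(cz)[:, None]) & (a < tol * np.abs(cz)[None, :])
            kz &= count > 0  # trio skipped when every ratio term was excluded
            kz[z, :] = False
            kz[:, z] = False
            kz[idx, idx] = False
            kill |= kz
    mask = ~kill
    np.fill_diagonal(mask, False)
    return mask


def threshold_edges(
    corr: pd.DataFrame,
    mask: np.ndarray,
    r_min: float = 0.95,
    group: str = "",
) -> pd.DataFrame:
    """Edge set: PCIT-significant pairs with |r| >= r_min.

    Returns a DataFrame with columns gene_a, gene_b, r, group (gene_a <
    gene_b lexicographically, rows sorted) carrying the raw within-group
    correlation as the edge weight.
    """
    if not (0.0 < r_min <= 1.0):
        raise ValueError(f"r_min must lie in (0, 1], got {r_min}")
    genes = corr.index.astype(str)
    c = corr.to_numpy(dtype=float)
    n = c.shape[0]
    if mask.shape != (n, n):
        raise ValueError("mask shape does not match correlation matrix")
    rows = []
    iu, ju = np.triu_indices(n, k=1)
    keep = mask[iu, ju] & (np.abs(c[iu, ju]) >= r_min)
    for i, j in zip(iu[keep], ju[keep]):
        ga, gb = sorted((genes[i], genes[j]))
        rows.append((ga, gb, float(c[i, j]), group))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "group"])
    return out.sort_values(["gene_a", "gene_b"], ignore_index=True)
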