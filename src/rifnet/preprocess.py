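"""Detection-call filtering and normalization.

The pipeline order is fixed: detection call / flags → present-filter →
quantile normalization.  Flags are defined on the raw signals, so filtering
happens before normalization.

The platform this package emulates is a one-color, single-probe oligo
array.  RMA in the strict sense (multi-probe median polish on CEL files) is
Affymetrix-specific; the standard normalization for this platform is
quantile normalization of all samples followed by log2, which is what
:func:`normalize` implements.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ABSENT, PRESENT, Dataset

__all__ = ["call_detection", "filter_expressed", "quantile_normalize", "normalize"]


def call_detection(
    raw_intensity: pd.DataFrame,
    background_mean: float,
    background_sd: float,
    k: float = 2.0,
) -> pd.DataFrame:
    """Present/absent calls from raw signal vs background.

    A cell is flagged "P" (present, i.e. expressed above background) iff
    ``raw_intensity > background_mean + k * background_sd``; otherwise "A".
    This reproduces the scanner semantics of flagging a probe absent when
    its signal does not exceed the local background.

    Parameters
    ----------
    raw_intensity : DataFrame
        Non-negative probe × sample signal.
    background_mean, background_sd : float
        Background signal distribution; ``background_sd >= 0``.
    k : float
        Number of background s.d. above the mean required for a present
        call (default 2).
    """
    if background_sd < 0:
        raise ValueError("background_sd must be non-negative")
    vals = raw_intensity.to_numpy()
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative intensity at probe {raw_intensity.index[r]!r}, "
            f"sample {raw_intensity.columns[c]!r}: raw scale assumed non-negative"
        )
    threshold = background_mean + k * background_sd
    flags = np.where(vals > threshold, PRESENT, ABSENT)
    return pd.DataFrame(flags, index=raw_intensity.index, columns=raw_intensity.columns)


def filter_expressed(dataset: Dataset) -> Dataset:
    """Keep exactly the probes flagged present in at least one sample.

    Probe ordering is preserved; idempotent.  An empty result is allowed
    (with a warning) so degenerate inputs fail downstream, not here.
    """
    keep = (dataset.flags == PRESENT).any(axis=1)
    if not keep.any():
        warnings.warn("no probe is present in any sample; result is empty")
    annot = dataset.probe_annotation
    return Dataset(
        expression=dataset.expression.loc[keep],
        flags=dataset.flags.loc[keep],
        design=dataset.design,
        probe_annotation=annot,
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples (columns).

    Each column is replaced by the reference distribution (the mean of the
    per-sample order statistics) at its own ranks, so afterwards every
    sample has the identical sorted value vector.  Ties are resolved by
    averaging the reference values of the tied ranks.
    """
    x = matrix.to_numpy(dtype=float)
    n, m = x.shape
    if n == 0:
        return matrix.copy()
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(m):
        col_order = order[:, j]
        sorted_vals = x[col_order, j]
        assigned = ref.copy()
        # average the reference values over runs of equal input values
        starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        sums = np.add.reduceat(ref, starts)
        sizes = np.diff(np.r_[starts, n])
        assigned = np.repeat(sums / sizes, sizes)
        out[col_order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize(matrix: pd.DataFrame, assume_log2: bool = False) -> pd.DataFrame:
    """Normalize an expression matrix to the analysis-ready log2 scale.

    Raw-scale input (``assume_log2=False``) must be strictly positive; it
    is quantile-normalized and then log2-transformed.  Input already on the
    log2 scale is quantile-normalized as-is.
    """
    if assume_log2:
        return quantile_normalize(matrix)
    vals = matrix.to_numpy()
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive raw value at probe {matrix.index[r]!r}, sample "
            f"{matrix.columns[c]!r}; declare assume_log2 if data are already log2"
        )
    return np.log2(quantile_normalize(matrix))
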