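"""Offset-corrected log2 expression ("CQN values").

Removes technical variation tied to gene GC content, gene length and
library size.  Library size is absorbed by the counts-per-million scaling;
GC and length trends are estimated per sample as an additive natural-cubic-
spline mean model of log2 CPM on GC fraction and log10 length, fitted by
least squares, and subtracted as a per-gene x sample offset.  Offsets are
centered to zero mean within each sample, so normalization never shifts a
sample's overall expression level.

The downstream coupling statistics use only within-sample ranks, which are
insensitive to monotone residual differences between this additive-spline
correction and a full conditional-quantile fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("osteocoupling")

#: Quantiles at which spline knots are placed.
KNOT_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class NormalizedMatrix:
    """Offset-corrected log2 expression with the technical offsets kept."""

    values: pd.DataFrame   # genes x samples, log2 scale
    offsets: pd.DataFrame  # genes x samples, log2 units, zero-mean per sample

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.offsets.index) or \
           not self.values.columns.equals(self.offsets.columns):
            raise ValueError("values and offsets must share gene and sample axes")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized values must be finite")
        col_means = self.offsets.to_numpy().mean(axis=0)
        if self.offsets.shape[0] and not np.allclose(col_means, 0.0, atol=1e-8):
            raise ValueError("offsets must have zero mean within each sample")


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with 0.5 / 1 pseudo-counts.

    value(g, i) = log2((count + 0.5) / (libsize_i + 1) * 1e6) where
    libsize_i is the column sum.  Errors on an all-zero sample.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total counts: {counts.columns[zero].tolist()}"
        )
    values = np.log2((counts.to_numpy(float) + 0.5) / (lib + 1.0) * 1e6)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    With K distinct interior knots xi_1 < ... < xi_K the basis is
    [x, N_1(x), ..., N_{K-2}(x)] where
    N_k = d_k - d_{K-1} and d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) /
    (xi_K - xi_k); linear beyond the boundary knots.
    """
    knots = np.unique(np.asarray(knots, dtype=float))
    x = np.asarray(x, dtype=float)
    cols = [x]
    K = len(knots)
    if K >= 3:
        def d(k):
            return (np.clip(x - knots[k], 0, None) ** 3
                    - np.clip(x - knots[K - 1], 0, None) ** 3) / (knots[K - 1] - knots[k])
        d_last = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - d_last)
    return np.column_stack(cols)


def _covariate_basis(values: np.ndarray, name: str) -> np.ndarray | None:
    if np.ptp(values) == 0:
        logger.warning("covariate %s is constant across genes; term dropped", name)
        return None
    knots = np.quantile(values, KNOT_QUANTILES)
    return natural_cubic_basis(values, knots)


def fit_technical_offsets(
    log_expr: pd.DataFrame,
    gc: pd.Series,
    length: pd.Series,
    fit_genes: pd.Index | list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample additive spline fit of log expression on GC and log10 length.

    The model is fitted over *fit_genes* (default: all genes) and evaluated
    on every gene; the returned offsets are the fitted technical trends,
    centered to zero mean within each sample.  Constant covariates are
    dropped with a warning; if both are constant all offsets are zero.
    """
    genes = log_expr.index
    gc_arr = gc.reindex(genes).to_numpy(float)
    len_arr = length.reindex(genes).to_numpy(float)
    if np.isnan(gc_arr).any() or np.isnan(len_arr).any():
        raise ValueError("gc/length annotation missing for some genes")
    if ((gc_arr < 0) | (gc_arr > 1)).any():
        raise ValueError("gc fractions must lie in [0, 1]")
    if (len_arr <= 0).any():
        raise ValueError("gene lengths must be positive")

    if fit_genes is None:
        fit_mask = np.ones(len(genes), dtype=bool)
    else:
        fit_mask = np.asarray(genes.isin(pd.Index(fit_genes)))
    n_fit = int(fit_mask.sum())
    if n_fit < 20:
        raise ValueError(f"need at least 20 genes to fit offsets, got {n_fit}")

    blocks = []
    for values, name in ((gc_arr, "gc"), (np.log10(len_arr), "log10_length")):
        # Knots from the fitting subset so quantiles reflect fitted genes.
        if np.ptp(values[fit_mask]) == 0:
            logger.warning("covariate %s is constant across genes; term dropped", name)
            continue
        knots = np.quantile(values[fit_mask], KNOT_QUANTILES)
        blocks.append(natural_cubic_basis(values, knots))

    n_genes, n_samples = log_expr.shape
    if not blocks:
        offsets = np.zeros((n_genes, n_samples))
        return pd.DataFrame(offsets, index=genes, columns=log_expr.columns)

    design = np.column_stack([np.ones(n_genes), *blocks])
    if n_fit <= design.shape[1]:
        raise ValueError("fewer fitted genes than spline coefficients")
    y = log_expr.to_numpy(float)
    beta, *_ = np.linalg.lstsq(design[fit_mask], y[fit_mask], rcond=None)
    fitted = design @ beta
    offsets = fitted - fitted.mean(axis=0, keepdims=True)
    return pd.DataFrame(offsets, index=genes, columns=log_expr.columns)


def cqn_normalize(
    counts: pd.DataFrame,
    gc: pd.Series,
    length: pd.Series,
    fit_genes: pd.Index | list[str] | None = None,
) -> NormalizedMatrix:
    """Offset-corrected log2 expression: log2 CPM minus technical offsets."""
    expr = log2_cpm(counts)
    offsets = fit_technical_offsets(expr, gc, length, fit_genes=fit_genes)
    return NormalizedMatrix(values=expr - offsets, offsets=offsets)
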