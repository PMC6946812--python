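"""Negative-binomial two-group differential expression.

The model for gene g in sample i is NB with log mean
``log mu_gi = beta_g(group_i) + o_gi`` and variance ``mu + phi_g mu^2``,
where the offset ``o_gi`` combines log library size and the per-gene
technical offset from :mod:`osteocoupling.normalization`.  Genes are first
screened by the low-count rule (within-group median count >= 10 in at least
one group), per-gene dispersions are method-of-moments estimates shrunk
toward a trimmed-mean common value, each gene is tested by a likelihood-
ratio test of the group term (chi-square, 1 df), and p-values are converted
to FDRs by Benjamini-Hochberg.

An exact conditional NB test (:func:`nb_exact_test`) is provided for the
equal-library-size case; it enumerates the conditional distribution of the
group-A sum given the total and serves as an independent check of the LRT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import NormalizedMatrix, cqn_normalize

logger = logging.getLogger("osteocoupling")

MEDIAN_COUNT_THRESHOLD = 10
DEFAULT_PRIOR_WEIGHT = 10.0
PRIOR_COUNT = 0.125           # added to group means for reported log2FC
_POISSON_R = 1e12             # effective NB size when dispersion is zero


class GroupLabelError(ValueError):
    """Sample grouping does not match the count matrix."""


def _group_masks(columns: pd.Index, groups: pd.Series) -> dict[str, np.ndarray]:
    groups = groups.reindex(columns)
    if groups.isna().any():
        missing = columns[groups.isna()].tolist()[:5]
        raise GroupLabelError(f"no group label for sample(s): {missing}")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise GroupLabelError(f"expected exactly two groups, got {labels}")
    return {lab: (groups == lab).to_numpy() for lab in labels}


# ---------------------------------------------------------------------------
# Low-count filter
# ---------------------------------------------------------------------------

def filter_low_counts(counts: pd.DataFrame, groups: pd.Series) -> pd.Index:
    """Genes retained for testing.

    A gene is kept iff its within-group median count reaches the threshold
    (10) in at least one group; genes with low medians in all groups are
    excluded.
    """
    masks = _group_masks(counts.columns, groups)
    values = counts.to_numpy()
    keep = np.zeros(len(counts), dtype=bool)
    for mask in masks.values():
        keep |= np.median(values[:, mask], axis=1) >= MEDIAN_COUNT_THRESHOLD
    return counts.index[keep]


# ---------------------------------------------------------------------------
# Offsets and adjusted counts
# ---------------------------------------------------------------------------

def combined_offsets(counts: pd.DataFrame,
                     technical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Natural-log offsets: log library size plus the technical offset.

    *technical* is the per-gene x sample offset in log2 units (as stored on
    a :class:`~osteocoupling.normalization.NormalizedMatrix`).
    """
    lib = counts.sum(axis=0).to_numpy(float)
    offsets = np.broadcast_to(np.log(lib), counts.shape).copy()
    if technical is not None:
        offsets = offsets + np.log(2.0) * technical.reindex(
            index=counts.index, columns=counts.columns).to_numpy()
    return pd.DataFrame(offsets, index=counts.index, columns=counts.columns)


def _adjusted_counts(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    # Rescale to each gene's mean offset so a global library rescaling
    # cancels exactly.
    centered = offsets - offsets.mean(axis=1, keepdims=True)
    return values * np.exp(-centered)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    """Per-gene NB dispersions shrunk toward a common value.

    ``phi`` are the shrunk estimates, convex combinations of the raw
    (truncated-at-zero) method-of-moments values and the 20%-trimmed-mean
    common dispersion ``common`` with prior weight ``prior_weight``.
    """

    phi: pd.Series
    raw: pd.Series
    common: float
    prior_weight: float


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    offsets: pd.DataFrame | None = None,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
) -> DispersionEstimates:
    """Method-of-moments dispersions with shrinkage toward the trimmed mean.

    Raw per-gene estimates pool the within-group moments of offset-adjusted
    counts: phi_hat = sum_k (n_k - 1) (s_k^2 - m_k) / m_k^2 / sum_k (n_k - 1),
    truncated at zero; the common value is the 20%-per-tail trimmed mean of
    the raw estimates; shrinkage is phi = (n phi_hat + w phi0) / (n + w)
    with n the total sample count.
    """
    masks = _group_masks(counts.columns, groups)
    for lab, mask in masks.items():
        if mask.sum() < 2:
            raise GroupLabelError(
                f"group {lab!r} has a single sample; dispersion cannot be "
                f"estimated — supply a fixed dispersion instead"
            )
    values = counts.to_numpy(float)
    if offsets is None:
        offsets_arr = np.broadcast_to(
            np.log(values.sum(axis=0)), values.shape)
    else:
        offsets_arr = offsets.to_numpy(float)
    adj = _adjusted_counts(values, offsets_arr)

    num = np.zeros(len(counts))
    den = 0.0
    for mask in masks.values():
        sub = adj[:, mask]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_k = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        w = mask.sum() - 1
        num += w * phi_k
        den += w
    raw = np.maximum(num / den, 0.0)
    common = float(stats.trim_mean(raw, 0.2))
    n_total = values.shape[1]
    phi = (n_total * raw + prior_weight * common) / (n_total + prior_weight)
    index = counts.index
    return DispersionEstimates(
        phi=pd.Series(phi, index=index, name="phi"),
        raw=pd.Series(raw, index=index, name="phi_raw"),
        common=common,
        prior_weight=prior_weight,
    )


# ---------------------------------------------------------------------------
# Exact conditional NB test (equal library sizes)
# ---------------------------------------------------------------------------

ENUMERATION_BOUND = 10_000


def nb_exact_test(counts_g: np.ndarray, groups: np.ndarray, phi: float) -> float:
    """Exact conditional two-group NB test for one gene, equal library sizes.

    Conditional on the total count t, the group-A sum follows the
    distribution proportional to ``f_A(s) f_B(t - s)`` where the group sums
    are NB with size ``n_k / phi`` (binomial when phi = 0, the Poisson
    limit).  The two-sided p-value is the total probability of outcomes no
    more likely than the observed split.
    """
    counts_g = np.asarray(counts_g)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise GroupLabelError(f"expected exactly two groups, got {labels}")
    mask_a = groups == labels[0]
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    t = int(counts_g.sum())
    s_a = int(counts_g[mask_a].sum())
    if max(s_a, t - s_a) > ENUMERATION_BOUND:
        raise ValueError(
            f"a group sum exceeds the enumeration bound "
            f"{ENUMERATION_BOUND}; use nb_lrt instead"
        )
    s_obs = int(counts_g[mask_a].sum())
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if phi == 0:
        logp = stats.binom.logpmf(s, t, n_a / (n_a + n_b))
    else:
        r_unit = 1.0 / phi
        # The success probability cancels in the conditional distribution;
        # any valid value gives the same normalized result.
        logp = (stats.nbinom.logpmf(s, n_a * r_unit, 0.5)
                + stats.nbinom.logpmf(t - s, n_b * r_unit, 0.5))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[s_obs]
    return float(prob[prob <= p_obs * (1.0 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """NB log likelihood per gene (beta-dependent terms only), summed over
    samples.  y, mu: (G, N); r: (G, 1).

    Written as y log mu - (y + r) log1p(mu / r): the omitted (y + r) log r
    term does not depend on the mean, so it cancels in likelihood ratios,
    and log1p keeps the Poisson limit (large r) numerically exact.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return (term - (y + r) * np.log1p(mu / r)).sum(axis=1)


def _fit_nb_intercept(y: np.ndarray, offsets: np.ndarray, r: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 100
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the single-intercept NB GLM per gene by Fisher scoring.

    Returns (beta, loglik, converged) arrays of length G.  The likelihood
    is strictly concave in beta, so scoring with step clipping converges;
    genes that fail the gradient tolerance are flagged.
    """
    y = np.asarray(y, float)
    exp_off = np.exp(offsets - offsets.max(axis=1, keepdims=True))
    off_shift = offsets.max(axis=1, keepdims=True)
    total = y.sum(axis=1)
    beta = np.log((total + 0.1) / exp_off.sum(axis=1)) - off_shift[:, 0]
    grad = np.full_like(beta, np.inf)
    for _ in range(max_iter):
        mu = np.exp(beta[:, None] + offsets)
        grad = ((y - mu) * r / (r + mu)).sum(axis=1)
        info = (mu * r / (r + mu)).sum(axis=1)
        step = grad / np.maximum(info, 1e-300)
        np.clip(step, -5.0, 5.0, out=step)
        beta = np.clip(beta + step, -50.0, 50.0)
        if np.max(np.abs(grad)) < tol:
            break
    mu = np.exp(beta[:, None] + offsets)
    grad = ((y - mu) * r / (r + mu)).sum(axis=1)
    converged = (np.abs(grad) < 1e-4 * np.maximum(1.0, total)) | (total == 0)
    return beta, _nb_loglik(y, mu, r), converged


def nb_lrt_matrix(
    counts: pd.DataFrame,
    groups: pd.Series,
    offsets: pd.DataFrame | None,
    phi: pd.Series | float,
) -> pd.DataFrame:
    """Vectorized NB LRT over all genes.

    Under the alternative each group has its own intercept (so the two
    group fits are independent single-intercept problems); the null shares
    one intercept.  Twice the log-likelihood ratio is referred to
    chi-square with 1 df.  Reported log2 fold changes are treated minus
    placebo from offset-adjusted group means with a 0.125 prior count.
    """
    masks = _group_masks(counts.columns, groups)
    labels = list(masks)
    y = counts.to_numpy(float)
    if offsets is None:
        offsets = combined_offsets(counts)
    off = offsets.reindex(index=counts.index, columns=counts.columns).to_numpy(float)
    phi_arr = (np.full(len(counts), float(phi)) if np.isscalar(phi)
               else phi.reindex(counts.index).to_numpy(float))
    if np.isnan(phi_arr).any() or (phi_arr < 0).any():
        raise ValueError("dispersions must be finite and non-negative")
    r = np.where(phi_arr > 0, 1.0 / np.maximum(phi_arr, 1e-300), _POISSON_R)[:, None]

    _, ll_null, conv_null = _fit_nb_intercept(y, off, r)
    ll_alt = np.zeros_like(ll_null)
    converged = conv_null
    for lab in labels:
        mask = masks[lab]
        _, ll_k, conv_k = _fit_nb_intercept(y[:, mask], off[:, mask], r)
        ll_alt += ll_k
        converged &= conv_k

    lr = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lr, df=1)
    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("NB LRT failed to converge for %d gene(s); their "
                       "p-values are reported as NaN", n_bad)
        p = np.where(converged, p, np.nan)

    adj = _adjusted_counts(y, off)
    # treated minus placebo; fall back to second-listed group if labels differ
    lab_ref, lab_alt = labels[0], labels[1]
    if "placebo" in labels and "treated" in labels:
        lab_ref, lab_alt = "placebo", "treated"
    m_ref = adj[:, masks[lab_ref]].mean(axis=1)
    m_alt = adj[:, masks[lab_alt]].mean(axis=1)
    log2fc = np.log2((m_alt + PRIOR_COUNT) / (m_ref + PRIOR_COUNT))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "lr_statistic": lr,
         "mean_expression": np.log2(adj.mean(axis=1) + PRIOR_COUNT)},
        index=counts.index,
    )


def nb_lrt(
    counts_g: np.ndarray,
    groups: np.ndarray,
    offsets_g: np.ndarray | None,
    phi: float,
) -> tuple[float, float]:
    """Single-gene NB LRT; returns (log2_fold_change, p_value)."""
    counts_g = np.asarray(counts_g, float)
    cols = [f"s{i}" for i in range(len(counts_g))]
    counts = pd.DataFrame(counts_g[None, :], index=["gene"], columns=cols)
    groups_s = pd.Series(np.asarray(groups), index=cols)
    if offsets_g is None:
        off = None
    else:
        off = pd.DataFrame(np.asarray(offsets_g, float)[None, :],
                           index=["gene"], columns=cols)
    res = nb_lrt_matrix(counts, groups_s, off, float(phi))
    return float(res["log2fc"].iloc[0]), float(res["p_value"].iloc[0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up FDR: q_i = min_{j: p_j >= p_i} m p_j / rank_j,
    capped at 1.  NaN p-values propagate to NaN q-values with a warning."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        logger.warning("bh_fdr: %d NaN p-value(s) propagate to NaN FDRs",
                       int(nan_mask.sum()))
    valid = ~nan_mask
    pv = p[valid]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        qq = np.empty(m)
        qq[order] = np.minimum(qv, 1.0)
        q[valid] = qq
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index, name="fdr")
    return q


# ---------------------------------------------------------------------------
# Whole-pipeline differential expression
# ---------------------------------------------------------------------------

def run_de(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    metadata: pd.DataFrame,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
    normalized: NormalizedMatrix | None = None,
) -> pd.DataFrame:
    """Filter, normalize, estimate dispersions, test per gene, and BH-adjust.

    Returns a table indexed by gene_id with columns log2fc, p_value, fdr,
    direction, mean_expression, sorted by p-value.  *normalized* may be
    passed to reuse previously computed offsets.
    """
    groups = metadata["group"].reindex(counts.columns)
    kept = filter_low_counts(counts, groups)
    if len(kept) == 0:
        logger.warning("no genes pass the low-count filter; empty DE table")
        return pd.DataFrame(
            columns=["log2fc", "p_value", "fdr", "direction", "mean_expression"])
    if normalized is None:
        normalized = cqn_normalize(
            counts, annotation["gc_fraction"], annotation["length_bp"],
            fit_genes=kept)
    sub = counts.loc[kept]
    offsets = combined_offsets(sub, normalized.offsets.loc[kept])
    disp = estimate_dispersions(sub, groups, offsets, prior_weight=prior_weight)
    table = nb_lrt_matrix(sub, groups, offsets, disp.phi)
    table["fdr"] = bh_fdr(table["p_value"])
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    table["phi"] = disp.phi
    table.index.name = "gene_id"
    return table.sort_values("p_value", kind="stable")
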