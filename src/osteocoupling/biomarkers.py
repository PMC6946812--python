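"""Nonparametric endpoint statistics for serum markers and NPX proteomics.

Serum bone-turnover markers are compared between arms as per-subject
percent change from baseline with the Mann-Whitney U test (exact
enumeration up to a combined n of 20, tie-corrected normal approximation
beyond).  Olink NPX values, which live on a log2 scale, are converted to
linear scale (2**NPX) before the Kruskal-Wallis test — a monotone map, so
the rank-based p is unchanged; the conversion mirrors how the assay's
group comparisons are reported.  Correlations are Spearman throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr

logger = logging.getLogger("osteocoupling")

EXACT_MW_MAX_COMBINED_N = 20
DEFAULT_MARKER_PAIRS = (
    ("CTX", "P1NP"), ("CTX", "OCN"), ("TRAP5b", "P1NP"), ("TRAP5b", "OCN"),
)


@dataclass
class EndpointResult:
    """One endpoint comparison: group summaries, statistic and p-value."""

    name: str
    test: str
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]]   # group -> {n, mean, sd}

    def to_dict(self) -> dict:
        return {
            "name": self.name, "test": self.test,
            "statistic": self.statistic, "p_value": self.p_value,
            "groups": self.group_summaries,
        }


# ---------------------------------------------------------------------------
# Percent change from baseline
# ---------------------------------------------------------------------------

def percent_change(baseline: pd.Series, followup: pd.Series) -> pd.Series:
    """Per-subject percent change: 100 (followup - baseline) / baseline.

    Subjects are paired on the index; zero-baseline subjects are excluded
    with a warning.
    """
    shared = baseline.index.intersection(followup.index)
    b = baseline.loc[shared].astype(float)
    f = followup.loc[shared].astype(float)
    zero = b == 0
    if zero.any():
        logger.warning("%d subject(s) with zero baseline excluded from "
                       "percent change", int(zero.sum()))
    b, f = b[~zero], f[~zero]
    out = 100.0 * (f - b) / b
    out.name = "percent_change"
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Valid with ties (the permutation distribution conditions on the
    observed values).  Returns (U of group a, p).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    u_all = np.array([
        ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        for idx in itertools.combinations(range(n), n_a)
    ])
    p_low = np.mean(u_all <= u_obs + 1e-9)
    p_high = np.mean(u_all >= u_obs - 1e-9)
    return float(u_obs), float(min(1.0, 2.0 * min(p_low, p_high)))


def _mann_whitney_normal_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    u = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    mean = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return float(u), 1.0
    z = (abs(u - mean) - 0.5) / np.sqrt(var)
    return float(u), float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def mann_whitney_change(
    change_a: pd.Series | np.ndarray,
    change_b: pd.Series | np.ndarray,
    name: str = "",
    labels: tuple[str, str] = ("placebo", "treated"),
    method: str = "auto",
) -> EndpointResult:
    """Two-sided Mann-Whitney comparison of two groups of percent changes.

    ``method`` is ``"exact"`` (full enumeration), ``"normal"``
    (tie-corrected approximation) or ``"auto"`` (exact when the combined n
    is at most 20).
    """
    a = np.asarray(change_a, float)
    b = np.asarray(change_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if a.size + b.size <= EXACT_MW_MAX_COMBINED_N else "normal"
    if method == "exact":
        u, p = _mann_whitney_exact_p(a, b)
    elif method == "normal":
        u, p = _mann_whitney_normal_p(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    summaries = {
        labels[0]: {"n": int(a.size), "mean": float(a.mean()),
                    "sd": float(a.std(ddof=1)) if a.size > 1 else float("nan")},
        labels[1]: {"n": int(b.size), "mean": float(b.mean()),
                    "sd": float(b.std(ddof=1)) if b.size > 1 else float("nan")},
    }
    return EndpointResult(name=name, test=f"mann-whitney ({method})",
                          statistic=u, p_value=p, group_summaries=summaries)


def serum_percent_change_endpoints(
    serum: pd.DataFrame,
    metadata: pd.DataFrame,
    baseline_timepoint: str = "baseline",
    followup_timepoint: str = "month3",
) -> list[EndpointResult]:
    """Percent-change Mann-Whitney endpoints for every serum marker.

    *serum* is the long-form marker table; groups come from *metadata*
    (indexed by sample/subject id).
    """
    group_of = metadata["group"]
    results = []
    for marker, sub in serum.groupby("marker", sort=True):
        wide = sub.pivot_table(index="subject_id", columns="timepoint",
                               values="value", aggfunc="mean")
        if baseline_timepoint not in wide or followup_timepoint not in wide:
            logger.warning("marker %s lacks the requested timepoints; skipped",
                           marker)
            continue
        change = percent_change(wide[baseline_timepoint],
                                wide[followup_timepoint])
        groups = group_of.reindex(change.index)
        results.append(mann_whitney_change(
            change[groups == "placebo"], change[groups == "treated"],
            name=marker))
    return results


# ---------------------------------------------------------------------------
# Kruskal-Wallis on linear-scale NPX
# ---------------------------------------------------------------------------

def kruskal_wallis_npx(npx: pd.DataFrame, groups: pd.Series,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein Kruskal-Wallis test on linear-scale (2**NPX) values.

    Returns a table with H, p, BH-adjusted p (reported alongside; the
    per-protein significance count uses the unadjusted p < alpha) and the
    constant-protein flag (p = 1 by convention).
    """
    g = groups.reindex(npx.columns)
    if g.isna().any():
        raise ValueError(
            f"no group for sample(s): {npx.columns[g.isna()].tolist()[:5]}")
    labels = list(dict.fromkeys(g))
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    masks = [(g == lab).to_numpy() for lab in labels]
    if any(m.sum() < 1 for m in masks):
        raise ValueError("every group needs at least one sample")
    linear = 2.0 ** npx.to_numpy(float)
    rows = []
    for i, protein in enumerate(npx.index):
        values = linear[i]
        if np.ptp(values) == 0:
            rows.append((protein, 0.0, 1.0, True))
            continue
        h, p = stats.kruskal(*[values[m] for m in masks])
        rows.append((protein, float(h), float(p), False))
    table = pd.DataFrame(rows, columns=["protein_id", "H", "p_value",
                                        "constant"]).set_index("protein_id")
    table["fdr"] = bh_fdr(table["p_value"])
    table["significant"] = table["p_value"] < alpha
    return table


# ---------------------------------------------------------------------------
# Correlation endpoints
# ---------------------------------------------------------------------------

def baseline_marker_correlations(
    measures: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_MARKER_PAIRS,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Pairwise Spearman correlations between baseline markers.

    *measures* is subjects x markers (one row per subject).  Pairs lacking
    *min_overlap* complete observations are skipped with a warning.
    """
    rows = []
    for x, y in pairs:
        if x not in measures.columns or y not in measures.columns:
            logger.warning("marker pair (%s, %s) absent from the table; "
                           "skipped", x, y)
            continue
        sub = measures[[x, y]].dropna()
        if len(sub) < min_overlap:
            logger.warning("marker pair (%s, %s) has %d complete pair(s); "
                           "skipped", x, y, len(sub))
            continue
        res = stats.spearmanr(sub[x].to_numpy(), sub[y].to_numpy())
        rows.append((x, y, float(res.statistic), float(res.pvalue), len(sub)))
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "rho",
                                       "p_value", "n"])


def protein_geneset_correlation(
    npx: pd.DataFrame,
    profiles: dict[str, pd.Series],
    sample_map: dict[str, str] | None = None,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Spearman of each protein's linear-scale level vs gene-set profiles.

    Rank-mean profiles are NEGATED before correlating so the reported rho
    refers to expression (low rank mean = high expression); a protein that
    tracks a program's expression therefore reports a positive rho.
    *sample_map* maps NPX sample ids to profile subject ids when they differ.
    """
    rows = []
    npx_cols = pd.Index([sample_map.get(c, c) for c in npx.columns]
                        if sample_map else npx.columns)
    linear = pd.DataFrame(2.0 ** npx.to_numpy(float), index=npx.index,
                          columns=npx_cols)
    for set_name, profile in profiles.items():
        expression_score = -profile
        shared = expression_score.index.intersection(linear.columns)
        if len(shared) < min_overlap:
            logger.warning("profile %s overlaps %d NPX sample(s); skipped",
                           set_name, len(shared))
            continue
        for protein in linear.index:
            res = stats.spearmanr(linear.loc[protein, shared].to_numpy(),
                                  expression_score.loc[shared].to_numpy())
            rows.append((protein, set_name, float(res.statistic),
                         float(res.pvalue), len(shared)))
    return pd.DataFrame(rows, columns=["protein_id", "gene_set", "rho",
                                       "p_value", "n"])
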