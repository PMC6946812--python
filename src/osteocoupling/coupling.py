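"""Within-subject rank-mean gene-set coupling.

The coupling statistic asks whether two gene programs (osteoclast and
osteoblast markers) co-vary across subjects.  For each subject, all
detected genes are ranked by normalized expression from high to low (rank
1 = highest, average ties); a gene set's profile is the per-subject mean of
its members' ranks; and the coupling between two sets is the Spearman
correlation of their profiles.  Because high expression maps to a LOW rank,
a positive correlation of two rank-mean profiles means the two programs
rise and fall together.

Significance comes from a randomization test: the observed correlation is
compared with correlations of randomly drawn, size-matched, disjoint gene
sets (5000 draws by default), with a one-sided add-one p-value
p = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

logger = logging.getLogger("osteocoupling")

DEFAULT_N_PERMUTATIONS = 5000


def within_subject_ranks(values: pd.DataFrame) -> pd.DataFrame:
    """Rank genes within each sample from high to low (rank 1 = highest).

    Ties receive average ranks, so each column's rank sum is G(G+1)/2.
    """
    arr = values.to_numpy(float)
    if arr.shape[0] < 2:
        raise ValueError("ranking needs at least 2 genes")
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"NaN expression for gene {values.index[g]!r}, "
            f"sample {values.columns[s]!r}"
        )
    ranks = stats.rankdata(-arr, axis=0, method="average")
    return pd.DataFrame(ranks, index=values.index, columns=values.columns)


def heatmap_ranks(values: pd.DataFrame, samples: list[str] | None = None
                  ) -> pd.DataFrame:
    """Per-gene ranks across samples (rank 1 = highest), for heat-map export.

    Restricting *samples* re-ranks within the subset only.
    """
    sub = values if samples is None else values[list(samples)]
    if sub.shape[1] < 2:
        raise ValueError("across-sample ranking needs at least 2 samples")
    if np.isnan(sub.to_numpy()).any():
        raise ValueError("expression matrix contains NaN values")
    ranks = stats.rankdata(-sub.to_numpy(float), axis=1, method="average")
    return pd.DataFrame(ranks, index=sub.index, columns=sub.columns)


def gene_set_rank_mean(
    ranks: pd.DataFrame,
    gene_set: GeneSet,
    subjects: list[str] | None = None,
) -> pd.Series:
    """Per-subject mean of the set members' within-subject ranks.

    Members absent from the detected-gene universe are dropped with a
    logged warning; an empty intersection is an error.
    """
    present = gene_set.intersect(ranks.index)
    if len(present) == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no members in the gene universe")
    cols = ranks.columns if subjects is None else pd.Index(subjects)
    missing = cols.difference(ranks.columns)
    if len(missing):
        raise ValueError(f"unknown subject(s): {missing.tolist()}")
    profile = ranks.loc[list(present.genes), cols].mean(axis=0)
    profile.name = gene_set.name
    return profile


def coupling_correlation(profile_a: pd.Series, profile_b: pd.Series) -> float:
    """Spearman correlation of two rank-mean profiles over shared subjects."""
    if not profile_a.index.equals(profile_b.index):
        raise ValueError("profiles must cover the same subjects in the same order")
    if len(profile_a) < 3:
        raise ValueError("need at least 3 subjects")
    a = profile_a.to_numpy(float)
    b = profile_b.to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant profile: Spearman correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


@dataclass
class CouplingResult:
    """Observed coupling with its randomization null."""

    rho_observed: float
    p_permutation: float
    p_asymptotic: float          # Spearman's asymptotic p for the observed rho
    n_permutations: int
    null_rhos: np.ndarray
    seed: int
    set_a_used: int              # set sizes after universe intersection
    set_b_used: int

    def summary(self) -> dict:
        return {
            "rho_observed": self.rho_observed,
            "p_permutation": self.p_permutation,
            "p_asymptotic": self.p_asymptotic,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "set_a_used": self.set_a_used,
            "set_b_used": self.set_b_used,
        }


def _spearman_many(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman of two (R, n) matrices (average ties)."""
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra ** 2).sum(axis=1) * (rb ** 2).sum(axis=1))
    return (ra * rb).sum(axis=1) / denom


def randomization_test(
    ranks: pd.DataFrame,
    set_a: GeneSet,
    set_b: GeneSet,
    subjects: list[str] | None = None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> CouplingResult:
    """Random-gene-set null for the coupling of *set_a* and *set_b*.

    Each replicate draws two disjoint gene sets, size-matched to the
    observed sets after intersection with the detected-gene universe,
    computes their rank-mean profiles over the chosen subjects, and records
    their Spearman correlation.  One-sided p with add-one correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    profile_a = gene_set_rank_mean(ranks, set_a, subjects)
    profile_b = gene_set_rank_mean(ranks, set_b, subjects)
    rho_obs = coupling_correlation(profile_a, profile_b)
    p_asym = float(stats.spearmanr(profile_a.to_numpy(),
                                   profile_b.to_numpy()).pvalue)

    n_a = len(set_a.intersect(ranks.index))
    n_b = len(set_b.intersect(ranks.index))
    n_genes = ranks.shape[0]
    if n_a + n_b > n_genes:
        raise ValueError(
            f"universe of {n_genes} genes cannot hold disjoint sets of sizes "
            f"{n_a} and {n_b}"
        )
    cols = ranks.columns if subjects is None else pd.Index(subjects)
    rank_arr = ranks[cols].to_numpy(float)

    rng = np.random.default_rng(seed)
    # (n_perm, n_a + n_b) disjoint index draws without replacement
    draws = np.empty((n_perm, n_a + n_b), dtype=np.intp)
    for i in range(n_perm):
        draws[i] = rng.choice(n_genes, size=n_a + n_b, replace=False)
    prof_a = rank_arr[draws[:, :n_a]].mean(axis=1)
    prof_b = rank_arr[draws[:, n_a:]].mean(axis=1)
    null_rhos = _spearman_many(prof_a, prof_b)
    p_perm = (1.0 + np.count_nonzero(null_rhos >= rho_obs)) / (n_perm + 1.0)
    return CouplingResult(
        rho_observed=rho_obs,
        p_permutation=float(p_perm),
        p_asymptotic=p_asym,
        n_permutations=n_perm,
        null_rhos=null_rhos,
        seed=seed,
        set_a_used=n_a,
        set_b_used=n_b,
    )


def correlate_with_measures(
    profile: pd.Series,
    measures: pd.DataFrame,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of a rank-mean profile with external measures.

    *measures* is subjects x measures.  Pairwise-complete; measures with
    fewer than *min_overlap* overlapping subjects are skipped with a
    warning.  NOTE the sign convention: a LOW rank mean means HIGH
    expression, so a measure tracking expression correlates negatively with
    the raw profile.
    """
    rows = []
    for name in measures.columns:
        m = measures[name].dropna()
        shared = profile.index.intersection(m.index)
        if len(shared) < min_overlap:
            logger.warning("measure %s skipped: only %d overlapping subject(s)",
                           name, len(shared))
            continue
        res = stats.spearmanr(profile.loc[shared].to_numpy(),
                              m.loc[shared].to_numpy())
        rows.append((name, float(res.statistic), float(res.pvalue), len(shared)))
    return pd.DataFrame(rows, columns=["measure", "rho", "p_value", "n"]
                        ).set_index("measure")
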