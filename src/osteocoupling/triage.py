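"""Multi-stage triage of osteoclast-derived secreted candidate factors.

Stage 1 takes the treatment-suppressed, secreted-annotated genes from the
centrifuged-bone differential-expression table.  Stage 2 removes those also
suppressed in the osteocyte-enriched fraction (genes below the osteocyte
detection limit stay in play: they cannot be osteocyte-regulated), leaving
the surface-restricted set.  Stage 3 asks which suppressed secreted genes
are expressed higher in cultured osteoclasts than in osteoblast-enriched
digests, by paired qPCR normalized to the most stable housekeeping genes
(geNorm) and tested with the exact Wilcoxon signed-rank test.  The final
candidates are the surface-restricted genes that are osteoclast-enriched.

geNorm stability: for genes j, k let A_jk be the per-sample log2 ratio of
their relative quantities; the pairwise variation V_jk is the standard
deviation of A_jk across samples, and the stability M_j is the mean of
V_jk over k != j.  The least stable gene (highest M) is removed and M is
recomputed until the requested number of reference genes remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

logger = logging.getLogger("osteocoupling")

DEFAULT_ALPHA = 0.05
DEFAULT_N_KEEP = 3
DEFAULT_EFFICIENCY = 2.0     # assumed qPCR amplification efficiency
MIN_COMPLETE_PAIRS = 5
EXACT_WILCOXON_MAX_N = 25


# ---------------------------------------------------------------------------
# Stage 1: suppressed / upregulated secreted genes
# ---------------------------------------------------------------------------

def classify_secreted_de(
    de: pd.DataFrame,
    secreted: GeneSet,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[str], list[str]]:
    """Split secreted genes into treatment-suppressed and -upregulated.

    Suppressed: p < alpha and log2fc < 0; upregulated: p < alpha and
    log2fc > 0.  Order follows the DE table.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    members = set(secreted.genes)
    sub = de[de.index.isin(members)]
    sig = sub["p_value"] < alpha
    suppressed = sub.index[sig & (sub["log2fc"] < 0)].tolist()
    upregulated = sub.index[sig & (sub["log2fc"] > 0)].tolist()
    return suppressed, upregulated


# ---------------------------------------------------------------------------
# Stage 2: osteocyte overlap
# ---------------------------------------------------------------------------

def osteocyte_overlap(
    suppressed: list[str],
    de_osteocyte: pd.DataFrame,
    detected_osteocyte: list[str],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, list[str]]:
    """Partition suppressed secreted genes by their osteocyte behaviour.

    ``osteocyte_suppressed``: also significantly decreased (p < alpha,
    negative log2fc) in the osteocyte-enriched fraction.
    ``undetected``: below the osteocyte detection limit.
    ``surface_restricted``: everything not osteocyte-suppressed (undetected
    genes included — absence of osteocyte expression cannot rule them out).
    """
    detected = set(detected_osteocyte)
    in_table = de_osteocyte.index.intersection(suppressed)
    tab = de_osteocyte.loc[in_table]
    ocy_sig = set(tab.index[(tab["p_value"] < alpha) & (tab["log2fc"] < 0)])
    osteocyte_suppressed = [g for g in suppressed if g in ocy_sig and g in detected]
    undetected = [g for g in suppressed if g not in detected]
    surface_restricted = [g for g in suppressed if g not in set(osteocyte_suppressed)]
    return {
        "osteocyte_suppressed": osteocyte_suppressed,
        "undetected": undetected,
        "surface_restricted": surface_restricted,
    }


# ---------------------------------------------------------------------------
# qPCR quantities and geNorm reference selection
# ---------------------------------------------------------------------------

def ct_to_quantity(ct: np.ndarray | float,
                   efficiency: float = DEFAULT_EFFICIENCY):
    """Relative quantity from a Ct value: efficiency ** (-Ct)."""
    return np.asarray(efficiency, dtype=float) ** (-np.asarray(ct, dtype=float))


def qpcr_quantities(
    qpcr: pd.DataFrame,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Pivot a long qPCR table into gene x (participant, cell_type) quantities.

    Missing Ct values propagate as NaN with a logged count.
    """
    n_missing = int(qpcr["ct"].isna().sum())
    if n_missing:
        logger.warning("qPCR table has %d missing Ct value(s)", n_missing)
    wide = qpcr.pivot_table(index="gene", columns=["participant", "cell_type"],
                            values="ct", aggfunc="mean")
    return efficiency ** (-wide)


@dataclass
class GeNormResult:
    """geNorm reference-gene selection outcome.

    ``m_initial`` holds every panel gene's stability on the full panel;
    ``elimination_order`` lists removed genes, least stable first;
    ``selected`` are the surviving reference genes and ``factors`` the
    per-sample normalization factor (geometric mean of their quantities).
    """

    m_initial: pd.Series
    elimination_order: list[str]
    selected: tuple[str, ...]
    factors: pd.Series


def genorm_m_values(quantities: pd.DataFrame) -> pd.Series:
    """Stability M per gene: mean over partners of the SD of per-sample
    pairwise log2 ratios."""
    q = quantities.to_numpy(float)
    if (q <= 0).any() or np.isnan(q).any():
        raise ValueError("geNorm requires positive, complete quantities")
    logq = np.log2(q)
    n = len(quantities)
    m = np.empty(n)
    for j in range(n):
        diffs = logq[j][None, :] - logq   # (n, samples)
        v = diffs.std(axis=1, ddof=1)
        m[j] = np.delete(v, j).mean()
    return pd.Series(m, index=quantities.index, name="M")


def genorm_select(quantities: pd.DataFrame,
                  n_keep: int = DEFAULT_N_KEEP) -> GeNormResult:
    """Iteratively eliminate the least stable gene until n_keep remain.

    Ties in the maximal M are broken by removing the lexicographically last
    gene ID.  Quantities must be positive; at least n_keep + 1 genes and
    2 samples are required.
    """
    if len(quantities) < n_keep + 1:
        raise ValueError(
            f"need at least {n_keep + 1} panel genes, got {len(quantities)}")
    if quantities.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    m_initial = genorm_m_values(quantities)
    remaining = quantities.copy()
    elimination: list[str] = []
    while len(remaining) > n_keep:
        m = genorm_m_values(remaining)
        worst = m.max()
        candidates = sorted(m.index[m == worst])
        victim = candidates[-1]
        elimination.append(victim)
        remaining = remaining.drop(index=victim)
    factors = np.exp(np.log(remaining.to_numpy(float)).mean(axis=0))
    return GeNormResult(
        m_initial=m_initial,
        elimination_order=elimination,
        selected=tuple(remaining.index),
        factors=pd.Series(factors, index=quantities.columns, name="factor"),
    )


def qpcr_normalize(quantities: pd.DataFrame,
                   genorm: GeNormResult) -> pd.DataFrame:
    """Divide each sample's quantities by its housekeeping factor."""
    factors = genorm.factors.reindex(quantities.columns)
    if (factors <= 0).any() or factors.isna().any():
        raise ValueError("normalization factors must be positive and cover "
                         "every sample")
    return quantities / factors


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, int]:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped (standard convention).  For n <= 25 the
    null distribution of W+ (sum of ranks of positive differences, average
    ties) is computed exactly over all 2^n sign patterns by dynamic
    programming on doubled ranks; beyond that, a tie-corrected normal
    approximation with continuity correction is used.  Returns (p, n_used).
    """
    d = np.asarray(differences, float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        r2 = np.round(2 * ranks).astype(int)      # doubled ranks are integers
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = dist + shifted
        dist /= 2.0 ** n
        w2 = int(round(2 * w_pos))
        p_low = dist[: w2 + 1].sum()
        p_high = dist[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = (n * (n + 1) * (2 * n + 1) / 24.0
               - (tie_counts ** 3 - tie_counts).sum() / 48.0)
        z = (abs(w_pos - mean) - 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return float(p), n


def wilcoxon_paired_oc_ob(
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    min_pairs: int = MIN_COMPLETE_PAIRS,
) -> pd.DataFrame:
    """Paired osteoclast-vs-osteoblast test per gene.

    *expr* has a (participant, cell_type) column MultiIndex with cell types
    ``Ob`` and ``Oc``.  Genes with fewer than *min_pairs* complete pairs are
    skipped with a warning.  Returns per-gene two-sided p and the median
    Oc - Ob difference.
    """
    cell_types = expr.columns.get_level_values("cell_type")
    if not {"Ob", "Oc"} <= set(cell_types):
        raise ValueError("expression matrix must contain Ob and Oc samples")
    ob = expr.xs("Ob", axis=1, level="cell_type")
    oc = expr.xs("Oc", axis=1, level="cell_type")
    shared = ob.columns.intersection(oc.columns)
    rows = []
    for gene in (expr.index if genes is None else genes):
        if gene not in expr.index:
            logger.warning("gene %s absent from the qPCR data; skipped", gene)
            continue
        d = (oc.loc[gene, shared] - ob.loc[gene, shared]).to_numpy(float)
        d = d[~np.isnan(d)]
        if d.size < min_pairs:
            logger.warning("gene %s has %d complete pair(s) (< %d); skipped",
                           gene, d.size, min_pairs)
            continue
        p, n_used = wilcoxon_signed_rank(d)
        rows.append((gene, float(np.median(d)), p, n_used))
    return pd.DataFrame(
        rows, columns=["gene_id", "median_oc_minus_ob", "p_value", "n_pairs"]
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# The full triage
# ---------------------------------------------------------------------------

@dataclass
class TriageReport:
    """Per-stage outcome of the secreted-factor triage."""

    suppressed_secreted: list[str]
    upregulated_secreted: list[str]
    osteocyte_suppressed: list[str]
    osteocyte_undetected: list[str]
    surface_restricted: list[str]
    oc_enriched: list[str]
    final_candidates: list[str]
    genorm: GeNormResult | None = None
    wilcoxon: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        # Set algebra the stages must satisfy, by construction.
        assert set(self.surface_restricted) == (
            set(self.suppressed_secreted) - set(self.osteocyte_suppressed))
        assert set(self.final_candidates) == (
            set(self.surface_restricted) & set(self.oc_enriched))

    @property
    def counts(self) -> dict[str, int]:
        return {
            "suppressed_secreted": len(self.suppressed_secreted),
            "upregulated_secreted": len(self.upregulated_secreted),
            "osteocyte_suppressed": len(self.osteocyte_suppressed),
            "osteocyte_undetected": len(self.osteocyte_undetected),
            "surface_restricted": len(self.surface_restricted),
            "oc_enriched": len(self.oc_enriched),
            "final_candidates": len(self.final_candidates),
        }

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "suppressed_secreted": self.suppressed_secreted,
            "upregulated_secreted": self.upregulated_secreted,
            "osteocyte_suppressed": self.osteocyte_suppressed,
            "osteocyte_undetected": self.osteocyte_undetected,
            "surface_restricted": self.surface_restricted,
            "oc_enriched": self.oc_enriched,
            "final_candidates": self.final_candidates,
        }


def run_triage(
    de_centrifuged: pd.DataFrame,
    de_osteocyte: pd.DataFrame,
    detected_osteocyte: list[str],
    secreted: GeneSet,
    qpcr: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_keep: int = DEFAULT_N_KEEP,
    efficiency: float = DEFAULT_EFFICIENCY,
    housekeeping: tuple[str, ...] | None = None,
) -> TriageReport:
    """Run the three triage stages end to end.

    *housekeeping* names the reference panel within the qPCR table
    (defaults to the packaged nine-gene panel intersected with the table).
    Osteoclast enrichment requires two-sided Wilcoxon p < alpha AND a
    positive median Oc - Ob difference.
    """
    from .synthetic import HOUSEKEEPING_PANEL

    suppressed, upregulated = classify_secreted_de(de_centrifuged, secreted, alpha)
    partition = osteocyte_overlap(suppressed, de_osteocyte,
                                  detected_osteocyte, alpha)

    quantities = qpcr_quantities(qpcr, efficiency=efficiency)
    if housekeeping is None:
        housekeeping = tuple(g for g in HOUSEKEEPING_PANEL
                             if g in quantities.index)
    genorm = genorm_select(quantities.loc[list(housekeeping)], n_keep=n_keep)
    expr = qpcr_normalize(quantities, genorm)
    targets = [g for g in suppressed if g in expr.index]
    wilcoxon = wilcoxon_paired_oc_ob(expr, genes=targets)
    enriched_mask = (wilcoxon["p_value"] < alpha) & \
                    (wilcoxon["median_oc_minus_ob"] > 0)
    oc_enriched = wilcoxon.index[enriched_mask].tolist()

    surface = partition["surface_restricted"]
    final = [g for g in surface if g in set(oc_enriched)]
    return TriageReport(
        suppressed_secreted=suppressed,
        upregulated_secreted=upregulated,
        osteocyte_suppressed=partition["osteocyte_suppressed"],
        osteocyte_undetected=partition["undetected"],
        surface_restricted=surface,
        oc_enriched=oc_enriched,
        final_candidates=final,
        genorm=genorm,
        wilcoxon=wilcoxon,
    )
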