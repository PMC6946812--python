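"""Synthetic bone-biopsy cohort generator.

Emulates the statistical structure of a two-arm anti-resorptive trial in
which an anti-RANKL antibody ablates osteoclasts: a per-subject latent
remodeling activity ``a_i ~ Normal(0, 1)`` jointly drives osteoclast- and
osteoblast-program genes (producing the transcriptional coupling), counts
are negative-binomial with GC-content technical trends, treatment suppresses
the osteoclast program (and, via coupling, a fraction of the osteoblast
program), and serum markers / NPX proteins are affine in the same latent
activity.

Count model
-----------
For gene g in sample i,

    mu_gi = L_i * q_g * 2**(b_g * a_i - x_i * delta_g + f(gc_g))
    counts_gi ~ NB(mean = mu_gi, var = mu_gi + phi * mu_gi**2)

where ``L_i`` is the library size (log-uniform within ``lib_size_range``),
``q_g`` the baseline relative abundance (log-normal, sigma = 1.5 on the log2
scale, normalized to sum to one), ``x_i`` the treatment indicator, ``f`` a
quadratic GC trend ``gc_effect * gc**2``, ``b_g = coupling_loading`` for
program genes (0 otherwise), and ``delta_g`` equal to ``suppression_log2fc``
for osteoclast-program genes and ``coupled_ob_fraction *
suppression_log2fc`` for osteoblast-program genes.

The variance convention ``var = mu + phi * mu**2`` matches the NB
parameterization used throughout :mod:`osteocoupling.diffexp`.

Each component (gene/sample structure, counts, serum markers, NPX) draws
from its own RNG stream spawned from the master seed, so adding a component
never perturbs another component's draws; the same seed yields a
bit-identical study.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ocio
from .io import ConfigError, GeneSet

__all__ = [
    "CohortConfig", "SyntheticTruth", "SyntheticStudy",
    "simulate_cohort", "emit_study", "load_study",
    "simulate_qpcr", "triage_fixture",
    "HOUSEKEEPING_PANEL",
]

#: The nine-gene housekeeping panel screened for qPCR normalization.
HOUSEKEEPING_PANEL = (
    "ACTB", "B2M", "G6PD", "GAPDH", "GUSB", "POLR2A", "RPL13A", "TBP", "TUBA1A",
)

#: Serum bone-turnover markers: loading on the latent remodeling activity
#: (resorption markers load strongest), baseline intercept (assay units), and
#: multiplicative 3-month change under treatment (placebo is 1.0). The
#: treated multipliers emulate the strong suppression of resorption markers
#: (CTX, TRAP5b) and the coupling-mediated decline of formation markers
#: (P1NP, OCN) seen under osteoclast ablation.
SERUM_MARKERS: dict[str, dict[str, float]] = {
    "CTX":    {"loading": 1.0, "intercept": 10.0, "treated_multiplier": 0.10},
    "P1NP":   {"loading": 1.0, "intercept": 10.0, "treated_multiplier": 0.40},
    "TRAP5b": {"loading": 0.6, "intercept": 10.0, "treated_multiplier": 0.45},
    "OCN":    {"loading": 0.5, "intercept": 10.0, "treated_multiplier": 0.60},
}

#: NPX proteomics panel: latent-activity loading and log2 treatment shift.
#: DPP4-like and CST3-like proteins track remodeling and fall under
#: treatment; the NULL proteins are unrelated to both.
NPX_PANEL: dict[str, dict[str, float]] = {
    "DPP4": {"loading": 1.0, "treatment_log2fc": -0.5},
    "CST3": {"loading": 0.8, "treatment_log2fc": -0.8},
    "LIF":  {"loading": 0.6, "treatment_log2fc": -0.6},
    **{f"NULL{i:02d}": {"loading": 0.0, "treatment_log2fc": 0.0} for i in range(1, 10)},
}

#: Calibrated so that the population Spearman correlation between the
#: osteoclast- and osteoblast-program rank-mean profiles is ~0.75 at the
#: study's scale (15 placebo subjects, 2000 detected genes, 8-gene sets,
#: dispersion 0.2) — the coupling-strength regime the analysis targets.
DEFAULT_COUPLING_LOADING = 0.50


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated two-arm cohort.

    ``coupling_loading`` is in log2-expression units per latent-activity
    unit; ``suppression_log2fc`` is the log2 fold suppression of the
    osteoclast program under treatment, of which ``coupled_ob_fraction``
    propagates to the osteoblast program.
    """

    n_placebo: int = 15
    n_treated: int = 15
    n_genes: int = 2000
    set_size_oc: int = 8
    set_size_ob: int = 8
    n_secreted: int = 55
    secreted_in_oc: int = 3
    coupling_loading: float = DEFAULT_COUPLING_LOADING
    suppression_log2fc: float = 1.5
    coupled_ob_fraction: float = 0.5
    dispersion: float = 0.2
    lib_size_range: tuple[int, int] = (1_000_000, 3_000_000)
    gc_effect: float = 4.0
    marker_noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_placebo", "n_treated", "n_genes", "set_size_oc",
                     "set_size_ob", "n_secreted"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.set_size_oc + self.set_size_ob + len(HOUSEKEEPING_PANEL) > self.n_genes:
            raise ConfigError(
                "set_size_oc + set_size_ob + housekeeping panel exceed n_genes"
            )
        n_reserved = self.set_size_oc + self.set_size_ob + len(HOUSEKEEPING_PANEL)
        if self.n_secreted - self.secreted_in_oc > self.n_genes - n_reserved:
            raise ConfigError("n_secreted does not fit outside the program "
                              "and housekeeping genes")
        if not 0 <= self.secreted_in_oc <= min(self.set_size_oc, self.n_secreted):
            raise ConfigError("secreted_in_oc must fit in both the OC program "
                              "and the secreted set")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not 0.0 <= self.coupled_ob_fraction <= 1.0:
            raise ConfigError("coupled_ob_fraction must lie in [0, 1]")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("lib_size_range must be a positive, ordered pair")
        if self.marker_noise_sd < 0:
            raise ConfigError("marker_noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery and calibration tests."""

    latent_activity: pd.Series            # per subject, a_i
    true_de_genes: pd.Series              # signed log2 effect per truly DE gene
    program_memberships: dict[str, str]   # gene -> {"oc", "ob"}
    marker_loadings: dict[str, float]


@dataclass
class SyntheticStudy:
    """A complete simulated study: counts, annotation, metadata, gene sets,
    serum markers, NPX proteomics, and the generating truth."""

    config: CohortConfig
    counts: pd.DataFrame                  # genes x samples, int
    gene_annotation: pd.DataFrame         # gc_fraction, length_bp, secreted
    metadata: pd.DataFrame                # sample_id -> subject_id, group
    gene_sets: dict[str, GeneSet]         # oc_program, ob_program, secreted, housekeeping
    serum: pd.DataFrame                   # long form: subject_id, marker, timepoint, value
    npx: pd.DataFrame                     # proteins x samples, log2 NPX
    truth: SyntheticTruth


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohort(config: CohortConfig) -> SyntheticStudy:
    """Draw one synthetic study under *config*. Deterministic given the seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_structure, rng_counts, rng_serum, rng_npx = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n_subjects = config.n_placebo + config.n_treated
    subjects = [f"S{i:03d}" for i in range(1, n_subjects + 1)]
    group = np.array(["placebo"] * config.n_placebo + ["treated"] * config.n_treated)
    x = (group == "treated").astype(float)

    genes = _gene_ids(config.n_genes)
    # Baseline relative abundance: log-normal, sigma = 1.5 on log2 scale.
    q = 2.0 ** rng_structure.normal(0.0, 1.5, size=config.n_genes)
    q /= q.sum()
    gc = rng_structure.beta(20.0, 20.0, size=config.n_genes)
    length = 10 ** rng_structure.uniform(np.log10(300), np.log10(30_000),
                                         size=config.n_genes)
    lo, hi = config.lib_size_range
    lib_sizes = np.exp(rng_structure.uniform(np.log(lo), np.log(hi), size=n_subjects))
    latent = rng_structure.normal(0.0, 1.0, size=n_subjects)

    # Program membership: OC and OB sets disjoint, housekeeping panel apart
    # from both, the secreted set overlapping the OC program in
    # `secreted_in_oc` genes.
    perm = rng_structure.permutation(config.n_genes)
    oc_idx = perm[: config.set_size_oc]
    ob_idx = perm[config.set_size_oc: config.set_size_oc + config.set_size_ob]
    hk_start = config.set_size_oc + config.set_size_ob
    hk_idx = perm[hk_start: hk_start + len(HOUSEKEEPING_PANEL)]
    rest = perm[hk_start + len(HOUSEKEEPING_PANEL):]
    n_extra_secreted = config.n_secreted - config.secreted_in_oc
    secreted_idx = np.concatenate(
        [oc_idx[: config.secreted_in_oc], rest[:n_extra_secreted]]
    ).astype(int)

    b = np.zeros(config.n_genes)
    b[oc_idx] = config.coupling_loading
    b[ob_idx] = config.coupling_loading
    delta = np.zeros(config.n_genes)
    delta[oc_idx] = config.suppression_log2fc
    delta[ob_idx] = config.coupled_ob_fraction * config.suppression_log2fc

    log2_shift = (np.outer(b, latent)
                  - np.outer(delta, x)
                  + (config.gc_effect * gc ** 2)[:, None])
    mu = lib_sizes[None, :] * q[:, None] * 2.0 ** log2_shift

    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        counts = rng_counts.negative_binomial(r, p)
    else:
        counts = rng_counts.poisson(mu)
    counts_df = pd.DataFrame(counts.astype(np.int64),
                             index=pd.Index(genes, name="gene_id"),
                             columns=subjects)

    secreted_flag = np.zeros(config.n_genes, dtype=int)
    secreted_flag[secreted_idx] = 1
    annotation = pd.DataFrame(
        {"gc_fraction": gc, "length_bp": np.round(length).astype(int),
         "secreted": secreted_flag},
        index=pd.Index(genes, name="gene_id"),
    )
    metadata = pd.DataFrame(
        {"subject_id": subjects, "group": group},
        index=pd.Index(subjects, name="sample_id"),
    )

    genes_arr = np.asarray(genes)
    gene_sets = {
        "oc_program": GeneSet("oc_program", tuple(genes_arr[oc_idx]),
                              "osteoclast marker program"),
        "ob_program": GeneSet("ob_program", tuple(genes_arr[ob_idx]),
                              "osteoblast lineage program"),
        "secreted": GeneSet("secreted", tuple(genes_arr[np.sort(secreted_idx)]),
                            "annotated secreted genes"),
        "housekeeping": GeneSet("housekeeping", tuple(genes_arr[hk_idx]),
                                "stable reference genes"),
    }

    # Serum markers: baseline affine in the latent activity; 3-month value is
    # baseline times a group-specific multiplier with log-normal noise.
    serum_rows = []
    for marker, m_params in SERUM_MARKERS.items():
        baseline = (m_params["intercept"] + m_params["loading"] * latent
                    + rng_serum.normal(0.0, config.marker_noise_sd, n_subjects))
        multiplier = np.where(x > 0, m_params["treated_multiplier"], 1.0)
        followup = baseline * multiplier * np.exp(
            rng_serum.normal(0.0, 0.15, n_subjects))
        for s, b0, f0 in zip(subjects, baseline, followup):
            serum_rows.append((s, marker, "baseline", b0))
            serum_rows.append((s, marker, "month3", f0))
    serum = pd.DataFrame(serum_rows,
                         columns=["subject_id", "marker", "timepoint", "value"])

    # NPX proteomics (log2 scale): affine in the latent activity plus a log2
    # treatment shift.
    npx_values = {}
    for protein, p_params in NPX_PANEL.items():
        npx_values[protein] = (
            5.0 + p_params["loading"] * latent + p_params["treatment_log2fc"] * x
            + rng_npx.normal(0.0, config.marker_noise_sd, n_subjects)
        )
    npx = pd.DataFrame(npx_values, index=subjects).T
    npx.index.name = "protein_id"

    memberships = {g: "oc" for g in genes_arr[oc_idx]}
    memberships.update({g: "ob" for g in genes_arr[ob_idx]})
    effects = pd.concat([
        pd.Series(-config.suppression_log2fc, index=genes_arr[oc_idx]),
        pd.Series(-config.coupled_ob_fraction * config.suppression_log2fc,
                  index=genes_arr[ob_idx]),
    ])
    truth = SyntheticTruth(
        latent_activity=pd.Series(latent, index=subjects, name="latent_activity"),
        true_de_genes=effects,
        program_memberships=memberships,
        marker_loadings={m: s["loading"] for m, s in SERUM_MARKERS.items()},
    )
    return SyntheticStudy(config, counts_df, annotation, metadata, gene_sets,
                          serum, npx, truth)


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

def emit_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write a study to *directory* in the pipeline's plain-text formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "annotation": directory / "gene_annotation.tsv",
        "metadata": directory / "metadata.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "serum": directory / "serum.csv",
        "npx": directory / "npx.csv",
        "truth": directory / "truth.json",
    }
    ocio.write_counts(study.counts, paths["counts"])
    ocio.write_annotation(study.gene_annotation, paths["annotation"])
    ocio.write_metadata(study.metadata, paths["metadata"])
    ocio.write_gmt(study.gene_sets, paths["gene_sets"])
    ocio.write_serum(study.serum, paths["serum"])
    ocio.write_npx(study.npx, paths["npx"])
    ocio.write_json(
        {
            "config": {**asdict(study.config),
                       "lib_size_range": list(study.config.lib_size_range)},
            "latent_activity": study.truth.latent_activity.to_dict(),
            "true_de_genes": study.truth.true_de_genes.to_dict(),
            "program_memberships": study.truth.program_memberships,
            "marker_loadings": study.truth.marker_loadings,
        },
        paths["truth"],
    )
    return paths


def load_study(directory: str | Path) -> SyntheticStudy:
    """Re-read a study emitted by :func:`emit_study`."""
    directory = Path(directory)
    counts, annotation = ocio.read_counts(directory / "counts.tsv",
                                          directory / "gene_annotation.tsv")
    metadata = ocio.read_metadata(directory / "metadata.tsv")
    gene_sets = ocio.read_gmt(directory / "gene_sets.gmt")
    serum = ocio.read_serum(directory / "serum.csv")
    npx = ocio.read_npx(directory / "npx.csv")
    truth_raw = ocio.read_json(directory / "truth.json")
    cfg_raw = dict(truth_raw["config"])
    cfg_raw["lib_size_range"] = tuple(cfg_raw["lib_size_range"])
    config = CohortConfig(**cfg_raw)
    truth = SyntheticTruth(
        latent_activity=pd.Series(truth_raw["latent_activity"]),
        true_de_genes=pd.Series(truth_raw["true_de_genes"], dtype=float),
        program_memberships=truth_raw["program_memberships"],
        marker_loadings=truth_raw["marker_loadings"],
    )
    return SyntheticStudy(config, counts, annotation, metadata, gene_sets,
                          serum, npx, truth)


# ---------------------------------------------------------------------------
# Paired qPCR simulation (osteoblast-enriched vs osteoclast cultures)
# ---------------------------------------------------------------------------

def simulate_qpcr(
    target_genes: list[str],
    oc_enriched_genes: list[str],
    n_participants: int = 9,
    enrichment_delta_ct: float = 3.0,
    noise_sd: float = 0.3,
    input_shift_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a paired Ct table for targets plus the housekeeping panel.

    Every participant contributes one osteoblast-enriched (``Ob``) and one
    osteoclast (``Oc``) sample.  Genes in *oc_enriched_genes* amplify
    *enrichment_delta_ct* cycles earlier in the Oc sample (higher
    expression); a per-sample input-RNA shift (SD *input_shift_sd* cycles)
    affects every gene in a sample equally and must be removed by
    housekeeping normalization.
    """
    rng = np.random.default_rng(seed)
    oc_enriched = set(oc_enriched_genes)
    participants = [f"P{i}" for i in range(1, n_participants + 1)]
    base_ct = {g: rng.uniform(22.0, 30.0) for g in
               list(target_genes) + list(HOUSEKEEPING_PANEL)}
    rows = []
    for participant in participants:
        for cell_type in ("Ob", "Oc"):
            shift = rng.normal(0.0, input_shift_sd)
            for gene in list(target_genes) + list(HOUSEKEEPING_PANEL):
                ct = base_ct[gene] + shift + rng.normal(0.0, noise_sd)
                if gene in oc_enriched and cell_type == "Oc":
                    ct -= enrichment_delta_ct
                rows.append((gene, participant, cell_type, float(np.clip(ct, 5.0, 40.0))))
    return pd.DataFrame(rows, columns=["gene", "participant", "cell_type", "ct"])


# ---------------------------------------------------------------------------
# Deterministic triage fixture
# ---------------------------------------------------------------------------

def triage_fixture() -> dict:
    """Build a synthetic fixture with the staged secreted-factor structure.

    Deterministically constructs the inputs of the secreted-factor triage
    with a known composition: 55 treatment-suppressed
    secreted genes (and 51 upregulated ones) in the centrifuged-bone DE
    table; of the 55, 17 also suppressed in the osteocyte-enriched fraction
    and 3 below the osteocyte detection limit; 10 genes enriched in
    osteoclast vs osteoblast cultures by paired qPCR, exactly 5 of which lie
    outside the osteocyte-suppressed subset.  Running the triage on this
    fixture must therefore yield 38 surface-restricted genes and the 5
    final candidates.
    """
    final_five = ["LIF", "CREG2", "CST3", "CCBE1", "DPP4"]
    suppressed = final_five + [f"SUP{i:02d}" for i in range(1, 51)]      # 55
    upregulated = [f"UPR{i:02d}" for i in range(1, 52)]                  # 51
    neutral_secreted = [f"NEU{i:02d}" for i in range(1, 21)]             # 20
    non_secreted = [f"OTH{i:02d}" for i in range(1, 31)]                 # 30

    # Osteocyte behaviour of the 55 suppressed genes: the last 17 detected
    # ones are also suppressed in osteocyte-enriched bone; 3 are below its
    # detection limit.
    osteocyte_undetected = suppressed[5:8]                               # 3
    detected = [g for g in suppressed + upregulated + neutral_secreted
                + non_secreted if g not in osteocyte_undetected]
    osteocyte_suppressed = [g for g in suppressed if g in detected][-17:]

    # Osteoclast-enriched in culture: the 5 candidates (outside the
    # osteocyte-suppressed subset) plus 5 that are osteocyte-suppressed and
    # therefore drop out of the final intersection.
    oc_enriched = final_five + osteocyte_suppressed[:5]                  # 10

    def de_table(gene_list, down, up):
        down, up = set(down), set(up)
        rows = []
        for i, g in enumerate(gene_list):
            if g in down:
                rows.append((g, -1.5 - 0.01 * i, 1e-4))
            elif g in up:
                rows.append((g, 1.2 + 0.01 * i, 1e-4))
            else:
                rows.append((g, 0.05 * ((i % 3) - 1), 0.6))
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value"])
        df["fdr"] = df["p_value"]
        df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
        df["mean_expression"] = 8.0
        return df.set_index("gene_id")

    all_genes = suppressed + upregulated + neutral_secreted + non_secreted
    de_centrifuged = de_table(all_genes, suppressed, upregulated)
    de_osteocyte = de_table(detected, osteocyte_suppressed, [])

    # Deterministic paired qPCR: osteoclast-enriched genes amplify 3 cycles
    # earlier in every Oc sample; all other targets alternate the sign of a
    # small Oc-Ob offset across participants, so they can never reach
    # signed-rank significance.  A per-sample input-RNA shift exercises the
    # housekeeping normalization.
    oc_set = set(oc_enriched)
    qpcr_rows = []
    for p_idx in range(9):
        participant = f"P{p_idx + 1}"
        for ct_idx, cell_type in enumerate(("Ob", "Oc")):
            input_shift = 0.4 * p_idx - 1.5 + 0.7 * ct_idx
            for g_idx, gene in enumerate(suppressed + list(HOUSEKEEPING_PANEL)):
                ct = 22.0 + (g_idx % 8) + input_shift
                if cell_type == "Oc":
                    if gene in oc_set:
                        ct -= 3.0
                    elif gene not in HOUSEKEEPING_PANEL:
                        ct += 0.2 * (-1) ** (p_idx + g_idx)
                qpcr_rows.append((gene, participant, cell_type, ct))
    qpcr = pd.DataFrame(qpcr_rows,
                        columns=["gene", "participant", "cell_type", "ct"])
    secreted = GeneSet(
        "secreted",
        tuple(suppressed + upregulated + neutral_secreted),
        "annotated secreted genes",
    )
    return {
        "de_centrifuged": de_centrifuged,
        "de_osteocyte": de_osteocyte,
        "detected_osteocyte": detected,
        "secreted": secreted,
        "qpcr": qpcr,
        "expected_final": final_five,
    }
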