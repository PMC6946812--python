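# osteocoupling

Analysis toolkit for studying **osteoclast–osteoblast coupling** — the
physiological linkage by which bone resorption drives subsequent bone
formation — in two-arm anti-resorptive trials with bone-biopsy RNA-seq.
Treating one arm with an anti-RANKL antibody (denosumab) ablates
osteoclasts and serves as a biological probe: genes and secreted factors
that fall together with the osteoclast program are candidate carriers of
the coupling signal.

The package is aimed at computational biologists analysing bulk RNA-seq of
bone biopsies alongside serum bone-turnover markers (CTX, TRAP5b, P1NP,
OCN), paired qPCR of cell fractions, and Olink NPX proteomics.

## What it computes

**Rank-mean gene-set coupling.** For each subject, all `G` detected genes
are ranked by offset-corrected log2 expression from high to low (rank 1 =
highest, average ties). A gene set `S` gets a per-subject profile

```
m_i(S) = (1/|S|) Σ_{g∈S} rank_i(g),       m_i ∈ [1, G]
```

and the coupling between the osteoclast and osteoblast marker programs is
the Spearman correlation ρ of their profiles across subjects. Significance
comes from a randomization test against disjoint, size-matched random gene
sets (5000 draws by default), with a one-sided add-one p-value
`p = (1 + #{ρ_null ≥ ρ_obs}) / (n_perm + 1)`. Because rank 1 means highest
expression, a *low* rank mean means *high* program expression.

Supporting machinery, each independently tested against small-instance
oracles:

* **Normalization** (`cqn_normalize`): log2 CPM minus a per-sample additive
  natural-cubic-spline correction for GC content and log10 gene length
  ("CQN values"), centered so per-sample mean offsets are exactly zero.
* **Differential expression** (`run_de`): NB GLM with log-link, technical
  offsets, median-count filtering (within-group median ≥ 10 in at least
  one group), method-of-moments dispersions shrunk to a trimmed mean,
  likelihood-ratio tests (χ², 1 df) and Benjamini–Hochberg FDR. An exact
  conditional NB test (`nb_exact_test`) is kept as a verification oracle
  for the equal-library case.
* **Secreted-factor triage** (`run_triage`): suppressed ∩ secreted →
  minus osteocyte-regulated → ∩ osteoclast-enriched by paired qPCR
  (geNorm reference-gene selection, exact Wilcoxon signed-rank test).
* **Biomarker endpoints**: percent change from baseline with Mann–Whitney,
  Kruskal–Wallis on linear-scale NPX, Spearman correlation tables.
* **Synthetic cohorts** (`simulate_cohort`): NB counts driven by a latent
  per-subject remodeling activity shared between the osteoclast and
  osteoblast programs, with treatment suppression, GC trends, serum
  markers and NPX proteins tied to the same latent activity — plus ground
  truth for calibration and recovery tests.

## Worked example

```python
from osteocoupling import CohortConfig, simulate_cohort
from osteocoupling.normalization import cqn_normalize
from osteocoupling.coupling import within_subject_ranks, randomization_test

study = simulate_cohort(CohortConfig(seed=1))        # 15 + 15 subjects, 2000 genes
norm = cqn_normalize(study.counts,
                     study.gene_annotation["gc_fraction"],
                     study.gene_annotation["length_bp"])
ranks = within_subject_ranks(norm.values)
placebo = study.metadata.index[study.metadata["group"] == "placebo"].tolist()
result = randomization_test(ranks,
                            study.gene_sets["oc_program"],
                            study.gene_sets["ob_program"],
                            subjects=placebo, n_perm=5000, seed=2)
print(f"rho = {result.rho_observed:.2f}, "
      f"permutation p = {result.p_permutation:.4f}, "
      f"asymptotic p = {result.p_asymptotic:.4f}")
```

```
rho = 0.72, permutation p = 0.0016, asymptotic p = 0.0024
```

The osteoclast and osteoblast rank-mean profiles of the untreated arm are
strongly coupled (ρ ≈ 0.7): subjects with high osteoclast-program
expression also show high osteoblast-program expression. Only ~0.2% of
random gene-set pairs reach that correlation, so the coupling is specific
to the programs, not an artifact of ranking.

The same pipeline is available from the shell:

```bash
osteocoupling all --seed 7 --out results/
```

which simulates a cohort, then runs normalization, differential
expression, coupling, triage and biomarker endpoints, writing result
tables and a JSON run manifest.

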