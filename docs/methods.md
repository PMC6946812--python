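# Methods

This note records the statistical models, parameter choices and numerical
conventions behind `osteocoupling`, and what the synthetic-data tests do
and do not establish about real data.

## The coupling statistic

Within each subject, all detected genes are ranked by normalized log2
expression from high to low (rank 1 = highest; ties get average ranks, so
each subject's rank sum is G(G+1)/2). A gene set's profile is the
per-subject mean of its members' ranks; the coupling of two sets is the
Spearman correlation of their profiles across subjects. Working on
within-subject ranks makes the statistic invariant to any strictly
monotone per-subject transform of the expression values — in particular to
residual differences between normalization schemes — which is verified by
a metamorphic test.

Significance is assessed by a randomization test: each of `n_perm`
replicates (default 5000) draws two **disjoint, size-matched** random gene
sets from the detected-gene universe and records their profile
correlation. Disjointness mirrors the disjoint osteoclast/osteoblast
marker panels; size-matching preserves the variance of the rank-mean
statistic. The p-value is one-sided with add-one correction,
`p = (1 + #{ρ_null ≥ ρ_obs}) / (n_perm + 1)`, since coupling is a
directional hypothesis; the asymptotic Spearman p for the observed ρ is
reported alongside. Set members absent from the detected universe are
dropped (with a logged count), not imputed. By default the statistic is
computed over the placebo arm's subjects, where coupling reflects
unperturbed physiology; a flag includes all subjects.

Sign convention: rank 1 = highest expression, so a *low* rank mean means
*high* program expression. Wherever profiles meet external measures
(serum markers, NPX proteins), correlations against raw rank-mean
profiles flip sign relative to expression; `protein_geneset_correlation`
negates profiles first so its reported ρ refers to expression.

## Normalization ("CQN values")

Expression is log2 CPM with the usual 0.5/1 pseudo-counts, minus a
per-gene×sample technical offset. The offset is fitted per sample by least
squares as an additive model of log2 CPM on natural cubic splines of GC
fraction and log10 length (5 knots each, at the 5/25/50/75/95 % quantiles
of the fitted genes), evaluated on all genes and centered to zero mean
within each sample — so normalization never shifts a sample's overall
level, and genes sharing GC and length keep their within-sample order.
This is a deliberate simplification of full conditional-quantile
regression: it captures the GC/length/library-size adjustment while
remaining small and exactly testable, and the downstream coupling
statistics consume only within-sample ranks, which are insensitive to the
remaining difference. Offsets are fitted on the genes that pass the
low-count filter and applied to all genes. Constant covariates are dropped
with a warning; fewer than 20 fitted genes is an error.

## Differential expression

Counts for gene g, sample i are modelled NB with
`log mu_gi = beta_g(group_i) + o_gi` and variance `mu + phi_g mu^2`, where
the natural-log offset combines library size and the technical offset.
Genes are screened by the median rule: kept iff the within-group median
count is ≥ 10 in at least one group.

*Dispersions.* Raw per-gene estimates pool within-group method-of-moments
values on offset-adjusted counts, truncated at zero; the common value is
the 20 %-per-tail trimmed mean; shrinkage is
`phi = (n·phi_hat + w·phi0) / (n + w)` with prior weight `w = 10`
(moderate shrinkage at n ≈ 15/group; exposed as a parameter).

*Testing.* With a two-level factor, the alternative decomposes into
independent per-group intercept fits, so all fits are single-parameter
Fisher-scoring problems vectorized across genes (strictly concave
likelihood; gradient tolerance 1e-8, 100 iterations, steps clipped to ±5
and intercepts to ±50; non-convergence yields p = NaN with a logged
diagnostic, never a silent value). The likelihood is evaluated as
`y log mu − (y + r) log1p(mu/r)` — the omitted `(y + r) log r` term is
mean-independent and cancels in ratios, and `log1p` keeps the Poisson
limit (phi → 0, r → ∞) exact to machine precision. Twice the
log-likelihood ratio is referred to χ²(1). Reported fold changes are
treated − placebo in log2 units from offset-adjusted group means with a
0.125 prior count, which keeps them finite and exactly antisymmetric
under label swap. FDR is Benjamini–Hochberg step-up, with NaN p-values
propagated.

*Exact oracle.* For equal library sizes the group-A sum conditional on the
total follows the distribution ∝ f_A(s)·f_B(t−s) with NB group sums of
size n_k/phi (binomial in the Poisson limit); the two-sided p is the total
probability of outcomes no more likely than the observed split. The
enumeration applies while each group sum is ≤ 10⁴. In the cross-check
between this exact test and the LRT, the simulated counts are placed well
inside the enumeration domain (mean ≈ 300 per sample, 15 + 15 samples):
the probability-mass convention carries an irreducible discrete
conservatism of the order of the conditional pmf at the observed total
(~0.01 at this scale, but 0.05–0.2 at very small totals), so comparing the
two p distributions is only informative where that granularity is small.

## Secreted-factor triage

Stage 1 intersects the suppressed DE genes (p < α, log2FC < 0; α = 0.05)
with a user-supplied secreted-gene annotation (a GMT list replaces any
proprietary pathway database). Stage 2 removes genes also significantly
decreased in the osteocyte-enriched fraction (operationalized as p < 0.05
with negative fold change); genes below the osteocyte detection limit stay
in the surface-restricted set, since absent expression cannot establish
osteocyte regulation. Stage 3 tests paired osteoclast-vs-osteoblast qPCR:
Ct values convert to relative quantities as `efficiency^(−Ct)` with
efficiency fixed at 2 (exposed as a parameter); normalization divides by
the geometric mean of the geNorm-selected reference genes; enrichment
requires a two-sided exact Wilcoxon p < α AND a positive median Oc − Ob
difference, with at least 5 complete pairs. Final candidates are the
surface-restricted ∩ osteoclast-enriched genes, with per-stage provenance
kept in the report and the stage set-algebra asserted on every run.

*geNorm.* Stability M_j is the mean over partners k of the SD (ddof = 1)
of per-sample log2 quantity ratios; the gene with the highest M is removed
and M recomputed until `n_keep` (default 3, from a nine-gene candidate
panel) remain. Ties in the maximal M remove the lexicographically last
gene ID — an arbitrary but documented and deterministic rule. M is
invariant to rescaling any sample, so input-RNA differences cancel.

*Exact Wilcoxon.* Zero differences are dropped; for n ≤ 25 the null
distribution of W+ with average-tied ranks is built by dynamic programming
on doubled ranks (equivalent to enumerating all 2ⁿ sign patterns) and the
two-sided p is `min(1, 2·min(P(W ≤ w), P(W ≥ w)))`; beyond n = 25 a
tie-corrected normal approximation with continuity correction is used.

## Biomarker endpoints

Percent change is computed per subject (100·(followup − baseline)/baseline,
zero-baseline subjects excluded with a warning) and compared between arms
by two-sided Mann–Whitney — exact by full enumeration of group assignments
(valid under ties) up to a combined n of 20, tie-corrected normal
approximation with continuity correction beyond. NPX values (log2 scale)
are converted to linear scale (2^NPX) before Kruskal–Wallis, matching how
the assay's group comparisons are reported; the monotone conversion leaves
the rank-based p unchanged, which a regression test pins down. Per-protein
p-values are reported unadjusted (the significance count uses p < 0.05)
with a BH column alongside for users. Constant proteins are flagged with
p = 1.

## Synthetic cohort generator

The generator emulates the study design: two arms (default 15 + 15
subjects with biopsy RNA-seq; 24 + 24 for serum endpoints), a latent
per-subject remodeling activity `a_i ~ N(0,1)`, and NB counts with

    mu_gi = L_i · q_g · 2^(b_g a_i − x_i δ_g + f(gc_g)),   var = mu + φ mu².

Defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | detected genes after filtering (working scale; tests that need finer spline resolution raise it) |
| `coupling_loading` b | 0.50 | log2 units per latent-activity unit on program genes; calibrated by simulation so the population coupling ρ ≈ 0.75 at 15 subjects, 2000 genes, 8-gene sets, φ = 0.2 — the coupling-strength regime the analysis targets |
| `suppression_log2fc` δ | 1.5 | treatment suppression of the osteoclast program |
| `coupled_ob_fraction` | 0.5 | fraction of δ propagated to the osteoblast program |
| `dispersion` φ | 0.2 | NB dispersion, var = mu + φ mu² |
| `lib_size_range` | 1–3 M | log-uniform library sizes; realistic spread without heavy tails |
| `gc_effect` | 4.0 | coefficient of the quadratic GC trend f(gc) = gc_effect·gc² |
| `marker_noise_sd` | 0.3 | non-shared noise on serum markers and NPX proteins |

Baseline abundances q_g are log-normal (σ = 1.5 on the log2 scale) so the
within-subject ranking is non-degenerate; GC fractions are Beta(20, 20)
and lengths log-uniform over 300 bp–30 kb, plausible annotation ranges.
Serum markers are affine in a_i (resorption markers load strongest) with
3-month values generated from baseline via group-specific multipliers —
strong suppression of CTX/TRAP5b and a coupling-mediated decline of
P1NP/OCN under treatment; these effect sizes are generator parameters
chosen to be physiologically plausible, not estimates. NPX proteins follow
the same affine structure on the log2 scale with DPP4-, CST3- and LIF-like
entries tied to the latent activity plus unrelated null proteins. Each
component (gene/sample structure, counts, serum, NPX) uses its own RNG
stream spawned from the master seed, so adding one component never
perturbs another's draws and identical configurations are bit-identical.

What the generator does **not** emulate: batch effects, sample quality
gradients, more than two time points, correlated gene-gene structure
beyond the single latent factor, detection-limit censoring in qPCR, or
realistic marker–activity effect sizes (only the qualitative correlation
structure of the marker panel is targeted). Tests passing on this
generator therefore establish internal statistical correctness and
calibration under the assumed model, not robustness to those real-data
features.

The deterministic triage fixture constructs DE tables, an osteocyte
detection list and a paired qPCR table whose staged composition is fixed
(55 suppressed secreted genes, of which 17 osteocyte-suppressed and 3
below detection; 10 osteoclast-enriched, 5 outside the osteocyte subset),
so the full triage must reproduce 38 surface-restricted genes and 5 final
candidates by computation; it is synthetic data standing in for the cell-
fraction experiments.

## Problem sizes in the checks

The acceptance checks run 200 uncoupled cohorts (G = 2000, 199
permutations) for null calibration, 100 coupled cohorts for the
power/strength check, 5 + 20 cohorts for DE recovery and type-I error,
and 200 genes per dispersion for the LRT/exact cross-check — sizes chosen
so every Monte-Carlo bracket is decisively inside its band while the whole
suite stays interactive.

## Known limitations

* The spline mean-correction is not full conditional-quantile
  normalization; absolute normalized values can differ from that method
  even though rank-based downstream statistics do not.
* The NB LRT relies on χ²(1) asymptotics; at very small totals its p can
  deviate from the exact conditional test by the discreteness noted above.
* Method-of-moments dispersions are mildly downward-biased; the shrinkage
  target compensates in calibration but per-gene values are not
  empirical-Bayes posterior means.
* Two-level designs only; no covariates, no multi-factor models.
* qPCR efficiency is assumed exactly 2 for all assays unless overridden.
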