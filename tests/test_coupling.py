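import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from osteocoupling import CohortConfig, simulate_cohort
from osteocoupling.io import GeneSet
from osteocoupling.coupling import (
    coupling_correlation, correlate_with_measures, gene_set_rank_mean,
    heatmap_ranks, randomization_test, within_subject_ranks,
)
from osteocoupling.normalization import log2_cpm

from conftest import make_counts


def frame(values, genes=None, samples=None):
    values = np.asarray(values, float)
    return pd.DataFrame(
        values,
        index=genes or [f"g{i}" for i in range(values.shape[0])],
        columns=samples or [f"s{i}" for i in range(values.shape[1])],
    )


class TestWithinSubjectRanks:
    def test_descending_definition(self):
        ranks = within_subject_ranks(frame([[5.0], [2.0], [9.0]]))
        assert ranks["s0"].tolist() == [2.0, 3.0, 1.0]

    def test_tie_averaging(self):
        ranks = within_subject_ranks(frame([[4.0], [4.0], [1.0]]))
        assert ranks["s0"].tolist() == [1.5, 1.5, 3.0]

    def test_all_equal_gives_midrank(self):
        ranks = within_subject_ranks(frame(np.ones((5, 1))))
        assert ranks["s0"].tolist() == [3.0] * 5

    def test_nan_is_error_with_cell_name(self):
        values = frame([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="g1"):
            within_subject_ranks(values)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(2, 40), st.integers(1, 6), st.integers(0, 10_000))
    def test_rank_sum_conservation(self, n_genes, n_samples, seed):
        rng = np.random.default_rng(seed)
        # duplicated values exercise tie handling
        values = frame(rng.integers(0, 5, size=(n_genes, n_samples)))
        sums = within_subject_ranks(values).sum(axis=0)
        assert np.allclose(sums, n_genes * (n_genes + 1) / 2)


class TestHeatmapRanks:
    def test_across_sample_definition(self):
        ranks = heatmap_ranks(frame([[1.0, 3.0, 2.0]]))
        assert ranks.iloc[0].tolist() == [3.0, 1.0, 2.0]

    def test_constant_gene_all_tied(self):
        ranks = heatmap_ranks(frame([[7.0, 7.0, 7.0]]))
        assert ranks.iloc[0].tolist() == [2.0, 2.0, 2.0]

    def test_subset_reranks_within_subset(self):
        values = frame([[1.0, 3.0, 2.0]])
        sub = heatmap_ranks(values, samples=["s1", "s2"])
        assert sub.iloc[0].tolist() == [1.0, 2.0]


class TestRankMean:
    def test_whole_universe_gives_midrank(self):
        values = frame(np.random.default_rng(0).normal(size=(7, 4)))
        ranks = within_subject_ranks(values)
        gs = GeneSet("all", tuple(values.index))
        profile = gene_set_rank_mean(ranks, gs)
        assert np.allclose(profile, (7 + 1) / 2)

    def test_singleton_set(self):
        ranks = within_subject_ranks(frame([[5.0], [2.0], [9.0]]))
        profile = gene_set_rank_mean(ranks, GeneSet("top", ("g2",)))
        assert profile.tolist() == [1.0]

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(3)
        values = frame(rng.normal(size=(5, 3)))
        ranks = within_subject_ranks(values)
        gs = GeneSet("pair", ("g1", "g3"))
        profile = gene_set_rank_mean(ranks, gs)
        expected = (ranks.loc["g1"] + ranks.loc["g3"]) / 2
        assert np.allclose(profile, expected)

    def test_empty_intersection_is_error(self):
        ranks = within_subject_ranks(frame([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="no members"):
            gene_set_rank_mean(ranks, GeneSet("x", ("absent",)))


class TestCouplingCorrelation:
    def test_identical_profiles(self):
        p = pd.Series([3.0, 1.0, 2.0, 5.0], index=list("abcd"))
        assert coupling_correlation(p, p) == pytest.approx(1.0)

    def test_reversed_profiles(self):
        p = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        q = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        assert coupling_correlation(p, q) == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # rho = 1 - 6 * sum(d^2) / (n(n^2-1)), sum(d^2) = 4
        a = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        b = pd.Series([1.0, 3, 2, 5, 4], index=list("abcde"))
        assert coupling_correlation(a, b) == pytest.approx(0.8)

    def test_constant_profile_is_error(self):
        a = pd.Series([1.0, 1, 1], index=list("abc"))
        b = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            coupling_correlation(a, b)


class TestRandomizationTest:
    def _perfect_coupling_values(self, n_genes=100, n_subjects=15, seed=0):
        # Background genes are iid noise; the two program genes sweep the
        # dynamic range in lock-step (one a hair above the other), so their
        # within-subject ranks are consecutive in every subject and their
        # rank-mean profiles are perfectly concordant (rho = 1).
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1000, size=(n_genes, n_subjects))
        sweep = 1000 * (np.arange(n_subjects) + 0.5) / n_subjects
        values[0] = sweep
        values[1] = sweep + 1e-6
        return frame(values)

    def test_counting_formula_when_observed_exceeds_null(self):
        ranks = within_subject_ranks(self._perfect_coupling_values())
        res = randomization_test(ranks, GeneSet("a", ("g0",)),
                                 GeneSet("b", ("g1",)), n_perm=499, seed=8)
        assert res.rho_observed == pytest.approx(1.0)
        assert res.rho_observed > max(res.null_rhos)
        assert res.p_permutation == pytest.approx(1 / 500)

    def test_null_matches_exhaustive_enumeration_on_tiny_universe(self):
        rng = np.random.default_rng(5)
        values = frame(rng.normal(size=(6, 8)))
        ranks = within_subject_ranks(values)
        res = randomization_test(ranks, GeneSet("a", ("g0",)),
                                 GeneSet("b", ("g1",)), n_perm=10_000, seed=3)
        exhaustive = []
        arr = ranks.to_numpy()
        for i, j in itertools.permutations(range(6), 2):
            exhaustive.append(stats.spearmanr(arr[i], arr[j]).statistic)
        # round so identical atoms align exactly across the two routes
        ks = stats.ks_2samp(np.round(res.null_rhos, 9),
                            np.round(exhaustive, 9)).statistic
        assert ks < 0.05

    def test_p_invariant_to_monotone_per_subject_transform(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, size=(100, 15))
        trend = np.linspace(0, 6, 15)
        values[:10] += trend
        vf = frame(values)
        transformed = vf.copy()
        for k, col in enumerate(vf.columns):
            x = vf[col]
            transformed[col] = np.exp(x / (k + 1)) + k   # strictly monotone
        a = GeneSet("a", tuple(f"g{i}" for i in range(5)))
        b = GeneSet("b", tuple(f"g{i}" for i in range(5, 10)))
        r1 = randomization_test(within_subject_ranks(vf), a, b,
                                n_perm=199, seed=11)
        r2 = randomization_test(within_subject_ranks(transformed), a, b,
                                n_perm=199, seed=11)
        assert r1.p_permutation == r2.p_permutation
        assert r1.rho_observed == pytest.approx(r2.rho_observed)

    def test_universe_too_small_is_error(self):
        ranks = within_subject_ranks(frame(np.random.default_rng(0)
                                           .normal(size=(3, 5))))
        with pytest.raises(ValueError, match="disjoint"):
            randomization_test(ranks, GeneSet("a", ("g0", "g1")),
                               GeneSet("b", ("g2", "g1")), n_perm=10, seed=0)


class TestMeasureCorrelations:
    def test_self_and_negated_measures(self):
        profile = pd.Series([4.0, 2.0, 8.0, 6.0],
                            index=["s1", "s2", "s3", "s4"], name="oc")
        measures = pd.DataFrame({"same": profile, "neg": -profile})
        out = correlate_with_measures(profile, measures)
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["neg", "rho"] == pytest.approx(-1.0)

    def test_insufficient_overlap_skipped(self, caplog):
        profile = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        measures = pd.DataFrame({"m": [1.0, 2.0]}, index=["a", "b"])
        with caplog.at_level("WARNING", logger="osteocoupling"):
            out = correlate_with_measures(profile, measures)
        assert out.empty

    def test_resorption_marker_negatively_tracks_oc_rank_mean(self):
        # CTX loads positively on the latent activity that raises OC-program
        # expression; high expression = low rank, so rho must be negative.
        rhos = []
        for seed in range(30):
            st_ = simulate_cohort(CohortConfig(n_genes=300, seed=seed))
            ranks = within_subject_ranks(log2_cpm(st_.counts))
            placebo = st_.metadata.index[
                st_.metadata["group"] == "placebo"].tolist()
            profile = gene_set_rank_mean(ranks, st_.gene_sets["oc_program"],
                                         placebo)
            base = st_.serum[st_.serum["timepoint"] == "baseline"].pivot_table(
                index="subject_id", columns="marker", values="value")
            out = correlate_with_measures(profile, base[["CTX"]])
            rhos.append(out.loc["CTX", "rho"])
        assert np.mean(rhos) < -0.3
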