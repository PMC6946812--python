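import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from osteocoupling import CohortConfig, simulate_cohort, simulate_qpcr, triage_fixture
from osteocoupling.io import GeneSet
from osteocoupling.diffexp import run_de
from osteocoupling.triage import (
    classify_secreted_de, genorm_m_values, genorm_select, osteocyte_overlap,
    qpcr_normalize, qpcr_quantities, run_triage, wilcoxon_paired_oc_ob,
    wilcoxon_signed_rank,
)


def de_row(gene, lfc, p):
    return {"gene_id": gene, "log2fc": lfc, "p_value": p}


class TestClassify:
    def setup_method(self):
        self.de = pd.DataFrame([
            de_row("A", -1.0, 0.01),
            de_row("B", 1.2, 0.001),
            de_row("C", -0.5, 0.2),
            de_row("D", -2.0, 0.03),
        ]).set_index("gene_id")

    def test_rule_application(self):
        secreted = GeneSet("sec", ("A", "B", "C"))
        down, up = classify_secreted_de(self.de, secreted, 0.05)
        assert down == ["A"] and up == ["B"]

    def test_non_secreted_ignored(self):
        secreted = GeneSet("sec", ("B",))
        down, up = classify_secreted_de(self.de, secreted, 0.05)
        assert down == [] and up == ["B"]

    def test_empty_secreted_list(self):
        down, up = classify_secreted_de(self.de, GeneSet("sec", ("Z",)), 0.05)
        assert down == [] and up == []

    def test_alpha_monotonicity(self):
        secreted = GeneSet("sec", ("A", "C", "D"))
        wide, _ = classify_secreted_de(self.de, secreted, 0.25)
        narrow, _ = classify_secreted_de(self.de, secreted, 0.02)
        assert set(narrow) <= set(wide)


class TestOsteocyteOverlap:
    def test_reference_arithmetic(self):
        # 55 suppressed, 17 osteocyte-suppressed, 3 undetected -> 38 surface
        fx = triage_fixture()
        down, _ = classify_secreted_de(fx["de_centrifuged"], fx["secreted"])
        part = osteocyte_overlap(down, fx["de_osteocyte"],
                                 fx["detected_osteocyte"])
        assert len(down) == 55
        assert len(part["osteocyte_suppressed"]) == 17
        assert len(part["undetected"]) == 3
        assert len(part["surface_restricted"]) == 38
        assert set(part["undetected"]) <= set(part["surface_restricted"])

    def test_gene_suppressed_in_both_excluded(self):
        de_o = pd.DataFrame([de_row("A", -1.0, 0.001)]).set_index("gene_id")
        part = osteocyte_overlap(["A", "B"], de_o, ["A", "B"])
        assert part["surface_restricted"] == ["B"]

    def test_no_osteocyte_rows_means_all_undetected(self):
        de_o = pd.DataFrame(columns=["log2fc", "p_value"])
        part = osteocyte_overlap(["A", "B"], de_o, [])
        assert part["undetected"] == ["A", "B"]
        assert part["surface_restricted"] == ["A", "B"]


class TestGeNorm:
    def _panel(self, rng, n_genes=5, n_samples=6):
        q = rng.lognormal(0, 0.3, size=(n_genes, n_samples))
        return pd.DataFrame(q, index=[f"h{i}" for i in range(n_genes)],
                            columns=[f"p{i}" for i in range(n_samples)])

    def test_m_matches_brute_force_double_loop(self, rng):
        for _ in range(10):
            panel = self._panel(rng, n_genes=int(rng.integers(4, 10)))
            m = genorm_m_values(panel)
            logq = np.log2(panel.to_numpy())
            for j, gene in enumerate(panel.index):
                vs = [np.std(logq[j] - logq[k], ddof=1)
                      for k in range(len(panel)) if k != j]
                assert m[gene] == pytest.approx(np.mean(vs), abs=1e-12)

    def test_proportional_pair_survives(self, rng):
        panel = self._panel(rng, n_genes=4)
        panel.loc["h1"] = panel.loc["h0"] * 3.0    # perfectly proportional
        res = genorm_select(panel, n_keep=2)
        assert set(res.selected) == {"h0", "h1"}

    def test_nine_gene_panel_keeps_three(self, rng):
        panel = self._panel(rng, n_genes=9)
        res = genorm_select(panel, n_keep=3)
        assert len(res.selected) == 3
        assert len(res.elimination_order) == 6

    def test_invariant_to_per_sample_rescaling(self, rng):
        panel = self._panel(rng)
        scaled = panel * rng.uniform(0.5, 2.0, size=panel.shape[1])
        pd.testing.assert_series_equal(genorm_m_values(panel),
                                       genorm_m_values(scaled), atol=1e-12)

    def test_non_positive_quantity_is_error(self, rng):
        panel = self._panel(rng)
        panel.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            genorm_select(panel, n_keep=2)

    def test_tie_break_removes_lexicographically_last(self):
        # two independent noisy genes plus a proportional pair: the noisy
        # genes tie in M by symmetry of the construction
        q = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0],
             [2.0, 1.0, 2.0, 1.0],
             [1.0, 1.0, 1.0, 1.0],
             [2.0, 2.0, 2.0, 2.0]],
            index=["a", "b", "c", "d"], columns=list("wxyz"))
        res = genorm_select(q, n_keep=3)
        assert res.elimination_order[0] == "b"   # tie with "a" -> last wins


class TestQpcrNormalize:
    def test_division_example(self, rng):
        panel = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [2.0, 2.0]}, index=["h0", "h1"])
        res = genorm_select(
            pd.concat([panel, pd.DataFrame({"s1": [1.0], "s2": [4.0]},
                                           index=["h2"])]),
            n_keep=2)
        raw = pd.DataFrame({"s1": [4.0], "s2": [4.0]}, index=["T"])
        out = qpcr_normalize(raw, res)
        assert out.loc["T"].tolist() == [4.0, 2.0]

    def test_per_sample_doubling_absorbed(self, rng):
        qpcr = simulate_qpcr(["T1"], [], n_participants=4, seed=2)
        q = qpcr_quantities(qpcr)
        res = genorm_select(q.drop(index="T1"), n_keep=3)
        norm1 = qpcr_normalize(q, res)
        q2 = q.copy()
        q2.iloc[:, 0] *= 2.0
        res2 = genorm_select(q2.drop(index="T1"), n_keep=3)
        norm2 = qpcr_normalize(q2, res2)
        pd.testing.assert_frame_equal(norm1, norm2, atol=1e-12)


def brute_force_wilcoxon(d):
    """Enumerate all 2^n sign patterns of W+ (average-tied ranks)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_all_positive_nine_pairs(self):
        p, n = wilcoxon_signed_rank(np.arange(1.0, 10.0))
        assert n == 9
        assert p == pytest.approx(2 / 2 ** 9)

    def test_sign_symmetry(self, rng):
        d = rng.normal(0, 1, 8)
        p1, _ = wilcoxon_signed_rank(d)
        p2, _ = wilcoxon_signed_rank(-d)
        assert p1 == pytest.approx(p2)

    def test_zero_differences_dropped(self, rng):
        d = np.array([0.0, 1.2, -0.4, 0.8, 2.0, -1.5])
        p, n = wilcoxon_signed_rank(d)
        assert n == 5
        assert p == pytest.approx(brute_force_wilcoxon(d))

    def test_all_zero_differences(self, caplog):
        with caplog.at_level("WARNING", logger="osteocoupling"):
            p, n = wilcoxon_signed_rank(np.zeros(4))
        assert p == 1.0 and n == 0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=12))
    def test_exact_matches_enumeration_up_to_n12(self, diffs):
        d = np.asarray(diffs, float)
        if (d == 0).all():
            return
        p, _ = wilcoxon_signed_rank(d)
        assert p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)


class TestRunTriage:
    def test_reference_flow_counts(self):
        fx = triage_fixture()
        report = run_triage(fx["de_centrifuged"], fx["de_osteocyte"],
                            fx["detected_osteocyte"], fx["secreted"],
                            fx["qpcr"])
        assert report.counts == {
            "suppressed_secreted": 55, "upregulated_secreted": 51,
            "osteocyte_suppressed": 17, "osteocyte_undetected": 3,
            "surface_restricted": 38, "oc_enriched": 10,
            "final_candidates": 5,
        }
        assert sorted(report.final_candidates) == \
            ["CCBE1", "CREG2", "CST3", "DPP4", "LIF"]

    def test_no_significant_qpcr_genes_gives_empty_candidates(self):
        fx = triage_fixture()
        flat = simulate_qpcr(list(fx["de_centrifuged"].index[:55]), [],
                             n_participants=9, seed=1)
        report = run_triage(fx["de_centrifuged"], fx["de_osteocyte"],
                            fx["detected_osteocyte"], fx["secreted"], flat)
        assert report.final_candidates == []

    def test_recovers_oc_program_secreted_genes_from_generator(self):
        # the three secreted OC-program genes should come out as candidates
        hits = 0
        for seed in range(8):
            study = simulate_cohort(CohortConfig(n_genes=1000, seed=seed))
            de = run_de(study.counts, study.gene_annotation, study.metadata)
            detected = de.index.tolist()
            secreted = study.gene_sets["secreted"]
            oc_secreted = [g for g in secreted.genes
                           if g in study.gene_sets["oc_program"]]
            qpcr = simulate_qpcr(
                [g for g in secreted.genes if g in de.index],
                oc_secreted, n_participants=9, seed=seed)
            de_ocy = pd.DataFrame({"log2fc": 0.0, "p_value": 1.0},
                                  index=de.index)
            report = run_triage(de, de_ocy, detected, secreted, qpcr)
            if set(oc_secreted) <= set(report.final_candidates):
                hits += 1
        assert hits >= 7
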