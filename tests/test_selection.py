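"""PCA selection scan: components, axis choice, statistics, BH, DAF."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from burdenscan.selection import (
    derived_allele_freqs,
    fdr_select,
    pca_panel,
    scan_selection,
    select_axis,
    snp_axis_pvalues,
)
from burdenscan.simulate import ReferencePanel, SimConfig, VariantRecord, \
    simulate_reference_panel


def brute_force_bh(p: np.ndarray, q: float) -> np.ndarray:
    """Independent step-up oracle: largest k with p_(k) <= k q / m, then
    flag everything at or below p_(k)."""
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k = i
    flags = np.zeros(m, dtype=bool)
    for idx in order[:k]:
        flags[idx] = True
    return flags


def _two_pop_panel(rng, n_per_pop=30, n_signal=40, n_noise=200, gap=0.9):
    freqs = np.concatenate(
        [np.full(n_signal, 0.05), rng.uniform(0.2, 0.8, n_noise)]
    )
    freqs_b = freqs.copy()
    freqs_b[:n_signal] += gap
    g_a = rng.binomial(2, freqs, size=(n_per_pop, n_signal + n_noise))
    g_b = rng.binomial(2, freqs_b, size=(n_per_pop, n_signal + n_noise))
    genotypes = np.vstack([g_a, g_b])
    pops = np.array(["EUR"] * n_per_pop + ["EAS"] * n_per_pop, dtype=object)
    return genotypes, pops


class TestPCA:
    def test_two_populations_separate_on_pc1_without_overlap(self):
        rng = np.random.default_rng(0)
        genotypes, pops = _two_pop_panel(rng)
        pca = pca_panel(genotypes, n_components=4)
        pc1 = pca.scores[:, 0]
        assert max(pc1[pops == "EUR"]) < min(pc1[pops == "EAS"]) or \
            max(pc1[pops == "EAS"]) < min(pc1[pops == "EUR"])

    def test_duplicate_samples_get_identical_scores(self):
        rng = np.random.default_rng(1)
        genotypes, _ = _two_pop_panel(rng)
        genotypes[5] = genotypes[3]
        pca = pca_panel(genotypes, n_components=3)
        assert pca.scores[5] == pytest.approx(pca.scores[3], abs=1e-10)

    def test_score_columns_are_orthogonal(self):
        rng = np.random.default_rng(2)
        genotypes, _ = _two_pop_panel(rng)
        pca = pca_panel(genotypes, n_components=5)
        gram = pca.scores.T @ pca.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(3)
        genotypes, _ = _two_pop_panel(rng, n_per_pop=10, n_signal=5, n_noise=20)
        with pytest.raises(ValueError, match="n_components"):
            pca_panel(genotypes, n_components=20)


class TestSelectAxis:
    def test_two_population_panel_returns_pc1(self):
        rng = np.random.default_rng(4)
        genotypes, pops = _two_pop_panel(rng)
        pca = pca_panel(genotypes, n_components=4)
        assert select_axis(pca.scores, pops, "EUR", "EAS") == 1

    def test_afr_structure_pushes_eur_eas_axis_to_pc2(self):
        cfg = SimConfig(n_panel_snps=3000, planted_selected_snps=20,
                        planted_afr_snps=60, daf_gap=0.8, seed=5)
        panel = simulate_reference_panel(cfg)
        pca = pca_panel(panel.genotypes)
        assert select_axis(pca.scores, panel.populations) == 2

    def test_tie_breaks_to_lowest_index(self):
        scores = np.array([[1.0, 1.0], [1.0, 1.0], [-1.0, -1.0], [-1.0, -1.0]])
        pops = np.array(["EUR", "EUR", "EAS", "EAS"], dtype=object)
        assert select_axis(scores, pops) == 1

    def test_missing_population_rejected(self):
        scores = np.zeros((4, 2))
        pops = np.array(["EUR"] * 4, dtype=object)
        with pytest.raises(ValueError, match="EAS"):
            select_axis(scores, pops)


class TestAxisStatistics:
    def test_snp_equal_to_axis_has_vanishing_p(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((50, 200))
        s = x[:, 0].copy()  # axis == first SNP
        stat, p, lam = snp_axis_pvalues(x, s)
        assert stat[0] == pytest.approx(50.0)
        assert p[0] < 1e-9

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            snp_axis_pvalues(np.zeros((5, 3)), np.zeros(5))

    def test_sample_permutation_leaves_stats_invariant(self):
        cfg = SimConfig(n_panel_snps=600, panel_size_afr=20, panel_size_eur=20,
                        panel_size_eas=20, planted_selected_snps=8, seed=7)
        panel = simulate_reference_panel(cfg)
        scan = scan_selection(panel, n_components=5)
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(panel.samples))
        permuted = ReferencePanel(
            [panel.samples[i] for i in perm],
            panel.populations[perm],
            panel.variants,
            panel.genotypes[perm],
            panel.truth,
        )
        scan_perm = scan_selection(permuted, n_components=5)
        assert scan_perm.table["stat"].to_numpy() == pytest.approx(
            scan.table["stat"].to_numpy(), rel=1e-8
        )

    def test_null_panel_calibration_smoke(self):
        panel = simulate_reference_panel(
            SimConfig(n_panel_snps=2000, panel_size_afr=60, panel_size_eur=60,
                      panel_size_eas=60, seed=9)
        )
        scan = scan_selection(panel)
        assert 0.8 <= scan.lambda_gc <= 1.2
        assert stats.kstest(scan.table["p_value"], "uniform").statistic < 0.05

    def test_recall_nondecreasing_in_daf_gap(self):
        def recall(gap, seed):
            cfg = SimConfig(n_panel_snps=1200, panel_size_afr=40,
                            panel_size_eur=40, panel_size_eas=40,
                            planted_selected_snps=15, daf_gap=gap, seed=seed)
            panel = simulate_reference_panel(cfg)
            scan = scan_selection(panel)
            truth = panel.truth["selected"].to_numpy()[
                scan.table["snp_index"].to_numpy()
            ]
            sig = scan.table["significant"].to_numpy()
            return (sig & truth).sum() / truth.sum()

        means = [
            np.mean([recall(gap, 200 + s) for s in range(6)])
            for gap in (0.3, 0.6, 0.9)
        ]
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9
        assert means[2] > 0.9


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        flags = fdr_select(np.array([0.001, 0.02, 0.9]), q=0.1)
        assert list(flags) == [True, True, False]

    def test_all_ones_select_nothing(self):
        assert not fdr_select(np.ones(10), q=0.1).any()

    def test_invalid_q_and_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_select(np.array([0.5]), q=1.5)
        with pytest.raises(ValueError):
            fdr_select(np.array([0.0, 0.5]), q=0.1)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(400):
            m = rng.integers(1, 60)
            p = rng.uniform(1e-6, 1.0, m)
            if rng.random() < 0.5:  # sprinkle strong signals
                p[: rng.integers(0, m) or 1] *= 1e-4
            q = rng.uniform(0.01, 0.5)
            assert np.array_equal(fdr_select(p, q), brute_force_bh(p, q))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, rng.integers(5, 200))
            flags = fdr_select(p, q=0.1)
            sm_flags = multipletests(p, alpha=0.1, method="fdr_bh")[0]
            assert np.array_equal(flags, sm_flags)

    @settings(max_examples=80, derandomize=True)
    @given(
        st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40),
        st.floats(0.01, 0.5),
    )
    def test_property_flags_form_a_pvalue_prefix(self, pvals, q):
        p = np.array(pvals)
        flags = fdr_select(p, q)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() if (~flags).any() else True
            assert np.array_equal(flags, brute_force_bh(p, q))


def _toy_panel():
    # 6 EUR + 6 EAS samples, 2 SNPs with known alt counts
    genotypes = np.array(
        [[2, 0], [2, 0], [2, 1], [1, 0], [2, 0], [1, 0],   # EUR
         [0, 2], [0, 2], [1, 2], [0, 1], [0, 2], [0, 2]],  # EAS
        dtype=np.int8,
    )
    variants = [
        VariantRecord("1", 100, "A", "G", ancestral_allele="A"),  # anc = ref
        VariantRecord("1", 200, "T", "C", ancestral_allele="C"),  # anc = alt
    ]
    pops = np.array(["EUR"] * 6 + ["EAS"] * 6, dtype=object)
    return ReferencePanel([f"s{i}" for i in range(12)], pops, variants,
                          genotypes, pd.DataFrame())


class TestDerivedAlleleFreqs:
    def test_polarity_and_higher_population(self):
        panel = _toy_panel()
        daf = derived_allele_freqs(panel, np.array([0, 1])).set_index("snp_index")
        # SNP 0: anc=ref -> DAF = alt freq: EUR 10/12, EAS 1/12
        assert daf.loc[0, "daf_eur"] == pytest.approx(10 / 12)
        assert daf.loc[0, "daf_eas"] == pytest.approx(1 / 12)
        assert daf.loc[0, "higher_daf_in"] == "Europe"
        # SNP 1: anc=alt -> DAF = 1 - alt freq: EUR 11/12, EAS 1/12
        assert daf.loc[1, "daf_eur"] == pytest.approx(11 / 12)
        assert daf.loc[1, "daf_eas"] == pytest.approx(1 / 12)
        assert daf.loc[1, "higher_daf_in"] == "Europe"

    def test_mismatching_ancestral_allele_skipped_with_warning(self):
        panel = _toy_panel()
        panel.variants[0].ancestral_allele = "T"
        with pytest.warns(UserWarning, match="neither ref nor alt"):
            daf = derived_allele_freqs(panel, np.array([0, 1]))
        assert list(daf["snp_index"]) == [1]

    def test_daf_matches_generator_truth(self):
        cfg = SimConfig(n_panel_snps=400, planted_selected_snps=10,
                        panel_size_afr=80, panel_size_eur=80,
                        panel_size_eas=80, seed=12)
        panel = simulate_reference_panel(cfg)
        idx = np.arange(cfg.n_panel_snps)
        daf = derived_allele_freqs(panel, idx).set_index("snp_index")
        se4 = 4 * np.sqrt(0.25 / 160)
        for pop in ("afr", "eur", "eas"):
            observed = daf[f"daf_{pop}"].to_numpy()
            expected = panel.truth[f"daf_{pop}"].to_numpy()
            assert np.abs(observed - expected).max() < se4


class TestScanIntegration:
    def test_planted_snps_found_and_rolled_up_to_genes(self, tiny_study):
        scan = scan_selection(tiny_study.panel, catalog=tiny_study.catalog)
        truth = tiny_study.panel.truth
        sel_truth = truth["selected"].to_numpy()[scan.table["snp_index"]]
        sig = scan.table["significant"].to_numpy()
        assert (sig & sel_truth).sum() / sel_truth.sum() >= 0.9
        genes = scan.genes_under_selection()
        planted = {
            g["gene"]
            for g in tiny_study.discovery.manifest.genes
            if g["true_group"] != "none"
        }
        assert set(genes["gene"]) <= planted | set()
        assert len(genes) > 0
        assert set(genes["higher_daf_in"]) <= {
            "Europe", "East Asia", "Europe, East Asia", "tie"
        }
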