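import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from pleiogene.genetest import (GeneSnpSet, GeneTestConfig, assign_snps_to_genes,
                                chisq_from_p, empirical_p, gene_statistic,
                                ld_matrix, run_gene_test, simulate_null)
from pleiogene.genetest import test_gene as single_gene_test
from pleiogene.io import GeneInterval, ReferencePanel, SnpAssociation
from pleiogene.simulate import SimulationConfig, generate_all


def chi2_quantile_oracle(p: float) -> float:
    """Independent root-find on the chi-square(1) CDF."""
    return optimize.brentq(lambda q: 1.0 - stats.chi2.cdf(q, 1) - p, 0, 400)


class TestChisqFromP:
    def test_p_one_maps_to_zero(self):
        assert chisq_from_p(1.0) == 0.0

    def test_standard_normal_identity(self):
        # two-sided p of z = 1 is 0.3173; the matching chi-square(1) value is 1
        assert chisq_from_p(0.3173) == pytest.approx(1.0, abs=1e-3)

    def test_quantile_against_root_find(self):
        assert chisq_from_p(0.05) == pytest.approx(chi2_quantile_oracle(0.05), abs=1e-9)
        assert chisq_from_p(0.05) == pytest.approx(3.8415, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            chisq_from_p(bad)


class TestGeneStatistic:
    def test_all_p_one_gives_zero(self):
        assert gene_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_single_member_equals_conversion(self):
        assert gene_statistic([0.05]) == pytest.approx(3.8415, abs=1e-4)

    def test_additivity(self):
        assert gene_statistic([0.05, 0.05]) == pytest.approx(2 * 3.84146, abs=1e-3)


class TestEmpiricalP:
    @pytest.mark.parametrize("r,m,expect", [(0, 999, 0.001), (999, 999, 1.0),
                                            (49, 999, 0.05)])
    def test_formula(self, r, m, expect):
        nulls = np.concatenate([np.full(r, 2.0), np.full(m - r, 0.0)])
        assert empirical_p(1.0, nulls) == pytest.approx(expect)

    def test_ties_do_not_surpass(self):
        assert empirical_p(1.0, np.array([1.0, 1.0, 2.0])) == pytest.approx(2 / 4)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0, 50), st.floats(0, 50), st.integers(10, 500))
    def test_bounds_and_monotonicity(self, obs1, obs2, m):
        nulls = np.random.default_rng(0).chisquare(3, size=m)
        p1, p2 = empirical_p(obs1, nulls), empirical_p(obs2, nulls)
        for p in (p1, p2):
            assert 1 / (m + 1) <= p <= 1.0
        if obs1 < obs2:
            assert p1 >= p2


class TestLdMatrix:
    def test_identical_columns_give_unit_correlation(self, tiny_panel):
        # PSD repair floors the zero eigenvalue, so r sits within 1e-6 of 1
        m = ld_matrix(tiny_panel, ["rs1", "rs2"])
        assert m.sigma[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_single_member(self, tiny_panel):
        m = ld_matrix(tiny_panel, ["rs1"])
        assert m.sigma.shape == (1, 1) and m.sigma[0, 0] == 1.0

    def test_monomorphic_member_dropped(self, tiny_panel, caplog):
        with caplog.at_level("WARNING"):
            m = ld_matrix(tiny_panel, ["rs1", "rs5"])
        assert m.source_snps == ["rs1"]

    def test_all_monomorphic_raises(self, tiny_panel):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_matrix(tiny_panel, ["rs5"])

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(5)
        dosages = rng.integers(0, 3, size=(10_000, 2)).astype(float)
        panel = ReferencePanel(
            snps=pd.DataFrame({"rsid": ["a", "b"], "chrom": "1", "pos": [1, 2]}),
            dosages=dosages)
        assert abs(ld_matrix(panel, ["a", "b"]).sigma[0, 1]) < 0.05

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, size=(500, 2)).astype(float)
        x[:50, 0] = np.nan
        panel = ReferencePanel(
            snps=pd.DataFrame({"rsid": ["a", "b"], "chrom": "1", "pos": [1, 2]}),
            dosages=x)
        m = ld_matrix(panel, ["a", "b"])
        assert np.isfinite(m.sigma).all()

    def test_rank_deficient_panel_is_repaired(self):
        # 4 individuals, 6 SNPs: sample correlation cannot be full rank
        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, size=(4, 6)).astype(float)
        panel = ReferencePanel(
            snps=pd.DataFrame({"rsid": [f"s{i}" for i in range(6)],
                               "chrom": "1", "pos": range(1, 7)}),
            dosages=dosages)
        m = ld_matrix(panel, [f"s{i}" for i in range(6)])
        w = np.linalg.eigvalsh(m.sigma)
        assert w.min() > 0  # PSD after repair
        np.testing.assert_allclose(np.diag(m.sigma), 1.0, atol=1e-12)
        # the repaired matrix must be Cholesky-decomposable for simulation
        simulate_null(m, 10, seed=0)


class TestSimulateNull:
    @pytest.mark.parametrize("n", [1, 4])
    def test_identity_sigma_matches_chi2_n(self, n):
        nulls = simulate_null(np.eye(n), 10_000, seed=123)
        assert stats.kstest(nulls, stats.chi2(n).cdf).pvalue > 0.01

    def test_perfect_ld_is_scaled_chi2_1(self):
        n = 4
        nulls = simulate_null(np.ones((n, n)), 10_000, seed=321)
        assert stats.kstest(nulls / n, stats.chi2(1).cdf).pvalue > 0.01

    def test_stream_determined_by_seed(self):
        a = simulate_null(np.eye(3), 100, seed=9)
        b = simulate_null(np.eye(3), 100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestAssignSnpsToGenes:
    def snps(self):
        return [SnpAssociation("rs1", 0.01), SnpAssociation("rs2", 0.5),
                SnpAssociation("rs3", 0.02), SnpAssociation("rs4", 0.9)]

    def test_boundary_snp_included(self, tiny_panel, gene_100_200):
        out = assign_snps_to_genes([SnpAssociation("rs1", 0.01)], [gene_100_200],
                                   tiny_panel)
        assert [m.rsid for m in out["GENE1"].members] == ["rs1"]  # pos 100 == start

    def test_ld_recruitment_above_threshold(self, tiny_panel, gene_100_200):
        # rs3 sits 5 kb outside but is a noisy copy of rs1 (r^2 ~ 0.9)
        out = assign_snps_to_genes(self.snps(), [gene_100_200], tiny_panel)
        members = out["GENE1"]
        assert "rs3" in [m.rsid for m in members.members]
        assert members.inside_flags[[m.rsid for m in members.members].index("rs3")] is False

    def test_low_ld_outside_snp_excluded(self, tiny_panel, gene_100_200):
        out = assign_snps_to_genes(self.snps(), [gene_100_200], tiny_panel)
        assert "rs4" not in [m.rsid for m in out["GENE1"].members]

    def test_absent_snps_dropped_and_counted(self, tiny_panel, gene_100_200, caplog):
        snps = self.snps() + [SnpAssociation("rs_nowhere", 0.01)]
        with caplog.at_level("WARNING"):
            assign_snps_to_genes(snps, [gene_100_200], tiny_panel)
        assert "dropped 1" in caplog.text

    def test_gene_without_members_absent(self, tiny_panel):
        lonely = GeneInterval(gene="G2", chrom="2", start=1, end=10)
        out = assign_snps_to_genes(self.snps(), [lonely], tiny_panel)
        assert out == {}

    def test_members_ordered_by_position(self, tiny_panel, gene_100_200):
        out = assign_snps_to_genes(list(reversed(self.snps())), [gene_100_200],
                                   tiny_panel)
        positions = [tiny_panel.position(m.rsid)[1] for m in out["GENE1"].members]
        assert positions == sorted(positions)


class TestTestGene:
    def test_all_p_one_gives_p_one(self, tiny_panel):
        gs = GeneSnpSet(gene="G", members=[SnpAssociation("rs1", 1.0),
                                           SnpAssociation("rs4", 1.0)],
                        inside_flags=[True, True])
        res = single_gene_test(gs, tiny_panel, GeneTestConfig(stages=(1000,)))
        assert res.statistic == 0.0 and res.empirical_p == 1.0

    def test_top_snp_min_p_position_tiebreak(self, tiny_panel):
        gs = GeneSnpSet(gene="G", members=[SnpAssociation("rs4", 0.01),
                                           SnpAssociation("rs1", 0.01)],
                        inside_flags=[True, True])
        res = single_gene_test(gs, tiny_panel, GeneTestConfig(stages=(1000,)))
        assert res.top_snp == "rs1"  # pos 100 < 9000 breaks the p-value tie

    def test_adaptive_schedule_stops_early_for_large_p(self, tiny_panel):
        gs = GeneSnpSet(gene="G", members=[SnpAssociation("rs1", 0.5)],
                        inside_flags=[True])
        res = single_gene_test(gs, tiny_panel, GeneTestConfig(stages=(1000, 100_000)))
        assert res.n_sims == 1000 and res.n_exceed >= 10

    def test_schedule_escalates_for_small_p(self, tiny_panel):
        gs = GeneSnpSet(gene="G", members=[SnpAssociation("rs1", 1e-6)],
                        inside_flags=[True])
        res = single_gene_test(gs, tiny_panel, GeneTestConfig(stages=(1000, 10_000)))
        assert res.n_sims == 10_000


class TestRunGeneTest:
    def test_planted_gene_ranks_first(self):
        cfg = SimulationConfig(seed=2, n_genes=30, n_individuals=300,
                               snps_per_gene=10, causal_genes={"G0007": 5.0})
        data = generate_all(cfg)
        table = run_gene_test(data["gwas_a"], data["genes"], data["panel"],
                              GeneTestConfig(stages=(1000, 10_000), seed=1))
        assert table.sort_values("empirical_p").iloc[0]["gene"] == "G0007"

    def test_type_i_error_calibrated_under_null(self):
        cfg = SimulationConfig(seed=4, n_genes=200, n_individuals=300,
                               snps_per_gene=(2, 8))
        data = generate_all(cfg)
        table = run_gene_test(data["gwas_a"], data["genes"], data["panel"],
                              GeneTestConfig(stages=(1000,), seed=11))
        frac = (table["empirical_p"] < 0.05).mean()
        half_width = 2.58 * np.sqrt(0.05 * 0.95 / len(table))  # 99% binomial band
        assert abs(frac - 0.05) < half_width

    def test_snp_order_permutation_is_bitwise_stable(self, tiny_panel, gene_100_200):
        snps = [SnpAssociation("rs1", 0.01), SnpAssociation("rs2", 0.5),
                SnpAssociation("rs3", 0.02), SnpAssociation("rs4", 0.9)]
        cfg = GeneTestConfig(stages=(1000,), seed=3)
        t1 = run_gene_test(snps, [gene_100_200], tiny_panel, cfg)
        t2 = run_gene_test(list(reversed(snps)), [gene_100_200], tiny_panel, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_intersection_gives_empty_table(self, tiny_panel, gene_100_200, caplog):
        with caplog.at_level("WARNING"):
            table = run_gene_test([SnpAssociation("rsX", 0.01)], [gene_100_200],
                                  tiny_panel, GeneTestConfig(stages=(100,)))
        assert table.empty
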