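"""Quality control, single-marker association, and chip construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gblend as gb
from tests.test_relmat import geno


class TestHweTest:
    def test_exact_proportions_give_p_one(self):
        assert gb.hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_heterozygote_statistic(self):
        # expected 25/50/25 -> chi2 = 25 + 50 + 25 = 100
        assert gb.hwe_test(0, 100, 0) == pytest.approx(
            float(stats.chi2.sf(100.0, 1))
        )

    def test_monomorphic_returns_one(self):
        assert gb.hwe_test(100, 0, 0) == 1.0
        assert gb.hwe_test(0, 0, 37) == 1.0

    @given(
        n_AA=st.integers(0, 200),
        n_Aa=st.integers(0, 200),
        n_aa=st.integers(0, 200),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_p_value_in_unit_interval(self, n_AA, n_Aa, n_aa):
        if n_AA + n_Aa + n_aa == 0:
            return
        p = gb.hwe_test(n_AA, n_Aa, n_aa)
        assert 0.0 <= p <= 1.0


class TestQcFilter:
    def test_maf_rule_counts(self):
        rng = np.random.default_rng(0)
        n = 200
        mafs = [0.0, 0.005, 0.02, 0.3, 0.5]
        cols = []
        for m in mafs:
            # HWE genotype draws at frequency m, full call rate
            cols.append(rng.binomial(2, m, size=n))
        counts = np.column_stack(cols).astype(np.int8)
        counts[:, 1] = 0
        counts[0, 1] = 1  # MAF 1/400 = 0.0025 < 0.01, in HWE at low freq
        out, report = gb.qc_filter(
            geno(counts), gb.QcThresholds(hwe_p_max=0.0, completeness_min=0.0)
        )
        assert out.n_markers == 3
        assert report.n_fail_maf == 2

    def test_zero_strength_thresholds_are_noop(self, toy_pop):
        g = toy_pop.marker_genotypes()
        out, report = gb.qc_filter(
            g, gb.QcThresholds(hwe_p_max=0.0, completeness_min=0.0, maf_min=0.0)
        )
        assert report.n_removed == 0
        assert np.array_equal(out.counts, g.counts)

    def test_double_failure_counted_twice_removed_once(self):
        rng = np.random.default_rng(1)
        good = rng.binomial(2, 0.4, size=400)
        # rare AND out of HWE: 3 minor homozygotes, no heterozygotes
        # (MAF = 6/800 < 0.01; expected AA ~ 0.02, observed 3)
        bad = np.zeros(400, dtype=np.int8)
        bad[:3] = 2
        counts = np.column_stack([good, bad]).astype(np.int8)
        out, report = gb.qc_filter(geno(counts), gb.QcThresholds(
            hwe_p_max=0.001, completeness_min=0.0, maf_min=0.01
        ))
        assert report.n_fail_maf == 1
        assert report.n_fail_hwe == 1
        assert report.n_removed == 1
        assert out.n_markers == 1

    def test_idempotent(self, toy_pop):
        thr = gb.QcThresholds()
        once, _ = gb.qc_filter(toy_pop.marker_genotypes(), thr)
        twice, rep = gb.qc_filter(once, thr)
        assert rep.n_removed == 0
        assert np.array_equal(once.counts, twice.counts)


class TestRunGwa:
    @staticmethod
    def phen_for(ids, y, rng):
        return pd.DataFrame(
            {
                "id": ids,
                "bwt": y,
                "sex": rng.choice(["M", "F"], len(ids)),
                "hatch_week": rng.integers(0, 3, len(ids)),
            }
        )

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n, m = 60, 5
        counts = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        g = geno(counts)
        phen = self.phen_for(g.ids, rng.normal(0, 1, n) + counts[:, 0], rng)
        res = gb.run_gwa(g, phen)
        from gblend.mixedmodel import design_matrix

        X, _ = design_matrix(phen)
        for k in range(m):
            ols = sm.OLS(
                phen["bwt"].to_numpy(),
                np.column_stack([counts[:, k].astype(float), X]),
            ).fit()
            assert res["beta"].iloc[k] == pytest.approx(ols.params[0])
            assert res["t"].iloc[k] == pytest.approx(ols.tvalues[0])
            assert res["p"].iloc[k] == pytest.approx(ols.pvalues[0])

    def test_null_type_one_error_rate(self):
        """Phenotype independent of genotype: ~5% of P values below 0.05."""
        cfg = gb.SimulationConfig(
            n_founders=300, n_generations=1, n_chromosomes=2,
            markers_per_chromosome=500, n_qtl=2, V_A=0.0, V_E=100.0,
            hatch_week_levels=3, seed=17,
        )
        pop = gb.simulate_population(cfg)
        res = gb.run_gwa(pop.marker_genotypes(include_qtl=True), pop.phenotypes)
        frac = (res["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.025)

    def test_large_effect_qtl_detected(self):
        rng = np.random.default_rng(4)
        n = 500
        counts = rng.binomial(2, 0.4, size=(n, 3)).astype(np.int8)
        g = geno(counts)
        y = 5.0 * counts[:, 1] + rng.normal(0, 2, n)
        res = gb.run_gwa(g, self.phen_for(g.ids, y, rng))
        assert res["p"].iloc[1] < 1e-6

    def test_monomorphic_marker_gets_null_result(self):
        rng = np.random.default_rng(6)
        counts = np.column_stack(
            [np.full(50, 2), rng.integers(0, 3, 50)]
        ).astype(np.int8)
        g = geno(counts)
        res = gb.run_gwa(g, self.phen_for(g.ids, rng.normal(0, 1, 50), rng))
        assert res["p"].iloc[0] == 1.0
        assert res["beta"].iloc[0] == 0.0

    def test_tst_rows_are_excluded(self):
        rng = np.random.default_rng(7)
        n = 80
        counts = rng.integers(0, 3, size=(n, 4)).astype(np.int8)
        g = geno(counts)
        phen = self.phen_for(g.ids, rng.normal(0, 1, n), rng)
        phen["subset"] = np.where(np.arange(n) < 50, "TRN", "TST")
        res_all = gb.run_gwa(g, phen)
        res_trn = gb.run_gwa(g, phen.loc[phen["subset"] == "TRN"])
        pd.testing.assert_frame_equal(res_all, res_trn)


def marker_table(per_chrom_counts, rng):
    rows = []
    for c, m in enumerate(per_chrom_counts, start=1):
        cm = np.sort(rng.uniform(0, 100, m))
        for j in range(m):
            rows.append((f"c{c}m{j}", c, cm[j], int(cm[j] * 1e4) + j + 1,
                         rng.uniform(0.01, 0.5)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp", "maf"])


class TestEsmPanel:
    def test_small_chromosome_taken_whole(self):
        rng = np.random.default_rng(8)
        tbl = marker_table([800], rng)
        panel = gb.select_esm_panel(tbl, 1000)
        assert panel.size == 800

    def test_study_chip_size(self):
        """Four short chromosomes (888/998/998/991) in 27 -> 26,875 SNPs."""
        rng = np.random.default_rng(9)
        sizes = [1100] * 23 + [888, 998, 998, 991]
        tbl = marker_table(sizes, rng)
        panel = gb.select_esm_panel(tbl, 1000)
        assert panel.size == 26_875

    def test_tie_prefers_higher_maf(self):
        tbl = pd.DataFrame(
            {
                "marker": ["a", "b"],
                "chrom": 1,
                "cM": [40.0, 60.0],
                "bp": [1, 2],
                "maf": [0.1, 0.4],
            }
        )
        panel = gb.select_esm_panel(tbl, 1)
        assert panel.markers == ["b"]

    def test_even_coverage_of_the_map(self):
        rng = np.random.default_rng(10)
        tbl = marker_table([2000], rng)
        panel = gb.select_esm_panel(tbl, 100)
        pos = tbl.set_index("marker").loc[panel.markers, "cM"].sort_values()
        gaps = np.diff(pos)
        assert panel.size == 100
        assert gaps.max() < 5.0  # near-even 1 cM spacing, no large holes


class TestGwamPanel:
    @staticmethod
    def gwa_table(per_chrom, rng):
        tbl = marker_table(per_chrom, rng)
        tbl["beta"] = rng.normal(size=len(tbl))
        tbl["t"] = rng.normal(size=len(tbl))
        tbl["p"] = rng.uniform(size=len(tbl))
        return tbl

    def test_study_chip_size(self):
        rng = np.random.default_rng(11)
        tbl = self.gwa_table([1005] * 27, rng)
        panel = gb.select_gwam_panel(tbl, 1000)
        assert panel.size == 27_000
        assert all(v == 1000 for v in panel.per_chromosome.values())

    def test_selects_smallest_p(self):
        rng = np.random.default_rng(12)
        tbl = self.gwa_table([50], rng)
        panel = gb.select_gwam_panel(tbl, 10)
        chosen_p = tbl.set_index("marker").loc[panel.markers, "p"]
        assert chosen_p.max() <= tbl["p"].nsmallest(10).max()

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(13)
        tbl = self.gwa_table([40, 40], rng)
        tbl.loc[:10, "p"] = 1.0  # force ties
        a = gb.select_gwam_panel(tbl, 15)
        b = gb.select_gwam_panel(tbl.sample(frac=1, random_state=5), 15)
        assert a.markers == b.markers

    def test_all_ties_falls_back_to_deterministic_order(self):
        rng = np.random.default_rng(14)
        tbl = self.gwa_table([30], rng)
        tbl["p"] = 1.0
        tbl["t"] = 0.0
        panel = gb.select_gwam_panel(tbl, 10)
        assert panel.size == 10
        assert panel.markers == sorted(tbl["marker"])[:10]


def test_esm_panel_has_higher_maf_than_gwam(toy_pop):
    """ESM prefers common variants; GWA ranking does not."""
    phen = toy_pop.phenotypes
    g, _ = gb.qc_filter(toy_pop.marker_genotypes())
    gwa = gb.run_gwa(g, phen.loc[phen["subset"] == "TRN"])
    esm = gb.select_esm_panel(g.markers.assign(maf=g.maf()), 30)
    gwam = gb.select_gwam_panel(gwa, 30)
    maf = pd.Series(g.maf(), index=g.markers["marker"])
    assert maf.loc[esm.markers].mean() > maf.loc[gwam.markers].mean()
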