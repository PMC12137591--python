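import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import hapreml as H
from hapreml.geno_io import PhenotypeTable
from hapreml.rhm_scan import (
    COMPARISONS,
    PrecorrectedPhenotype,
    RegionalScanResult,
    lrt_pvalue,
    precorrect,
    scan,
    significance_threshold,
    summarize_variance,
)
from hapreml.varcomp import ModelSpec

from conftest import random_hwe_panel


class TestMixturePvalues:
    def test_zero_statistic_one_df(self):
        for comp in ("snp_vs_null", "hap_vs_null", "snhap_vs_hap", "snhap_vs_snp"):
            assert lrt_pvalue(0.0, comp) == pytest.approx(0.5)

    def test_zero_statistic_two_df(self):
        assert lrt_pvalue(0.0, "snhap_vs_null") == pytest.approx(0.75)

    def test_chi2_95th_quantile_one_df(self):
        q = chi2.ppf(0.95, 1)  # 3.841...
        assert lrt_pvalue(q, "snp_vs_null") == pytest.approx(0.025, abs=5e-4)

    def test_monotone_nonincreasing(self):
        for comp in COMPARISONS:
            ps = [lrt_pvalue(x, comp) for x in np.linspace(0, 20, 50)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
            assert all(0 < p <= 1 for p in ps)

    def test_small_negative_clamped_large_negative_raises(self):
        assert lrt_pvalue(-1e-5, "snp_vs_null") == pytest.approx(0.5)
        with pytest.raises(ValueError, match="worse"):
            lrt_pvalue(-0.01, "snp_vs_null")

    def test_unknown_comparison_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(1.0, "not_a_test")


class TestThreshold:
    def test_study_scale_blocks(self):
        t = significance_threshold(48_125, 0.05)
        assert np.format_float_scientific(t, precision=2) == "1.04e-06"

    def test_no_correction_single_block(self):
        assert significance_threshold(1, 0.05) == 0.05

    def test_zero_blocks_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(0)


def _loco_and_phen(rng, n=120, m_chr1=6, m_chr2=40, y=None, extra_cols=None):
    panel = random_hwe_panel(
        rng, n=n, m=m_chr1 + m_chr2,
        chromosomes=["chr1"] * m_chr1 + ["chr2"] * m_chr2,
        positions=[1000 * (k + 1) for k in range(m_chr1)]
        + [1000 * (k + 1) for k in range(m_chr2)],
    )
    loco = H.loco_grm(panel, "chr1")
    if y is None:
        y = rng.normal(size=n)
    df = pd.DataFrame({"id": panel.individual_ids, "y": y, **(extra_cols or {})})
    return panel, loco, PhenotypeTable(df, "y")


class TestPrecorrect:
    def test_zero_genetic_variance_gives_centered_response(self):
        # seed chosen so the LOCO variance estimate hits the 0 boundary
        for seed in range(8):
            rng = np.random.default_rng(300 + seed)
            panel, loco, tab = _loco_and_phen(rng)
            spec = ModelSpec("y", genetic_components=[(None, "g_loco")])
            out = precorrect(tab, spec, loco)
            fitted = out.provenance["chr1"]["variances"]
            if fitted["g_loco"] == 0.0:
                y = tab.records["y"].to_numpy()
                np.testing.assert_allclose(
                    out.values["chr1"], y - y.mean(), atol=1e-10
                )
                return
        pytest.fail("no boundary fit found across seeds")

    def test_residuals_orthogonal_to_sex_at_zero_genetic_variance(self):
        for seed in range(8):
            rng = np.random.default_rng(400 + seed)
            sex = rng.integers(0, 2, size=120)
            panel, loco, tab = _loco_and_phen(rng, extra_cols={"sex": sex})
            spec = ModelSpec(
                "y", fixed_effects=["sex"], genetic_components=[(None, "g_loco")]
            )
            out = precorrect(tab, spec, loco)
            if out.provenance["chr1"]["variances"]["g_loco"] == 0.0:
                assert abs(out.values["chr1"] @ sex) <= 1e-8
                return
        pytest.fail("no boundary fit found across seeds")

    def test_repeated_shifted_twin_differs_by_shift(self, rng):
        # two genetically identical individuals; one's records all +c:
        # pe BLUP + mean residual must differ by exactly c
        c = 1.7
        n, R = 4, 3
        panel = random_hwe_panel(
            rng, n=n, m=8,
            chromosomes=["chr1"] * 2 + ["chr2"] * 6,
            positions=[1000, 2000, 1000, 2000, 3000, 4000, 5000, 6000],
        )
        hap = panel.haplotype_calls.copy()
        hap[1] = hap[0]  # s0 and s1 are genotype duplicates
        from conftest import make_panel

        panel = make_panel(
            hap,
            chromosomes=list(panel.chromosomes),
            positions=list(panel.positions_bp),
        )
        loco = H.loco_grm(panel, "chr1")
        base = rng.normal(size=n * R)
        ids = np.repeat(panel.individual_ids, R)
        y = base.copy()
        y[ids == "s1"] = y[ids == "s0"] + c
        tab = PhenotypeTable(
            pd.DataFrame({"id": ids, "y": y}), "y", repeated=True
        )
        spec = ModelSpec(
            "y", genetic_components=[(None, "g_loco")], repeated=True
        )
        out = precorrect(tab, spec, loco)
        i0 = list(out.individual_ids).index("s0")
        i1 = list(out.individual_ids).index("s1")
        assert out.values["chr1"][i1] - out.values["chr1"][i0] == pytest.approx(
            c, abs=1e-6
        )

    def test_ungenotyped_individuals_dropped(self, rng):
        panel, loco, tab = _loco_and_phen(rng, n=50)
        extra = pd.concat(
            [tab.records, pd.DataFrame({"id": ["ghost"], "y": [1.0]})],
            ignore_index=True,
        )
        tab2 = PhenotypeTable(extra, "y")
        spec = ModelSpec("y", genetic_components=[(None, "g_loco")])
        out = precorrect(tab2, spec, loco)
        assert "ghost" not in set(out.individual_ids)
        assert len(out.individual_ids) == 50

    def test_requires_loco_matrix(self, rng):
        panel, loco, tab = _loco_and_phen(rng, n=30)
        wg = H.whole_genome_grm(panel)
        spec = ModelSpec("y", genetic_components=[(None, "g")])
        with pytest.raises(ValueError, match="LOCO"):
            precorrect(tab, spec, wg)


@pytest.fixture(scope="module")
def scan_world():
    scen = H.SimScenario(
        seed=21, n_individuals=250, n_chromosomes=2, blocks_per_chromosome=2,
        qtl_architecture="snp_additive", regional_share=0.25,
    )
    geno = H.simulate_genotypes(scen)
    phen, truth = H.simulate_phenotypes(geno, scen)
    blocks = H.true_blocks(scen)
    values = {
        ch: phen.records["trait"].to_numpy()
        for ch in dict.fromkeys(geno.chromosomes)
    }
    y_pre = PrecorrectedPhenotype(geno.individual_ids, values)
    return scen, geno, blocks, y_pre, truth


class TestFitBlockAndScan:
    def test_scan_flags_causal_block(self, scan_world):
        scen, geno, blocks, y_pre, truth = scan_world
        res = scan(geno, blocks, y_pre, alpha=0.05)
        assert res.n_blocks == 4
        assert res.threshold == pytest.approx(0.05 / 4)
        t = res.table.set_index("block_id")
        causal = t.loc[truth.causal_block_id]
        assert causal["p_snp_vs_null"] < res.threshold
        # LRT statistics are non-negative and p-values valid everywhere
        for comp in COMPARISONS:
            ok = ~t[f"lrt_{comp}"].isna()
            assert (t.loc[ok, f"lrt_{comp}"] >= 0).all()
            assert t.loc[ok, f"p_{comp}"].between(0, 1, inclusive="right").all()

    def test_pvalue_pipeline_deterministic(self, scan_world):
        scen, geno, blocks, y_pre, truth = scan_world
        res = scan(geno, blocks, y_pre)
        t = res.table
        for comp, (alt, nested, _) in COMPARISONS.items():
            lrt = 2.0 * (t[f"loglik_{alt}"] - t[f"loglik_{nested}"])
            redo = [lrt_pvalue(max(x, 0.0), comp) for x in lrt]
            np.testing.assert_array_equal(redo, t[f"p_{comp}"].to_numpy())

    def test_degenerate_block_skipped_not_fatal(self, scan_world, rng):
        scen, geno, blocks, y_pre, truth = scan_world
        # monomorphise one block's SNPs in every individual
        hap = geno.haplotype_calls.copy()
        idx = list(blocks[1].snp_indices)
        hap[:, idx, :] = 0
        from conftest import make_panel

        geno2 = make_panel(
            hap,
            chromosomes=list(geno.chromosomes),
            positions=list(geno.positions_bp),
            ids=list(geno.individual_ids),
        )
        res = scan(geno2, blocks, y_pre)
        t = res.table.set_index("block_id")
        assert bool(t.loc[blocks[1].block_id, "skipped"])
        assert (~t["skipped"]).sum() == 3

    def test_single_snp_block_unreachable(self):
        with pytest.raises(ValueError):
            H.HaplotypeBlock("chr1", 1, 1, (0,), "bad")


class TestSummarizeVariance:
    def _result(self, rows):
        cols = {
            "block_id": [], "chrom": [], "start_bp": [], "end_bp": [],
            "skipped": [], "var_rsnp_snp": [], "var_rhap_hap": [],
            "var_rsnp_snhap": [], "var_rhap_snhap": [],
            "sig_snp_vs_null": [], "sig_hap_vs_null": [], "sig_snhap_vs_null": [],
        }
        for r in rows:
            for k in cols:
                cols[k].append(r[k])
        return RegionalScanResult(pd.DataFrame(cols), len(rows), 1e-6)

    @staticmethod
    def _row(bid, chrom, start, end, share, sig=True):
        return {
            "block_id": bid, "chrom": chrom, "start_bp": start, "end_bp": end,
            "skipped": False, "var_rsnp_snp": share, "var_rhap_hap": share,
            "var_rsnp_snhap": share / 2, "var_rhap_snhap": share / 2,
            "sig_snp_vs_null": sig, "sig_hap_vs_null": sig,
            "sig_snhap_vs_null": sig,
        }

    def test_single_block_share(self):
        res = self._result([self._row("b0", "chr1", 1_000_000, 1_050_000, 0.1)])
        out = summarize_variance(res, total_genetic_variance=1.0)
        row = out.set_index("method").loc["snp"]
        assert row["percent_genetic_variance"] == pytest.approx(10.0)
        assert row["n_loci"] == 1

    def test_adjacent_blocks_merge_to_best(self):
        res = self._result([
            self._row("b0", "chr1", 1_000_000, 1_050_000, 0.08),
            self._row("b1", "chr1", 1_250_000, 1_300_000, 0.05),  # 200 kb gap
        ])
        out = summarize_variance(res, 1.0).set_index("method")
        assert out.loc["snp", "percent_genetic_variance"] == pytest.approx(8.0)
        assert out.loc["snp", "n_loci"] == 1

    def test_distant_blocks_stay_separate(self):
        res = self._result([
            self._row("b0", "chr1", 1_000_000, 1_050_000, 0.08),
            self._row("b1", "chr1", 3_050_000, 3_100_000, 0.05),  # 2 Mb gap
        ])
        out = summarize_variance(res, 1.0).set_index("method")
        assert out.loc["snp", "percent_genetic_variance"] == pytest.approx(13.0)
        assert out.loc["snp", "n_loci"] == 2

    def test_snhap_uses_component_sum(self):
        res = self._result([self._row("b0", "chr1", 1_000_000, 1_050_000, 0.1)])
        out = summarize_variance(res, 1.0).set_index("method")
        assert out.loc["snhap", "percent_genetic_variance"] == pytest.approx(10.0)

    def test_no_significant_blocks_gives_zero_rows(self):
        res = self._result(
            [self._row("b0", "chr1", 1_000_000, 1_050_000, 0.1, sig=False)]
        )
        out = summarize_variance(res, 1.0)
        assert (out["percent_genetic_variance"] == 0.0).all()

    def test_nonpositive_total_rejected(self):
        res = self._result([self._row("b0", "chr1", 1, 2, 0.1)])
        with pytest.raises(ValueError):
            summarize_variance(res, 0.0)
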