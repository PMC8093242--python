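import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cvsem.datasets import GenotypeDataset
from cvsem.gwas import (
    CHI2_1_MEDIAN,
    Locus,
    ScanError,
    define_loci,
    export_plots_data,
    genomic_control,
    ld_r2,
    loci_table,
    run_scan,
    single_trait_scan,
)
from cvsem.simulate import (
    SimulationConfig,
    simulate_category_scores,
    simulate_genotypes,
)
from .conftest import make_category_data


def _fake_table(z: np.ndarray) -> pd.DataFrame:
    m = z.size
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "id": [f"v{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
            "maf": 0.3,
            "n": 100,
            "beta": z * 0.1,
            "se": 0.1,
            "z": z,
            "p_raw": 2 * stats.norm.sf(np.abs(z)),
        }
    )


class TestGenomicControl:
    def test_constant_median_statistic_lambda_one(self):
        z = np.full(200, np.sqrt(CHI2_1_MEDIAN))
        out = genomic_control(_fake_table(z))
        assert out.attrs["lambda_gc"] == pytest.approx(1.0)
        np.testing.assert_allclose(out["p_gc"], out["p_raw"])

    def test_doubling_statistics_doubles_lambda_keeps_p_gc(self, rng):
        z = rng.standard_normal(5000) * 1.5  # inflated
        t1 = genomic_control(_fake_table(z))
        t2 = genomic_control(_fake_table(z * np.sqrt(2)))
        assert t2.attrs["lambda_gc"] == pytest.approx(
            2 * t1.attrs["lambda_gc"], rel=1e-12
        )
        np.testing.assert_allclose(t2["p_gc"], t1["p_gc"], rtol=1e-10)

    def test_standard_normal_lambda_near_one(self, rng):
        z = rng.standard_normal(10_000)
        out = genomic_control(_fake_table(z))
        assert 0.95 <= out.attrs["lambda_gc"] <= 1.05

    def test_deflation_only_when_inflated(self, rng):
        z = rng.standard_normal(500) * 0.5  # deflated: lambda < 1
        out = genomic_control(_fake_table(z))
        assert out.attrs["lambda_gc"] < 1
        np.testing.assert_array_equal(out["p_gc"], out["p_raw"])

    def test_requires_100_statistics(self):
        with pytest.raises(ScanError):
            genomic_control(_fake_table(np.ones(50)))


class TestLdR2:
    def test_self_and_mirror(self, rng):
        g = rng.binomial(2, 0.4, 500).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2.0 - g) == pytest.approx(1.0)

    def test_independent_variants_small(self, rng):
        a = rng.binomial(2, 0.3, 5000).astype(float)
        b = rng.binomial(2, 0.3, 5000).astype(float)
        assert ld_r2(a, b) < 0.01

    def test_monomorphic_rejected(self, rng):
        with pytest.raises(ValueError):
            ld_r2(np.zeros(10), rng.binomial(2, 0.5, 10).astype(float))


def _block_panel(rng, n=400):
    """Five-variant panel: a perfect 3-variant LD block + 2 independent."""
    g = rng.binomial(2, 0.4, n).astype(float)
    other = rng.binomial(2, 0.4, (n, 2)).astype(float)
    dosages = np.column_stack([g, g, 2 - g, other])
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [1000, 2000, 3000, 200_000, 9_000_000],
            "id": [f"v{i}" for i in range(5)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeDataset(dosages, variants)


class TestDefineLoci:
    def test_block_locus_spans_members(self, rng):
        panel = _block_panel(rng)
        table = _fake_table(np.array([6.0, 1.0, 1.0, 1.0, 0.5]))
        table["pos"] = panel.variants["pos"]
        table[["ref", "alt"]] = panel.variants[["ref", "alt"]]
        table["p_gc"] = table["p_raw"]
        loci = define_loci(table, panel, p_threshold=1e-5)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (1000, 3000)
        assert set(loci[0].member_ids) == {"v0", "v1", "v2"}

    def test_isolated_lead_single_position(self, rng):
        panel = _block_panel(rng)
        table = _fake_table(np.array([0.5, 1.0, 1.0, 1.0, 6.0]))
        table["pos"] = panel.variants["pos"]
        table["p_gc"] = table["p_raw"]
        loci = define_loci(table, panel, p_threshold=1e-5)
        assert len(loci) == 1
        assert loci[0].start == loci[0].end == 9_000_000

    def test_no_hits_empty(self, rng):
        panel = _block_panel(rng)
        table = _fake_table(np.ones(5))
        table["p_gc"] = table["p_raw"]
        assert define_loci(table, panel) == []

    def test_correlated_leads_absorbed_best_p_first(self, rng):
        panel = _block_panel(rng)
        table = _fake_table(np.array([6.0, 5.5, 1.0, 1.0, 0.5]))
        table["pos"] = panel.variants["pos"]
        table["p_gc"] = table["p_raw"]
        loci = define_loci(table, panel, p_threshold=1e-5)
        assert len(loci) == 1 and loci[0].lead_id == "v0"

    def test_lead_absent_from_panel_degenerates(self, rng):
        panel = _block_panel(rng)
        table = _fake_table(np.array([6.0]))
        table["pos"] = [777]
        table["p_gc"] = table["p_raw"]
        with pytest.warns(UserWarning, match="absent"):
            loci = define_loci(table, panel, p_threshold=1e-5)
        assert loci[0].start == loci[0].end == 777


class TestSingleTraitScan:
    def test_exact_linear_function_detected(self, small_genotypes):
        y = pd.Series(small_genotypes.dosages[:, 10] * 2.0 - 1.0)
        table = single_trait_scan(small_genotypes, y)
        hit = table.loc[table["p_raw"].idxmin()]
        assert hit["id"] == "var000010"
        assert hit["p_raw"] < 1e-200

    def test_null_pvalues_uniform(self, rng, small_genotypes):
        y = pd.Series(rng.standard_normal(small_genotypes.n_samples))
        table = single_trait_scan(small_genotypes, y)
        ks = stats.kstest(table["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_ols(self, rng, small_genotypes):
        import statsmodels.api as sm

        y = rng.standard_normal(small_genotypes.n_samples)
        cov = pd.DataFrame({"age": rng.uniform(20, 80, small_genotypes.n_samples)})
        table = single_trait_scan(small_genotypes, pd.Series(y), cov)
        j = 5
        X = sm.add_constant(
            np.column_stack([cov["age"], small_genotypes.dosages[:, j]])
        )
        fit = sm.OLS(y, X).fit()
        row = table[table["id"] == "var000005"].iloc[0]
        assert row["beta"] == pytest.approx(fit.params[2], rel=1e-8)
        assert row["p_raw"] == pytest.approx(fit.pvalues[2], rel=1e-6)


class TestRunScan:
    @pytest.fixture(scope="class")
    def causal_scan(self):
        cfg = SimulationConfig(
            n_samples=500, n_variants=120, ld_block_size=10, ld_rho=0.6,
            causal_variants=[(60, 0.45)], covariate_effects={}, seed=13,
        )
        geno = simulate_genotypes(cfg)
        cats, _ = simulate_category_scores(geno, cfg)
        table = run_scan(geno, cats)
        return geno, cats, table

    def test_causal_variant_attains_minimum_p(self, causal_scan):
        _, _, table = causal_scan
        assert table.loc[table["p_raw"].idxmin(), "id"] == "var000060"

    def test_deterministic(self, causal_scan):
        geno, cats, table = causal_scan
        again = run_scan(geno, cats)
        pd.testing.assert_frame_equal(table, again)

    def test_sorted_and_complete(self, causal_scan):
        geno, _, table = causal_scan
        assert (table["pos"].diff().dropna() > 0).all()
        assert len(table) + table.attrs["n_monomorphic"] == geno.n_variants

    def test_multitrait_beats_best_single_trait_on_latent_signal(self):
        # effect spread across all four categories: the latent-factor test
        # should usually dominate the best per-category OLS test
        from cvsem.sem import fit_variant_model

        rng = np.random.default_rng(55)
        wins = 0
        reps = 20
        n = 600  # well-powered regime: the ordering is asymptotic
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            zg = (g - g.mean()) / g.std()
            latent = 0.4 * zg + rng.standard_normal(n)
            cats = make_category_data(rng, n, latent=latent)
            multi_p = fit_variant_model(cats, g).effect("dosage")[3]
            single_ps = []
            for c in cats.columns:
                r = stats.linregress(g, cats[c])
                single_ps.append(r.pvalue)
            wins += multi_p <= min(single_ps)
        assert wins / reps >= 0.7


class TestExports:
    def test_single_row_table(self, tmp_path):
        table = _fake_table(np.array([2.0]))
        paths = export_plots_data(table, None, str(tmp_path / "x"), render=False)
        man = pd.read_csv(paths["manhattan"], sep="\t")
        assert len(man) == 1

    def test_thresholds_in_metadata(self, tmp_path):
        table = _fake_table(np.array([1.0, 2.0]))
        paths = export_plots_data(table, [], str(tmp_path / "x"), render=False)
        meta = json.loads(open(paths["meta"]).read())
        assert meta["genomewide_threshold"] == 5.0e-8
        assert meta["suggestive_threshold"] == 1.0e-5

    def test_qq_near_diagonal_for_uniform_p(self, rng, tmp_path):
        z = stats.norm.isf(rng.uniform(0, 1, 100) / 2)
        table = _fake_table(z)
        paths = export_plots_data(table, None, str(tmp_path / "u"), render=False)
        qq = pd.read_csv(paths["qq"], sep="\t")
        # KS band at alpha=0.01 for n=100 on the uniform scale
        dev = np.abs(
            10 ** -qq["observed_neglog10"] - 10 ** -qq["expected_neglog10"]
        )
        assert dev.max() < 1.63 / np.sqrt(100)

    def test_loci_table_round_trip(self, tmp_path):
        loci = [
            Locus("v1", "1", 100, 200, 1e-6, ["v1"], {"v1": 1.0}),
        ]
        frame = loci_table(loci)
        assert frame.iloc[0]["n_members"] == 1
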