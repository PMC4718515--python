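"""Measured-genotype association: HWE, QC, per-SNP tests, inflation factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from famvar.association import (
    genomic_lambda,
    hwe_exact_test,
    measured_genotype_test,
    qc_filter,
    run_gwas,
)
from famvar.pedigree import build_pedigree
from famvar.simulate import TraitModelSpec, simulate_genotypes, simulate_traits


def _hwe_brute(n_AA, n_Aa, n_aa):
    """Independent enumeration oracle for the exact HWE test."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hr = (rare - het) // 2
        hc = n - het - hr
        logp = (het * np.log(2) + gammaln(n + 1) - gammaln(het + 1)
                - gammaln(hr + 1) - gammaln(hc + 1))
        probs[het] = logp
    mx = max(probs.values())
    z = sum(np.exp(v - mx) for v in probs.values())
    norm = {k: np.exp(v - mx) / z for k, v in probs.items()}
    obs = norm[n_Aa]
    return min(1.0, sum(p for p in norm.values() if p <= obs * (1 + 1e-12)))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(120, 0, 0) == 1.0

    def test_strong_heterozygote_deficit(self):
        assert hwe_exact_test(57, 14, 50) < 1e-6

    @pytest.mark.parametrize(
        "counts",
        [(57, 14, 50), (10, 50, 40), (68, 28, 4), (0, 10, 90), (33, 33, 34),
         (1, 1, 1), (100, 0, 100)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_brute(*counts), rel=1e-10)

    def test_equilibrium_counts_not_rejected(self):
        # p=0.5, perfect HWE proportions
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def _founder_pedigree(n):
    return build_pedigree([
        dict(id=f"i{k}", family_id=f"F{k % 2}", father_id=None,
             mother_id=None, sex="1", household_id=f"h{k}")
        for k in range(n)
    ])


class TestQcFilter:
    def _geno(self, ped, cols):
        return pd.DataFrame(cols, index=ped.ids)

    def test_low_maf_excluded(self):
        ped = _founder_pedigree(1000)
        rng = np.random.default_rng(0)
        g = self._geno(ped, {
            "rare": rng.binomial(2, 0.005, 1000).astype(float),
            "common": rng.binomial(2, 0.3, 1000).astype(float),
        })
        passed, flags = qc_filter(g, ped)
        assert "rare" not in passed.columns
        assert "common" in passed.columns
        assert flags.loc["rare", "maf_fail"]

    def test_low_info_excluded(self):
        ped = _founder_pedigree(500)
        rng = np.random.default_rng(1)
        g = self._geno(ped, {
            "a": rng.binomial(2, 0.3, 500).astype(float),
            "b": rng.binomial(2, 0.3, 500).astype(float),
        })
        info = pd.Series({"a": 0.2, "b": 0.9})
        passed, flags = qc_filter(g, ped, info=info)
        assert list(passed.columns) == ["b"]
        assert flags.loc["a", "info_fail"]

    def test_hwe_and_callrate(self):
        ped = _founder_pedigree(300)
        rng = np.random.default_rng(2)
        bad_hwe = np.repeat([0.0, 2.0], 150)  # no heterozygotes at p=0.5
        sparse = rng.binomial(2, 0.3, 300).astype(float)
        sparse[:30] = np.nan  # 90% call rate
        g = self._geno(ped, {"bad_hwe": bad_hwe, "sparse": sparse})
        passed, flags = qc_filter(g, ped)
        assert flags.loc["bad_hwe", "hwe_fail"]
        assert flags.loc["sparse", "callrate_fail"]
        assert passed.shape[1] == 0

    def test_all_filters_disabled_is_identity(self):
        ped = _founder_pedigree(100)
        rng = np.random.default_rng(3)
        g = self._geno(ped, {"s": rng.binomial(2, 0.01, 100).astype(float)})
        passed, flags = qc_filter(g, ped, maf_min=None, callrate_min=None,
                                  hwe_p_min=None, info_min=None)
        assert list(passed.columns) == ["s"]


class TestMeasuredGenotypeTest:
    def test_founders_reduce_to_ols(self):
        """With 2Phi = H = I the mixed-model test equals OLS regression."""
        ped = _founder_pedigree(500)
        rng = np.random.default_rng(4)
        g = pd.Series(rng.binomial(2, 0.3, 500).astype(float), index=ped.ids,
                      name="snp")
        y = pd.Series(0.4 * g + rng.normal(size=500), index=ped.ids)
        res = measured_genotype_test(ped, y, g)
        X = np.column_stack([np.ones(500), g])
        beta, rss1, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        s2 = np.sum((y.to_numpy() - X @ beta) ** 2)
        assert res.beta == pytest.approx(beta[1], abs=1e-6)
        # a strong simulated effect is decisively detected
        assert res.p < 1e-6

    def test_power_at_large_effect(self, small_study):
        ped, kin = small_study
        spec = TraitModelSpec(traits=("y",), h2=(0.4,), c2=(0.0,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=30, kin=kin)["y"]
        g, y2 = simulate_genotypes(ped, maf=0.2, n_snps=1, seed=31,
                                   effect_size=1.0, trait=y)
        res = measured_genotype_test(ped, y2, g["snp1"], kin=kin)
        assert res.p < 5e-8
        assert res.significance == "genome-wide"
        assert res.beta == pytest.approx(1.0, abs=0.3)

    def test_conditioning_on_causal_removes_signal(self, small_study):
        ped, kin = small_study
        spec = TraitModelSpec(traits=("y",), h2=(0.4,), c2=(0.0,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=32, kin=kin)["y"]
        g, y2 = simulate_genotypes(ped, maf=0.2, n_snps=1, seed=33,
                                   effect_size=1.0, trait=y)
        res = measured_genotype_test(ped, y2, g["snp1"], kin=kin,
                                     condition_on=g["snp1"])
        assert res.p > 1e-3

    def test_refit_matches_profile_on_null_snp(self, small_study):
        ped, kin = small_study
        spec = TraitModelSpec(traits=("y",), h2=(0.5,), c2=(0.1,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=34, kin=kin)["y"]
        g = simulate_genotypes(ped, maf=0.3, n_snps=1, seed=35)
        fast = measured_genotype_test(ped, y, g["snp1"], kin=kin)
        slow = measured_genotype_test(ped, y, g["snp1"], kin=kin, refit=True)
        assert fast.beta == pytest.approx(slow.beta, abs=0.02)
        assert np.log10(fast.p) == pytest.approx(np.log10(slow.p), abs=0.5)

    def test_monomorphic_skipped(self):
        ped = _founder_pedigree(50)
        g = pd.Series(0.0, index=ped.ids, name="mono")
        y = pd.Series(np.random.default_rng(6).normal(size=50), index=ped.ids)
        res = measured_genotype_test(ped, y, g)
        assert res.flags["monomorphic"]
        assert np.isnan(res.p)


class TestGenomicLambda:
    def test_theoretical_quantiles_give_unity(self):
        q = np.linspace(0.001, 0.999, 999)
        assert genomic_lambda(chi2_stats=stats.chi2.ppf(q, 1)) == pytest.approx(
            1.0, abs=1e-6)

    def test_scale_equivariance(self):
        q = np.linspace(0.001, 0.999, 999)
        c = stats.chi2.ppf(q, 1)
        assert genomic_lambda(chi2_stats=2 * c) == pytest.approx(2.0, abs=1e-6)

    def test_p_value_route(self):
        q = np.linspace(0.001, 0.999, 999)
        c = stats.chi2.ppf(q, 1)
        p = stats.chi2.sf(c, 1)
        assert genomic_lambda(p_values=p) == pytest.approx(1.0, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda(p_values=[])


class TestRunGwas:
    def test_empty_genotypes(self, small_study):
        ped, kin = small_study
        y = pd.Series(np.random.default_rng(7).normal(size=len(ped)),
                      index=ped.ids)
        res, summary = run_gwas(ped, y, pd.DataFrame(index=ped.ids), kin=kin)
        assert res.empty
        assert not summary["lambda_defined"]

    def test_spike_in_detected(self, small_study):
        ped, kin = small_study
        spec = TraitModelSpec(traits=("y",), h2=(0.4,), c2=(0.0,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=40, kin=kin)["y"]
        g = simulate_genotypes(ped, maf=0.25, n_snps=200, seed=41)
        y2 = y + 1.2 * g["snp7"]
        res, summary = run_gwas(ped, y2, g, qc=False, kin=kin)
        hits = set(res.loc[res["significance"] == "genome-wide", "snp"])
        assert hits == {"snp7"}

    def test_deterministic_rerun(self, small_study):
        ped, kin = small_study
        spec = TraitModelSpec(traits=("y",), h2=(0.3,), c2=(0.0,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=42, kin=kin)["y"]
        g = simulate_genotypes(ped, maf=0.2, n_snps=50, seed=43)
        r1, s1 = run_gwas(ped, y, g, kin=kin)
        r2, s2 = run_gwas(ped, y, g, kin=kin)
        pd.testing.assert_frame_equal(r1, r2)
        assert s1 == s2

    def test_qc_flags_independent_of_trait(self, small_study):
        ped, kin = small_study
        g = simulate_genotypes(ped, maf=0.1, n_snps=30, seed=44)
        _, f1 = qc_filter(g, ped)
        _, f2 = qc_filter(g, ped)  # flags never see a trait at all
        pd.testing.assert_frame_equal(f1, f2)
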