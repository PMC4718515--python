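"""Synthetic family-study generator: structure, traits, disease, genotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from famvar.pedigree import build_pedigree, classify_pairs, kinship_matrix
from famvar.simulate import (
    TraitModelSpec,
    ascertain_families,
    generate_pedigree,
    simulate_binary_trait,
    simulate_covariates,
    simulate_genotypes,
    simulate_traits,
)


def _sib_pair_pedigree(n_pairs):
    """Many independent nuclear families, one sibling pair each."""
    rows = []
    for k in range(n_pairs):
        f = f"F{k}"
        rows += [
            dict(id=f"d{k}", family_id=f, father_id=None, mother_id=None,
                 sex="1", household_id=None),
            dict(id=f"m{k}", family_id=f, father_id=None, mother_id=None,
                 sex="2", household_id=None),
            dict(id=f"a{k}", family_id=f, father_id=f"d{k}", mother_id=f"m{k}",
                 sex="1", household_id=None),
            dict(id=f"b{k}", family_id=f, father_id=f"d{k}", mother_id=f"m{k}",
                 sex="2", household_id=None),
        ]
    return build_pedigree(rows)


class TestGeneratePedigree:
    def test_deterministic_under_seed(self):
        p1 = generate_pedigree(n_families=4, seed=7)
        p2 = generate_pedigree(n_families=4, seed=7)
        pd.testing.assert_frame_equal(p1.to_frame(), p2.to_frame())

    def test_study_constraints(self):
        ped = generate_pedigree(n_families=35, min_family_size=10,
                                n_generations=3, seed=2)
        assert len(ped.families) == 35
        depth = ped.generation_depth()
        for fam, members in ped.families.items():
            assert len(members) >= 10
            assert max(depth[m] for m in members) >= 2  # >= 3 generations

    def test_relative_classes_populated(self):
        ped = generate_pedigree(n_families=4, seed=3)
        tab = classify_pairs(kinship_matrix(ped), ped)
        by_phi = tab.groupby("2phi")["n_pairs"].sum()
        for phi in (0.5, 0.25, 0.125):
            assert by_phi.get(phi, 0) > 0

    def test_unattainable_constraints(self):
        with pytest.raises(ValueError):
            generate_pedigree(n_families=1, min_family_size=10, n_generations=1)

    def test_households_follow_nuclear_units(self):
        ped = generate_pedigree(n_families=2, seed=1)
        for ind in ped.individuals:
            if not ind.is_founder:
                # every child shares a household with at least one parent,
                # unless it married out and founded its own
                parents_hh = {ped[ind.father_id].household_id,
                              ped[ind.mother_id].household_id}
                kids = ped.children_of(ind.id)
                assert ind.household_id in parents_hh or kids


class TestSimulateTraits:
    def test_pure_noise_siblings_uncorrelated(self):
        ped = _sib_pair_pedigree(4000)
        spec = TraitModelSpec(traits=("y",), h2=(0.0,), c2=(0.0,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=1)["y"]
        a = y[[f"a{k}" for k in range(4000)]].to_numpy()
        b = y[[f"b{k}" for k in range(4000)]].to_numpy()
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.05

    def test_sibling_covariance_closed_form(self):
        """cov(sibs) = 2Phi_sib/2 * sigma2_g = 0.25 * total for h2=0.5."""
        ped = _sib_pair_pedigree(8000)
        spec = TraitModelSpec(traits=("y",), h2=(0.5,), c2=(0.0,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=2)["y"]
        a = y[[f"a{k}" for k in range(8000)]].to_numpy()
        b = y[[f"b{k}" for k in range(8000)]].to_numpy()
        cov = np.cov(a, b)[0, 1]
        assert cov == pytest.approx(0.25, abs=0.03)

    def test_household_component_shared(self):
        ped = build_pedigree([
            dict(id=f"i{k}", family_id="F", father_id=None, mother_id=None,
                 sex="1" if k % 2 else "2", household_id="hh" if k < 50 else f"s{k}")
            for k in range(100)
        ])
        spec = TraitModelSpec(traits=("y",), h2=(0.0,), c2=(0.6,),
                              mean=(0.0,), total_var=(1.0,))
        reps = []
        for s in range(600):
            y = simulate_traits(ped, spec, seed=s)["y"]
            reps.append(y.iloc[:50].to_numpy())
        R = np.array(reps)
        # members of one household share the same realized common effect;
        # average over many replicates and several member pairs
        C = np.cov(R[:, :6].T)
        covs = C[np.triu_indices(6, 1)].mean()
        assert covs == pytest.approx(0.6, abs=0.10)

    def test_covariate_effect_recovered_by_regression(self):
        """Single-covariate regression on unrelated individuals recovers the
        oral-contraceptive effect used in generation (0.87)."""
        # independent singleton families: block sampling stays O(n)
        ped = build_pedigree([
            dict(id=f"i{k}", family_id=f"F{k}", father_id=None,
                 mother_id=None, sex="2", household_id=None)
            for k in range(20000)
        ])
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"oc": rng.binomial(1, 0.3, 20000)},
                           index=ped.ids, dtype=float)
        spec = TraitModelSpec(traits=("ETP",), h2=(0.0,), c2=(0.0,),
                              mean=(48.53,), total_var=(1.0,),
                              beta={"ETP": {"oc": 0.87}})
        y = simulate_traits(ped, spec, covariates=cov, seed=4)["ETP"]
        slope = np.polyfit(cov["oc"], y, 1)[0]
        assert slope == pytest.approx(0.87, abs=0.05)

    def test_raw_scale_positive(self):
        ped = _sib_pair_pedigree(10)
        spec = TraitModelSpec(traits=("y",), h2=(0.3,), c2=(0.0,),
                              mean=(1.0,), total_var=(0.2,))
        raw = simulate_traits(ped, spec, seed=5, raw_scale=True)["y"]
        assert (raw > 0).all()
        back = np.log(raw)
        assert back.std() < 2.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TraitModelSpec(traits=("y",), h2=(0.8,), c2=(0.4,),
                           mean=(0.0,), total_var=(1.0,))
        with pytest.raises(ValueError):
            TraitModelSpec(traits=("a", "b"), h2=(0.5, 0.5), c2=(0.0, 0.0),
                           mean=(0.0, 0.0), total_var=(1.0, 1.0), rho_g=1.5)


class TestSimulateBinaryTrait:
    def test_half_prevalence_threshold_zero(self):
        ped = _sib_pair_pedigree(2000)
        b = simulate_binary_trait(ped, h2=0.3, prevalence=0.5, seed=1)
        assert b["affected"].mean() == pytest.approx(0.5, abs=0.03)

    def test_no_heritability_no_familial_clustering(self):
        ped = _sib_pair_pedigree(6000)
        b = simulate_binary_trait(ped, h2=0.0, prevalence=0.1, seed=2)
        a = b["affected"][[f"a{k}" for k in range(6000)]].to_numpy()
        s = b["affected"][[f"b{k}" for k in range(6000)]].to_numpy()
        # sibling relative risk ~ 1
        rr = a[s == 1].mean() / max(a.mean(), 1e-9)
        assert rr == pytest.approx(1.0, abs=0.25)

    def test_sibling_recurrence_matches_orthant_probability(self):
        """Joint sib affection equals the bivariate-normal orthant probability
        with liability correlation h2/2 = 0.335 (independent 1-D integrator)."""
        K, h2 = 0.1, 0.67
        z = stats.norm.ppf(1 - K)
        rho = h2 / 2
        orthant, _ = integrate.quad(
            lambda x: stats.norm.pdf(x)
            * stats.norm.sf((z - rho * x) / np.sqrt(1 - rho**2)),
            z, np.inf,
        )
        ped = _sib_pair_pedigree(8000)
        b = simulate_binary_trait(ped, h2=h2, prevalence=K, seed=3)
        a = b["affected"][[f"a{k}" for k in range(8000)]].to_numpy()
        s = b["affected"][[f"b{k}" for k in range(8000)]].to_numpy()
        joint = np.mean(a * s)
        assert joint > K * K  # clustering present
        assert joint == pytest.approx(orthant, abs=0.01)

    def test_onset_only_for_affected(self):
        ped = _sib_pair_pedigree(100)
        b = simulate_binary_trait(ped, h2=0.5, prevalence=0.2, seed=4)
        assert b.loc[b.affected == 1, "onset_age"].notna().all()
        assert b.loc[b.affected == 0, "onset_age"].isna().all()

    def test_bad_prevalence(self):
        ped = _sib_pair_pedigree(5)
        with pytest.raises(ValueError):
            simulate_binary_trait(ped, h2=0.5, prevalence=1.5)


class TestAscertainment:
    def _toy(self):
        rows = []
        for fam, oa in (("F1", 40.0), ("F2", 60.0)):
            rows += [
                dict(id=f"{fam}d", family_id=fam, father_id=None,
                     mother_id=None, sex="1"),
                dict(id=f"{fam}m", family_id=fam, father_id=None,
                     mother_id=None, sex="2"),
                dict(id=f"{fam}k", family_id=fam, father_id=f"{fam}d",
                     mother_id=f"{fam}m", sex="1"),
            ]
        ped = build_pedigree(rows)
        phen = pd.DataFrame(
            {"affected": [0, 0, 1, 0, 0, 1],
             "onset_age": [np.nan, np.nan, 40.0, np.nan, np.nan, 60.0]},
            index=["F1d", "F1m", "F1k", "F2d", "F2m", "F2k"],
        )
        return ped, phen

    def test_rule_application(self):
        ped, phen = self._toy()
        kept, probands = ascertain_families(ped, phen)
        assert set(kept.families) == {"F1"}  # onset 40 < 45 qualifies
        assert probands == {"F1": "F1k"}
        assert kept["F1k"].proband

    def test_affected_relative_qualifies_late_onset(self):
        ped, phen = self._toy()
        phen.loc["F2d", ["affected", "onset_age"]] = [1, 55.0]
        kept, probands = ascertain_families(ped, phen)
        # F2 now has two affected first-degree relatives; earliest onset wins
        assert set(kept.families) == {"F1", "F2"}
        assert probands["F2"] == "F2d"

    def test_no_affected_gives_empty(self):
        ped, phen = self._toy()
        phen["affected"] = 0
        with pytest.warns(UserWarning):
            kept, probands = ascertain_families(ped, phen)
        assert len(kept) == 0 and probands == {}

    def test_all_families_qualify(self):
        ped, phen = self._toy()
        phen.loc["F2k", "onset_age"] = 30.0
        kept, probands = ascertain_families(ped, phen)
        assert set(kept.families) == {"F1", "F2"}
        assert sum(1 for i in kept.individuals if i.proband) == 2

    def test_ascertained_prevalence_inflated(self):
        ped = generate_pedigree(n_families=30, extra_generation_prob=0.0,
                                seed=8)
        phen = simulate_binary_trait(ped, h2=0.67, prevalence=0.10, seed=9)
        kept, _ = ascertain_families(ped, phen)
        assert len(kept.families) >= 1
        assert phen["affected"].loc[kept.ids].mean() > 0.10


class TestSimulateGenotypes:
    def test_mendelian_consistency_exhaustive(self):
        ped = generate_pedigree(n_families=3, seed=5)
        g = simulate_genotypes(ped, maf=0.3, n_snps=40, seed=6)
        for ind in ped.individuals:
            if ind.is_founder:
                continue
            child = g.loc[ind.id]
            f, m = g.loc[ind.father_id], g.loc[ind.mother_id]
            # allele counts compatible: child in [lo, hi] given parents
            lo = (f > 1).astype(int) + (m > 1).astype(int)
            hi = 2 - ((f < 1).astype(int) + (m < 1).astype(int))
            assert ((child >= lo) & (child <= hi)).all()

    def test_founder_allele_frequency(self):
        ped = build_pedigree([
            dict(id=f"i{k}", family_id="F", father_id=None, mother_id=None,
                 sex="1") for k in range(10000)
        ])
        g = simulate_genotypes(ped, maf=0.2, n_snps=1, seed=7)
        assert g["snp1"].mean() / 2 == pytest.approx(0.2, abs=0.01)

    def test_effect_recovered_by_regression(self):
        ped = build_pedigree([
            dict(id=f"i{k}", family_id="F", father_id=None, mother_id=None,
                 sex="1") for k in range(5000)
        ])
        rng = np.random.default_rng(8)
        base = pd.Series(rng.normal(size=5000), index=ped.ids)
        g, shifted = simulate_genotypes(ped, maf=0.25, n_snps=1, seed=9,
                                        effect_size=0.5, trait=base)
        slope = np.polyfit(g["snp1"], shifted, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_deterministic(self):
        ped = generate_pedigree(n_families=2, seed=10)
        g1 = simulate_genotypes(ped, maf=0.1, n_snps=5, seed=11)
        g2 = simulate_genotypes(ped, maf=0.1, n_snps=5, seed=11)
        pd.testing.assert_frame_equal(g1, g2)


class TestCovariates:
    def test_structure_and_ranges(self):
        ped = generate_pedigree(n_families=10, seed=12)
        cov = simulate_covariates(ped, seed=13)
        assert cov["age"].between(2, 101).all()
        assert set(cov["female"].unique()) <= {0, 1}
        # oral contraceptives only in women of reproductive age
        oc = cov[cov["oc"] == 1]
        assert (oc["female"] == 1).all()
        assert oc["age"].between(18, 50).all()
        # founders of the founding generation are older than their grandchildren
        depth = ped.generation_depth()
        top = [i for i in ped.ids if depth[i] == 0]
        bottom = [i for i in ped.ids if depth[i] >= 2]
        assert cov.loc[top, "age"].mean() > cov.loc[bottom, "age"].mean() + 20

    def test_relative_pair_trait_covariance_by_class(self):
        """Empirical covariance between 0.25-class relatives approaches
        0.25 * sigma2_g (no shared household)."""
        rows = []
        for k in range(4000):  # grandparent-grandchild chains
            f = f"F{k}"
            rows += [
                dict(id=f"g{k}", family_id=f, father_id=None, mother_id=None, sex="1"),
                dict(id=f"gm{k}", family_id=f, father_id=None, mother_id=None, sex="2"),
                dict(id=f"p{k}", family_id=f, father_id=f"g{k}", mother_id=f"gm{k}", sex="1"),
                dict(id=f"pm{k}", family_id=f, father_id=None, mother_id=None, sex="2"),
                dict(id=f"c{k}", family_id=f, father_id=f"p{k}", mother_id=f"pm{k}", sex="1"),
            ]
        ped = build_pedigree(rows)
        spec = TraitModelSpec(traits=("y",), h2=(0.6,), c2=(0.0,),
                              mean=(0.0,), total_var=(1.0,))
        y = simulate_traits(ped, spec, seed=14)["y"]
        g = y[[f"g{k}" for k in range(4000)]].to_numpy()
        c = y[[f"c{k}" for k in range(4000)]].to_numpy()
        assert np.cov(g, c)[0, 1] == pytest.approx(0.25 * 0.6, abs=0.04)
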