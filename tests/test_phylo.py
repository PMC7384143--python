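import numpy as np
import pandas as pd
import pytest

from leafprod.phylo import (Phylogeny, blomberg_k, blomberg_k_test,
                            cell_mean_clade_age, age_interaction_model)
from leafprod.synthetic import SyntheticScenario, make_phylogeny

FIVE_TAXON = "((A:1,B:1):2,((C:0.5,D:0.5):1.5,E:2):1);"
FIVE_TRAITS = pd.Series({"A": 2.0, "B": 3.5, "C": 1.0, "D": 1.2, "E": 5.0})
# Blomberg's K for this tree/trait pair, frozen from an independent
# phylogenetics implementation (R phytools::phylosig)
FIVE_TAXON_K = 0.953565935001


def star_tree(n=8):
    return Phylogeny.from_newick(
        "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");")


class TestBlombergK:
    def test_matches_independent_reference_value(self):
        ph = Phylogeny.from_newick(FIVE_TAXON)
        assert blomberg_k(ph, FIVE_TRAITS).k == pytest.approx(
            FIVE_TAXON_K, abs=1e-9)

    def test_star_tree_gives_exactly_one(self, rng):
        ph = star_tree()
        tr = pd.Series(rng.standard_normal(8), index=ph.taxa)
        assert blomberg_k(ph, tr).k == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        ph = Phylogeny.from_newick(FIVE_TAXON)
        k0 = blomberg_k(ph, FIVE_TRAITS).k
        k1 = blomberg_k(ph, 7.3 * FIVE_TRAITS - 2.0).k
        assert k1 == pytest.approx(k0, rel=1e-12)

    def test_tip_order_invariance(self):
        ph = Phylogeny.from_newick(FIVE_TAXON)
        shuffled = FIVE_TRAITS.sample(frac=1.0, random_state=1)
        assert blomberg_k(ph, shuffled).k == pytest.approx(
            FIVE_TAXON_K, abs=1e-9)

    def test_unmatched_tips_pruned_with_flag(self):
        ph = Phylogeny.from_newick(FIVE_TAXON)
        res = blomberg_k(ph, FIVE_TRAITS.drop("E"))
        assert res.flags["n_pruned"] == 1 and res.n == 4

    def test_too_few_taxa_rejected(self):
        ph = Phylogeny.from_newick(FIVE_TAXON)
        with pytest.raises(ValueError):
            blomberg_k(ph, FIVE_TRAITS.iloc[:2])

    def test_brownian_expectation_near_one(self):
        sc = SyntheticScenario(signal_weight=1.0)
        ks = [blomberg_k(*make_phylogeny(sc, seed=3000 + i, n_tips=100)).k
              for i in range(60)]
        assert 0.8 < np.mean(ks) < 1.2

    def test_white_noise_has_little_signal(self):
        sc = SyntheticScenario(signal_weight=0.0)
        ks = [blomberg_k(*make_phylogeny(sc, seed=4000 + i, n_tips=100)).k
              for i in range(30)]
        assert np.median(ks) < 0.5


class TestBlombergKTest:
    def test_deterministic_under_seed(self):
        ph, tr = make_phylogeny(SyntheticScenario(), seed=11, n_tips=50)
        a = blomberg_k_test(ph, tr, n_perm=199, seed=5)
        b = blomberg_k_test(ph, tr, n_perm=199, seed=5)
        assert a.p == b.p and a.k == b.k

    def test_strong_signal_detected(self):
        sc = SyntheticScenario(signal_weight=1.0)
        hits = 0
        for i in range(20):
            ph, tr = make_phylogeny(sc, seed=5000 + i, n_tips=100)
            if blomberg_k_test(ph, tr, n_perm=199, seed=i).p <= 0.05:
                hits += 1
        assert hits >= 18

    def test_small_permutation_count_warns(self):
        ph, tr = make_phylogeny(SyntheticScenario(), seed=12, n_tips=20)
        with pytest.warns(UserWarning):
            blomberg_k_test(ph, tr, n_perm=49, seed=0)


class TestCladeAges:
    def _presence(self):
        return pd.DataFrame(
            [[True, True, False], [False, False, True],
             [True, True, True], [False, False, False]],
            index=pd.Index(range(4), name="cell_id"),
            columns=["s1", "s2", "s3"])

    def test_two_family_mean(self):
        ages = cell_mean_clade_age(
            self._presence(),
            {"s1": "famA", "s2": "famB", "s3": "famB"},
            {"famA": 100.0, "famB": 60.0})
        assert ages.loc[0] == pytest.approx(80.0)

    def test_congeners_each_contribute_genus_age(self):
        ages = cell_mean_clade_age(
            self._presence(), {s: "genX" for s in ("s1", "s2", "s3")},
            {"genX": 40.0})
        assert ages.loc[2] == pytest.approx(40.0)

    def test_empty_cell_missing_and_bounds(self):
        ages = cell_mean_clade_age(
            self._presence(),
            {"s1": "famA", "s2": "famB", "s3": "famB"},
            {"famA": 100.0, "famB": 60.0})
        assert np.isnan(ages.loc[3])
        assert ages.dropna().between(60.0, 100.0).all()


class TestAgeInteraction:
    def test_null_interaction_not_detected(self, rng):
        hits = 0
        for i in range(50):
            r = np.random.default_rng(i)
            ls = r.standard_normal(400)
            age = r.standard_normal(400)
            y = ls + 0.3 * age + r.standard_normal(400)
            tab = age_interaction_model(y, ls, age)
            hits += abs(tab.loc["leaf_size:clade_age", "t"]) < 2
        assert hits >= 45

    def test_negative_interaction_sign_recovered(self):
        hits = 0
        for i in range(30):
            r = np.random.default_rng(100 + i)
            ls = r.standard_normal(1000)
            age = r.standard_normal(1000)
            y = ls + 0.3 * age - 0.2 * ls * age + r.standard_normal(1000)
            tab = age_interaction_model(y, ls, age)
            hits += tab.loc["leaf_size:clade_age", "coef"] < 0
        assert hits >= 29

    def test_constant_age_errors(self, rng):
        with pytest.raises(ValueError):
            age_interaction_model(rng.normal(size=50), rng.normal(size=50),
                                  np.ones(50))
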