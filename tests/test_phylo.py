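import dendropy
import numpy as np
import pandas as pd
import pytest

from microstab import phylo, synthetic


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")


class TestLog2FoldResponse:
    @staticmethod
    def _table():
        rng = np.random.default_rng(5)
        counts = rng.integers(5, 200, size=(6, 8))
        table = pd.DataFrame(
            counts, index=[f"t{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(8)],
        )
        meta = pd.Series(
            ["ref"] * 4 + ["trt"] * 4, index=table.columns
        )
        return table, meta

    def test_identical_groups_give_zero_ratio(self):
        table, _ = self._table()
        doubled = pd.concat([table, table], axis=1)
        doubled.columns = [f"s{j}" for j in range(16)]
        meta = pd.Series(["ref"] * 8 + ["trt"] * 8, index=doubled.columns)
        out = phylo.log2_fold_response(doubled, meta, "ref", "trt")
        assert np.allclose(out["log2_fold_ratio"], 0.0, atol=1e-12)

    def test_doubled_treatment_gives_ratio_one(self):
        rng = np.random.default_rng(0)
        base = rng.integers(500, 2000, size=6)
        ref = np.tile(base, (4, 1)).T
        trt = 2 * ref
        table = pd.DataFrame(
            np.hstack([ref, trt]), index=[f"t{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(8)],
        )
        meta = pd.Series(["ref"] * 4 + ["trt"] * 4, index=table.columns)
        out = phylo.log2_fold_response(table, meta, "ref", "trt")
        # size factors absorb the uniform doubling -> ratio ~ 0 ... unless a
        # taxon deviates; uniform doubling IS a library-size effect
        assert np.allclose(out["log2_fold_ratio"], 0.0, atol=1e-6)

    def test_matches_hand_computed_median_of_ratios_pipeline(self):
        table, meta = self._table()
        out = phylo.log2_fold_response(table, meta, "ref", "trt", pseudocount=0.5)
        logc = np.log(table.to_numpy(dtype=float))
        sf = np.exp(np.median(logc - logc.mean(axis=1, keepdims=True), axis=0))
        norm = table.to_numpy() / sf
        mean_ref = norm[:, :4].mean(axis=1)
        mean_trt = norm[:, 4:].mean(axis=1)
        expected = np.log2((mean_trt + 0.5) / (mean_ref + 0.5))
        assert np.allclose(out["log2_fold_ratio"], expected, atol=1e-10)
        assert (out["direction"] == np.where(expected > 0, "positive", "negative")).all()

    def test_small_group_errors(self):
        table, meta = self._table()
        with pytest.raises(ValueError):
            phylo.log2_fold_response(table, meta.iloc[:5], "ref", "trt")


class TestConsenTrait:
    def test_symmetric_tree_single_clade_depth_one(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        trait = pd.Series({"A": 1, "B": 1, "C": 0, "D": 0})
        res = phylo.consentrait(tree, trait, permutations=50, seed=0)
        assert res.tau_d == pytest.approx(1.0)
        assert len(res.clades) == 1
        assert res.clades.iloc[0]["size"] == 2

    def test_trait_on_all_leaves_uses_root_depth(self):
        tree = _tree("((A:1,B:1):1,(C:2,D:2):1);")
        trait = pd.Series({"A": 1, "B": 1, "C": 1, "D": 1})
        res = phylo.consentrait(tree, trait, permutations=10, seed=0)
        assert res.tau_d == pytest.approx((2 + 2 + 3 + 3) / 4)

    def test_singleton_contributes_half_terminal_branch(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:3):1);")
        trait = pd.Series({"A": 1, "B": 1, "C": 0, "D": 1})
        res = phylo.consentrait(tree, trait, permutations=10, seed=0)
        assert res.tau_d == pytest.approx((1.0 + 1.5) / 2)
        excl = phylo.consentrait(
            tree, trait, permutations=10, seed=0, include_singletons=False
        )
        assert excl.tau_d == pytest.approx(1.0)

    def test_maximal_clade_rule_prevents_double_counting(self):
        tree = _tree("(((A:1,B:1):1,C:2):1,(D:1,E:1):2);")
        trait = pd.Series({"A": 1, "B": 1, "C": 1, "D": 0, "E": 0})
        res = phylo.consentrait(tree, trait, permutations=10, seed=0)
        assert len(res.clades) == 1  # only the outermost qualifying clade

    def test_errors(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            phylo.consentrait(tree, pd.Series({"A": 0, "B": 0, "C": 0, "D": 0}))
        with pytest.raises(ValueError):
            phylo.consentrait(tree, pd.Series({"A": 1, "B": 1, "X": 0, "D": 0}))

    def test_conserved_traits_detected_on_simulated_trees(self):
        hits = 0
        for seed in range(20):
            tree, traits = synthetic.simulate_tree_and_traits(
                synthetic.TraitScenario(
                    n_leaves=64, trait_mode="clade_conserved", seed=seed
                )
            )
            res = phylo.consentrait(tree, traits["trait"], permutations=99, seed=seed)
            hits += res.p_value < 0.05
        assert hits >= 18


class TestConsenTraitEnsemble:
    def test_degenerate_ensemble_equals_single_tree(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        trait = pd.Series({"A": 1, "B": 1, "C": 0, "D": 0})
        single = phylo.consentrait(tree, trait, permutations=30, seed=0)
        trees = [_tree("((A:1,B:1):1,(C:1,D:1):1);") for _ in range(3)]
        ens = phylo.consentrait_ensemble(trees, trait, permutations_per_tree=10, seed=0)
        assert ens.tau_d == pytest.approx(single.tau_d)
        assert ens.n_permutations == 30

    def test_branch_length_scaling_is_linear(self):
        t1 = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = _tree("((A:3,B:3):3,(C:3,D:3):3);")
        trait = pd.Series({"A": 1, "B": 1, "C": 0, "D": 0})
        r1 = phylo.consentrait(t1, trait, permutations=10, seed=0)
        r2 = phylo.consentrait(t2, trait, permutations=10, seed=0)
        assert r2.tau_d == pytest.approx(3 * r1.tau_d)

    def test_mismatched_leaf_sets_error(self):
        trees = [
            _tree("((A:1,B:1):1,(C:1,D:1):1);"),
            _tree("((A:1,B:1):1,(C:1,E:1):1);"),
        ]
        trait = pd.Series({"A": 1, "B": 1, "C": 0, "D": 0})
        with pytest.raises(ValueError):
            phylo.consentrait_ensemble(trees, trait)


class TestMantelCorrelogram:
    @staticmethod
    def _data(seed=0, n=32):
        tree, traits = synthetic.simulate_tree_and_traits(
            synthetic.TraitScenario(n_leaves=n, trait_mode="random", seed=seed)
        )
        dist = phylo.cophenetic_distances(tree)
        mag = traits["response"].abs().reindex(dist.index).to_numpy()
        diff = pd.DataFrame(
            np.abs(mag[:, None] - mag[None, :]), index=dist.index, columns=dist.columns
        )
        return dist, diff

    def test_statistics_bounded_and_classes_partition_range(self):
        dist, diff = self._data()
        gram = phylo.mantel_correlogram(dist, diff, permutations=49, seed=1)
        c = gram.classes
        valid = c.dropna(subset=["r"])
        assert ((valid["r"] >= -1) & (valid["r"] <= 1)).all()
        assert c["n_pairs"].sum() == (len(dist) * (len(dist) - 1)) // 2
        assert (valid["p_adj"] >= valid["p_raw"] - 1e-12).all()

    def test_joint_relabeling_invariance(self, rng):
        dist, diff = self._data(seed=3)
        perm = rng.permutation(len(dist))
        dist_p = dist.iloc[perm, perm]
        diff_p = diff.iloc[perm, perm]
        g1 = phylo.mantel_correlogram(dist, diff, permutations=29, seed=5)
        g2 = phylo.mantel_correlogram(dist_p, diff_p, permutations=29, seed=5)
        assert np.allclose(
            g1.classes["r"].dropna(), g2.classes["r"].dropna(), atol=1e-12
        )

    def test_brownian_signal_negative_in_shortest_class(self):
        hits = 0
        for seed in range(10):
            tree, traits = synthetic.simulate_tree_and_traits(
                synthetic.TraitScenario(n_leaves=96, trait_mode="random", seed=seed)
            )
            dist = phylo.cophenetic_distances(tree)
            mag = traits["response"].reindex(dist.index).to_numpy()
            diff = pd.DataFrame(
                np.abs(mag[:, None] - mag[None, :]),
                index=dist.index, columns=dist.columns,
            )
            gram = phylo.mantel_correlogram(dist, diff, permutations=99, seed=seed)
            first = gram.classes.dropna(subset=["r"]).iloc[0]
            hits += (first["r"] < 0) and (first["p_raw"] < 0.05)
        assert hits >= 7

    def test_constant_response_errors(self):
        dist, diff = self._data()
        with pytest.raises(ValueError):
            phylo.mantel_correlogram(dist, diff * 0.0, permutations=9, seed=0)
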