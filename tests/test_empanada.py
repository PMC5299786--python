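import numpy as np
import pandas as pd
import pytest

import funcvar as fv
from funcvar.empanada import EligibilityFilter
from funcvar.profiles_io import FuncvarError
from oracles import naive_map_to_pathways, random_mapping_instance

OPEN = EligibilityFilter(min_nonshared=0, min_mean_rel_abundance=0.0)


def _profile(rows, genes, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    return fv.GeneProfile(pd.DataFrame(rows, index=samples, columns=genes))


@pytest.fixture
def support_instance():
    """One shared gene (value 3) between P1 (support 2) and P2 (support 1)."""
    pmap = fv.PathwayMap([("ns1", "P1"), ("ns2", "P1"), ("ns3", "P2"),
                          ("sh", "P1"), ("sh", "P2")])
    profile = _profile([[2.0, 2.0, 1.0, 3.0]], ["ns1", "ns2", "ns3", "sh"])
    return profile, pmap


class TestClassifyAndEligibility:
    def test_classification(self, toy_map):
        shared, nonshared = fv.classify_genes(toy_map)
        assert shared == {"KO1"}
        assert nonshared == {"KO2", "KO3", "KO4"}

    def test_all_single_pathway_means_no_shared(self):
        pmap = fv.PathwayMap([("a", "P1"), ("b", "P2")])
        shared, nonshared = fv.classify_genes(pmap)
        assert shared == frozenset()
        assert nonshared == {"a", "b"}

    def test_nonshared_count_threshold(self):
        genes9 = [(f"x{i}", "P1") for i in range(9)]
        genes10 = [(f"y{i}", "P2") for i in range(10)]
        pmap = fv.PathwayMap(genes9 + genes10)
        profile = _profile([np.ones(19)], [g for g, _ in genes9 + genes10])
        eligible = fv.eligible_pathways(profile, pmap,
                                        EligibilityFilter(10, 0.0))
        assert eligible == {"P2"}

    def test_abundance_threshold(self):
        pmap = fv.PathwayMap([("a", "P1"), ("b", "P2")])
        profile = _profile([[999.0, 1.0]], ["a", "b"])
        filt = EligibilityFilter(min_nonshared=0, min_mean_rel_abundance=0.01)
        assert fv.eligible_pathways(profile, pmap, filt) == {"P1"}

    def test_open_filter_keeps_everything(self, toy_profile, toy_map):
        assert fv.eligible_pathways(toy_profile, toy_map, OPEN) == {"P1", "P2"}


class TestPathwaySupport:
    def test_mean_of_nonshared(self, support_instance):
        profile, pmap = support_instance
        sup = fv.pathway_support(profile, pmap)
        assert sup.loc["s0", "P1"] == pytest.approx(2.0)
        assert sup.loc["s0", "P2"] == pytest.approx(1.0)

    def test_single_nonshared_gene_is_its_value(self):
        pmap = fv.PathwayMap([("a", "P1"), ("sh", "P1"), ("sh", "P2"),
                              ("b", "P2")])
        profile = _profile([[7.0, 1.0, 0.0]], ["a", "sh", "b"])
        sup = fv.pathway_support(profile, pmap)
        assert sup.loc["s0", "P1"] == 7.0
        assert sup.loc["s0", "P2"] == 0.0

    def test_pathway_without_nonshared_in_profile_warns(self):
        pmap = fv.PathwayMap([("a", "P1"), ("sh", "P1"), ("sh", "P2")])
        profile = _profile([[1.0, 1.0]], ["a", "sh"])
        with pytest.warns(UserWarning, match="no non-shared"):
            sup = fv.pathway_support(profile, pmap)
        assert list(sup.columns) == ["P1"]


class TestMapToPathways:
    def test_support_ratio_partition(self, support_instance):
        profile, pmap = support_instance
        out = fv.map_to_pathways(profile, pmap, "empanada", OPEN)
        # shared gene 3.0 split 2:1 on supports; plus non-shared sums
        assert out.data.loc["s0", "P1"] == pytest.approx(4.0 + 2.0)
        assert out.data.loc["s0", "P2"] == pytest.approx(1.0 + 1.0)

    def test_fractional_and_complete(self, support_instance):
        profile, pmap = support_instance
        frac = fv.map_to_pathways(profile, pmap, "fractional", OPEN)
        comp = fv.map_to_pathways(profile, pmap, "complete", OPEN)
        assert frac.data.loc["s0", "P1"] == pytest.approx(4.0 + 1.5)
        assert comp.data.loc["s0", "P1"] == pytest.approx(4.0 + 3.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            df, pairs = random_mapping_instance(rng)
            profile = fv.GeneProfile(df)
            pmap = fv.PathwayMap(pairs)
            for scheme in ("fractional", "complete", "empanada"):
                out = fv.map_to_pathways(profile, pmap, scheme, OPEN)
                expected = naive_map_to_pathways(df, pairs, scheme, 0, 0.0)
                assert sorted(out.pathway_ids) == sorted(expected.columns)
                assert np.allclose(
                    out.data[sorted(out.pathway_ids)].to_numpy(),
                    expected[sorted(expected.columns)].to_numpy(),
                    atol=1e-9)

    def test_mass_conservation(self):
        rng = np.random.default_rng(13)
        df, pairs = random_mapping_instance(rng)
        profile = fv.GeneProfile(df)
        pmap = fv.PathwayMap(pairs)
        mapped = [g for g in df.columns if g in pmap.genes]
        for scheme in ("fractional", "empanada"):
            out = fv.map_to_pathways(profile, pmap, scheme, OPEN)
            assert np.allclose(out.values.sum(axis=1),
                               df[mapped].sum(axis=1), atol=1e-9)

    def test_dominance_complete_ge_fractional(self):
        rng = np.random.default_rng(21)
        df, pairs = random_mapping_instance(rng)
        profile = fv.GeneProfile(df)
        pmap = fv.PathwayMap(pairs)
        frac = fv.map_to_pathways(profile, pmap, "fractional", OPEN)
        comp = fv.map_to_pathways(profile, pmap, "complete", OPEN)
        assert (comp.values - frac.values >= -1e-12).all()

    def test_equal_supports_reduce_to_fractional(self):
        pmap = fv.PathwayMap([("n1", "P1"), ("n2", "P2"), ("sh", "P1"),
                              ("sh", "P2")])
        profile = _profile([[5.0, 5.0, 4.0]], ["n1", "n2", "sh"])
        emp = fv.map_to_pathways(profile, pmap, "empanada", OPEN)
        frac = fv.map_to_pathways(profile, pmap, "fractional", OPEN)
        assert np.allclose(emp.values, frac.values, atol=1e-12)

    def test_zero_support_falls_back_to_uniform(self):
        pmap = fv.PathwayMap([("n1", "P1"), ("n2", "P2"), ("sh", "P1"),
                              ("sh", "P2")])
        profile = _profile([[0.0, 0.0, 6.0]], ["n1", "n2", "sh"])
        out = fv.map_to_pathways(profile, pmap, "empanada", OPEN)
        assert out.data.loc["s0", "P1"] == pytest.approx(3.0)
        assert out.data.loc["s0", "P2"] == pytest.approx(3.0)

    def test_all_shared_map_is_error(self):
        pmap = fv.PathwayMap([("sh1", "P1"), ("sh1", "P2"),
                              ("sh2", "P1"), ("sh2", "P2")])
        profile = _profile([[1.0, 2.0]], ["sh1", "sh2"])
        with pytest.raises(FuncvarError, match="non-shared"):
            fv.map_to_pathways(profile, pmap, "empanada", OPEN)

    def test_sample_permutation_equivariance(self, small_world):
        profile, _ = fv.simulate_profiles(small_world, n_samples=6, seed=2)
        out = fv.map_to_pathways(profile, small_world.pathway_map, "empanada")
        perm = ["S004", "S001", "S006", "S002", "S003", "S005"]
        shuffled = fv.GeneProfile(profile.data.loc[perm])
        out_perm = fv.map_to_pathways(shuffled, small_world.pathway_map,
                                      "empanada")
        assert np.allclose(out.data.loc[perm].to_numpy(),
                           out_perm.values, atol=1e-12)

    def test_partition_weights_sum_to_one(self, support_instance):
        profile, pmap = support_instance
        sup = fv.pathway_support(profile, pmap)
        weights = sup.to_numpy() / sup.to_numpy().sum(axis=1, keepdims=True)
        assert weights.min() >= 0
        assert np.allclose(weights.sum(axis=1), 1.0)
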