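import numpy as np
import pandas as pd
import pytest

import funcvar as fv
from funcvar.profiles_io import FuncvarError
from oracles import naive_bray_curtis


def _pathway_profile(rows, features=None, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    features = features or [f"P{i}" for i in range(rows.shape[1])]
    return fv.PathwayProfile(pd.DataFrame(rows, index=samples, columns=features))


class TestCov:
    @pytest.mark.parametrize("values,expected", [
        ([5, 5, 5], 0.0),
        ([1, 2, 3], 0.5),
    ])
    def test_known_values(self, values, expected):
        assert fv.coefficient_of_variation(values) == pytest.approx(expected)

    def test_zero_mean_sentinel(self):
        assert np.isnan(fv.coefficient_of_variation([0, 0, 0]))

    def test_too_short_is_error(self):
        with pytest.raises(FuncvarError):
            fv.coefficient_of_variation([1.0])

    def test_scale_invariance(self):
        x = np.random.default_rng(0).gamma(2, 3, 20)
        assert fv.coefficient_of_variation(7.7 * x) == pytest.approx(
            fv.coefficient_of_variation(x))


class TestFoldChange:
    def test_ratio_to_mean(self):
        prof = _pathway_profile([[1], [2], [3]], features=["P"])
        assert np.allclose(fv.fold_change_from_mean(prof, "P"),
                           [0.5, 1.0, 1.5])

    def test_constant_feature_all_ones(self):
        prof = _pathway_profile([[4], [4]], features=["P"])
        assert np.allclose(fv.fold_change_from_mean(prof, "P"), 1.0)

    def test_global_rescaling_invariance(self):
        prof = _pathway_profile([[1], [2], [3]], features=["P"])
        doubled = _pathway_profile([[2], [4], [6]], features=["P"])
        assert np.allclose(fv.fold_change_from_mean(prof, "P"),
                           fv.fold_change_from_mean(doubled, "P"))


class TestBrayCurtis:
    def test_disjoint_identical_and_nested(self):
        prof = _pathway_profile([[1, 0], [0, 1], [1, 0], [2, 2]])
        dist = fv.bray_curtis_matrix(prof)
        assert dist.data.iloc[0, 1] == pytest.approx(1.0)
        assert dist.data.iloc[0, 2] == pytest.approx(0.0)
        # [2,2] vs [1,1]: 1 - 2*2/(4+2) = 1/3
        nested = _pathway_profile([[2, 2], [1, 1]])
        assert fv.bray_curtis_matrix(nested).data.iloc[0, 1] \
            == pytest.approx(1 / 3)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(5)
        prof = _pathway_profile(rng.gamma(1, 5, (12, 9)) + 1e-6)
        dist = fv.bray_curtis_matrix(prof)
        assert np.allclose(dist.values, naive_bray_curtis(prof.values),
                           atol=1e-12)
        assert dist.values.max() <= 1.0

    def test_all_zero_sample_is_error(self):
        with pytest.raises(FuncvarError, match="all-zero"):
            fv.bray_curtis_matrix(_pathway_profile([[1, 1], [0, 0]]))


class TestNegativePairFraction:
    def test_perfect_anticorrelation(self):
        prof = fv.GeneProfile(pd.DataFrame(
            {"a": [1.0, 2, 3], "b": [3.0, 2, 1]}, index=["s1", "s2", "s3"]))
        assert fv.negative_pair_fraction(prof) == 1.0

    def test_identical_genes_fraction_zero(self):
        prof = fv.GeneProfile(pd.DataFrame(
            {"a": [1.0, 2, 3], "b": [1.0, 2, 3]}, index=["s1", "s2", "s3"]))
        assert fv.negative_pair_fraction(prof) == 0.0

    def test_null_matches_binomial_expectation(self):
        # independent genes: P(r < -0.3) has a known null level; check the
        # empirical fraction over many pairs against 3 binomial SDs
        rng = np.random.default_rng(17)
        n_samples, n_genes = 200, 40
        prof = fv.GeneProfile(pd.DataFrame(
            rng.lognormal(0, 1, (n_samples, n_genes)),
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"g{i}" for i in range(n_genes)]))
        frac = fv.negative_pair_fraction(prof, r_threshold=-0.3)
        from scipy import stats as sps
        # null P(r < -0.3) for Pearson r of n=200 independent pairs
        r = -0.3
        t = r * np.sqrt((n_samples - 2) / (1 - r ** 2))
        p_null = sps.t.cdf(t, df=n_samples - 2)
        n_pairs = n_genes * (n_genes - 1) // 2
        sd = np.sqrt(p_null * (1 - p_null) / n_pairs)
        assert abs(frac - p_null) < max(3 * sd, 0.01)

    def test_zero_variance_genes_excluded(self):
        prof = fv.GeneProfile(pd.DataFrame(
            {"a": [1.0, 2, 3], "b": [3.0, 2, 1], "c": [5.0, 5, 5]},
            index=["s1", "s2", "s3"]))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert fv.negative_pair_fraction(prof) == 1.0


class TestMantel:
    def _dist(self, seed, n=10, f=6):
        rng = np.random.default_rng(seed)
        prof = _pathway_profile(rng.gamma(1, 5, (n, f)) + 1e-9)
        return fv.bray_curtis_matrix(prof)

    def test_self_agreement(self):
        d = self._dist(1)
        r, p = fv.mantel_test(d, d, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_affine_transform_keeps_r_one(self):
        d = self._dist(2)
        d2 = fv.DistanceMatrix.from_square(0.5 * d.values + 0.1 * (d.values > 0),
                                           d.ids)
        r, _ = fv.mantel_test(d, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_id_mismatch_is_error(self):
        d1, d2 = self._dist(1), self._dist(2)
        renamed = fv.DistanceMatrix.from_square(
            d2.values, [f"x{i}" for i in range(len(d2.ids))])
        with pytest.raises(FuncvarError, match="ID sets"):
            fv.mantel_test(d1, renamed)

    def test_seeded_reproducibility(self):
        d1, d2 = self._dist(3), self._dist(4)
        out1 = fv.mantel_test(d1, d2, n_perm=199, seed=42)
        out2 = fv.mantel_test(d1, d2, n_perm=199, seed=42)
        assert out1 == out2

    def test_agrees_with_skbio_r(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM, mantel
        d1, d2 = self._dist(5), self._dist(6)
        r, _ = fv.mantel_test(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = mantel(SkDM(d1.values, ids=d1.ids),
                             SkDM(d2.values, ids=d2.ids),
                             permutations=0)
        assert r == pytest.approx(float(r_ref), abs=1e-10)


class TestCompareSchemeVariation:
    def test_identity_gives_unit_ratios(self):
        rng = np.random.default_rng(8)
        prof = _pathway_profile(rng.gamma(2, 3, (10, 5)))
        rep = fv.compare_scheme_variation(prof, prof)
        assert np.allclose(rep.table["cov_ratio"], 1.0)
        assert rep.statistic == 0.0
        assert rep.pvalue == 1.0

    def test_doubled_spread_doubles_cov_ratio(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(5, 10, (10, 4))
        prof_a = _pathway_profile(vals)
        spread = vals.copy()
        spread[:, 0] = vals[:, 0].mean() + 2 * (vals[:, 0] - vals[:, 0].mean())
        prof_b = _pathway_profile(spread)
        rep = fv.compare_scheme_variation(prof_a, prof_b)
        assert rep.table["cov_ratio"].iloc[0] == pytest.approx(2.0)
        assert np.allclose(rep.table["cov_ratio"].iloc[1:], 1.0)

    def test_too_few_shared_features_is_error(self):
        a = _pathway_profile([[1, 2], [2, 1]], features=["P1", "P2"])
        b = _pathway_profile([[1, 2], [2, 1]], features=["P3", "P4"])
        with pytest.warns(UserWarning, match="intersection"):
            with pytest.raises(FuncvarError, match="shared features"):
                fv.compare_scheme_variation(a, b)
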