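"""The eight tests of identical distribution: examples, invariances, oracles."""
import numpy as np
import pytest

from circompare.core import CircularDataError, TWO_PI
from circompare.identity import (
    embedding_anova,
    het_anova,
    kuiper_two,
    lr_anova,
    manova_trig,
    uniform_scores_test,
    watson_u2,
)
from circompare.simulate import sample_von_mises
from conftest import parametric_bootstrap_pvalue, permutation_pvalue

deg = np.deg2rad

IDENTITY_TESTS = {
    "WU2": watson_u2,
    "Kui": kuiper_two,
    "MWW": lambda a, b: uniform_scores_test(a, b, "MWW"),
    "WWe": lambda a, b: uniform_scores_test(a, b, "WWe"),
    "EmA": embedding_anova,
    "LlA": lr_anova,
    "HeA": het_anova,
    "Man": manova_trig,
}


@pytest.fixture(scope="module")
def generic_pair():
    rng = np.random.default_rng(10)
    return sample_von_mises(14, 0.3, 1.5, rng), sample_von_mises(19, 1.1, 1.5, rng)


class TestWatsonU2:
    def test_rotation_invariance(self, generic_pair):
        a1, a2 = generic_pair
        u = watson_u2(a1, a2).statistic
        phi = deg(37.0)
        u_rot = watson_u2(np.mod(a1 + phi, TWO_PI), np.mod(a2 + phi, TWO_PI)).statistic
        assert u_rot == pytest.approx(u, abs=1e-12)

    def test_small_pool_carries_warning(self):
        rng = np.random.default_rng(2)
        res = watson_u2(rng.uniform(0, TWO_PI, 8), rng.uniform(0, TWO_PI, 8))
        assert any("17" in w for w in res.warnings)

    def test_asymptotic_p_close_to_permutation_p(self):
        rng = np.random.default_rng(5)
        a1 = sample_von_mises(8, 0.0, 1.0, rng)
        a2 = sample_von_mises(8, 0.8, 1.0, rng)
        p_perm = permutation_pvalue(watson_u2, a1, a2, nperm=5000, seed=1)
        assert abs(watson_u2(a1, a2).p_value - p_perm) < 0.05

    def test_empty_sample_is_an_error(self):
        with pytest.raises(CircularDataError):
            watson_u2([], [0.1, 0.2])


class TestKuiper:
    def test_identical_samples_give_v_zero_p_one(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, TWO_PI, 12)
        res = kuiper_two(a, a.copy())
        # V is one ECDF step when the multisets coincide
        assert res.statistic <= 1.0 / 12 + 1e-12
        assert res.p_value == pytest.approx(1.0)

    def test_rotation_invariance(self, generic_pair):
        a1, a2 = generic_pair
        v = kuiper_two(a1, a2).statistic
        phi = deg(123.0)
        assert kuiper_two(np.mod(a1 + phi, TWO_PI), np.mod(a2 + phi, TWO_PI)).statistic == pytest.approx(v, abs=1e-12)


class TestUniformScoresTest:
    def test_symmetric_interleaving_gives_zero_statistic(self):
        res = uniform_scores_test(deg([0, 90, 180, 270]), deg([45, 135, 225, 315]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_rotation_and_exchange_invariance(self, generic_pair):
        a1, a2 = generic_pair
        w = uniform_scores_test(a1, a2).statistic
        phi = deg(61.0)
        w_rot = uniform_scores_test(np.mod(a1 + phi, TWO_PI), np.mod(a2 + phi, TWO_PI)).statistic
        assert w_rot == pytest.approx(w, abs=1e-9)
        assert uniform_scores_test(a2, a1).statistic == pytest.approx(w, abs=1e-12)

    def test_variant_guards(self):
        rng = np.random.default_rng(4)
        a1, a2 = rng.uniform(0, TWO_PI, 8), rng.uniform(0, TWO_PI, 30)
        assert uniform_scores_test(a1, a2, "MWW").warnings
        assert not uniform_scores_test(a1, a2, "WWe").warnings  # continuous, no ties
        tied = np.concatenate([a1, a1[:1]])
        assert uniform_scores_test(tied, a2, "WWe").warnings

    def test_chi2_p_close_to_permutation_p(self):
        rng = np.random.default_rng(6)
        a1 = sample_von_mises(15, 0.0, 2.0, rng)
        a2 = sample_von_mises(15, deg(60.0), 2.0, rng)
        p_perm = permutation_pvalue(lambda x, y: uniform_scores_test(x, y, "MWW"), a1, a2, 5000, seed=2)
        assert abs(uniform_scores_test(a1, a2, "MWW").p_value - p_perm) < 0.05


class TestCircularAnovas:
    def test_evenly_spread_samples_give_zero_statistic(self):
        # resultants vanish exactly on a regular lattice: no between-group signal
        a1 = deg([0, 90, 180, 270])
        a2 = deg([30, 120, 210, 300])
        for fn in (embedding_anova, lr_anova):
            res = fn(a1, a2)
            assert res.statistic == pytest.approx(0.0, abs=1e-9)
            assert res.p_value == pytest.approx(1.0)

    def test_collinear_resultants_give_zero_lr_statistic(self):
        res = lr_anova(deg([10, 50]), deg([20, 40]))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_het_anova_equal_mean_directions(self):
        res = het_anova(deg([10, 50]), deg([20, 40]))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_het_anova_rejects_zero_resultant_group(self):
        with pytest.raises(CircularDataError):
            het_anova(deg([0, 180]), deg([10, 20, 30]))

    @pytest.mark.parametrize("fn", [embedding_anova, lr_anova, het_anova])
    def test_rotation_invariance(self, fn, generic_pair):
        a1, a2 = generic_pair
        s = fn(a1, a2).statistic
        phi = deg(77.0)
        s_rot = fn(np.mod(a1 + phi, TWO_PI), np.mod(a2 + phi, TWO_PI)).statistic
        assert s_rot == pytest.approx(s, abs=1e-8)

    def test_lr_anova_p_close_to_parametric_bootstrap(self):
        rng = np.random.default_rng(9)
        a1 = sample_von_mises(25, 0.0, 3.0, rng)
        a2 = sample_von_mises(25, deg(25.0), 3.0, rng)
        p_boot = parametric_bootstrap_pvalue(lr_anova, a1, a2, nboot=3000, seed=3)
        assert abs(lr_anova(a1, a2).p_value - p_boot) < 0.05

    def test_embedding_anova_p_close_to_parametric_bootstrap(self):
        rng = np.random.default_rng(12)
        a1 = sample_von_mises(20, 0.0, 2.0, rng)
        a2 = sample_von_mises(20, deg(40.0), 2.0, rng)
        p_boot = parametric_bootstrap_pvalue(embedding_anova, a1, a2, nboot=3000, seed=4)
        assert abs(embedding_anova(a1, a2).p_value - p_boot) < 0.05

    def test_het_anova_p_close_to_permutation(self):
        rng = np.random.default_rng(13)
        a1 = sample_von_mises(50, 0.0, 2.0, rng)
        a2 = sample_von_mises(50, deg(45.0), 2.0, rng)
        p_perm = permutation_pvalue(het_anova, a1, a2, nperm=3000, seed=5)
        assert abs(het_anova(a1, a2).p_value - p_perm) < 0.05


class TestManova:
    def test_identical_groups_give_pillai_zero(self):
        a = deg([0, 90, 200])
        res = manova_trig(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_statsmodels_pillai_f(self, generic_pair):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        a1, a2 = generic_pair
        res = manova_trig(a1, a2)
        pooled = np.concatenate([a1, a2])
        df = pd.DataFrame(
            {
                "c": np.cos(pooled),
                "s": np.sin(pooled),
                "g": np.r_[np.zeros(len(a1)), np.ones(len(a2))],
            }
        )
        tab = MANOVA.from_formula("c + s ~ C(g)", data=df).mv_test().results["C(g)"]["stat"]
        assert res.statistic == pytest.approx(float(tab.loc["Pillai's trace", "F Value"]), rel=1e-8)
        assert res.p_value == pytest.approx(float(tab.loc["Pillai's trace", "Pr > F"]), abs=1e-10)

    def test_degenerate_identical_angles_raise(self):
        with pytest.raises(CircularDataError):
            manova_trig(np.full(5, 1.0), np.full(5, 1.0))

    def test_p_close_to_permutation(self):
        rng = np.random.default_rng(14)
        a1 = sample_von_mises(20, 0.0, 2.0, rng)
        a2 = sample_von_mises(20, deg(50.0), 2.0, rng)
        p_perm = permutation_pvalue(manova_trig, a1, a2, nperm=5000, seed=6)
        assert abs(manova_trig(a1, a2).p_value - p_perm) < 0.05


@pytest.mark.parametrize("tid,fn", sorted(IDENTITY_TESTS.items()))
def test_sample_exchange_symmetry(tid, fn, generic_pair):
    """Swapping the two samples never changes statistic or p-value."""
    a1, a2 = generic_pair
    r12, r21 = fn(a1, a2), fn(a2, a1)
    assert r21.statistic == pytest.approx(r12.statistic, rel=1e-9, abs=1e-9)
    assert r21.p_value == pytest.approx(r12.p_value, rel=1e-9, abs=1e-9)
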