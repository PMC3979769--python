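"""Repeatability, partial correlation, mismatch and AIC model selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from camomatch import synthgen
from camomatch.matchstats import (
    akaike_weights,
    candidate_term_sets,
    color_mismatch,
    icc,
    mixed_model_selection,
    partial_pearson,
)


class TestICC:
    def test_hand_anova_decomposition(self):
        """4x2 toy table against the explicit sums-of-squares: MSB=309.5,
        MSW=2.25, ICC=(MSB-MSW)/(MSB+MSW)."""
        vals = np.array([[10.0, 12.0], [20.0, 19.0], [30.0, 33.0], [40.0, 38.0]])
        res = icc(vals)
        assert res.ms_between == pytest.approx(309.5)
        assert res.ms_within == pytest.approx(2.25)
        assert res.icc == pytest.approx((309.5 - 2.25) / (309.5 + 2.25))
        assert res.f_statistic == pytest.approx(309.5 / 2.25)

    def test_identical_duplicates_give_one(self):
        vals = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        res = icc(vals)
        assert res.icc == 1.0
        assert res.p_value == 0.0

    def test_mean_square_ratio_example(self):
        """A variance structure engineered to MSB~99, MSW~1 at k=2 puts the
        coefficient near (99-1)/(99+1)."""
        vals = synthgen.simulate_duplicates(4000, 2, np.sqrt(49.0), 1.0, seed=0)
        assert icc(vals).icc == pytest.approx(0.98, abs=0.005)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        vals = synthgen.simulate_duplicates(30, 2, 5.0, 2.0, seed=1)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(30), 2),
                "raters": np.tile([0, 1], 30),
                "ratings": vals.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "targets", "raters", "ratings")
        icc1 = float(ref.loc[ref.Type == "ICC(1,1)", "ICC"].iloc[0])
        assert icc(vals).icc == pytest.approx(icc1, abs=1e-9)

    def test_parameter_recovery_bias_small(self):
        """Estimates converge to sigma_b^2/(sigma_b^2+sigma_w^2); bias at
        n=77 below 0.01 for true repeatability 0.75 and 0.98."""
        for b, w, truth in [(np.sqrt(3), 1.0, 0.75), (7.0, 1.0, 0.98)]:
            est = [
                icc(synthgen.simulate_duplicates(77, 2, b, w, seed=s)).icc
                for s in range(200)
            ]
            assert abs(np.mean(est) - truth) < 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            icc(np.array([[1.0], [2.0]]))  # k=1
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPartialPearson:
    def test_orthogonal_covariate_equals_plain_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        x -= x.mean()
        y -= y.mean()
        cov = np.tile([1.0, -1.0], 20)
        basis = np.c_[x, y]  # project out span{x, y} jointly
        cov = cov - basis @ np.linalg.lstsq(basis, cov, rcond=None)[0]
        plain = np.corrcoef(x, y)[0, 1]
        res = partial_pearson(x, y, cov)
        assert res.r == pytest.approx(plain, abs=1e-10)

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = partial_pearson(x, x.copy(), np.random.default_rng(0).normal(size=10))
        assert res.r == pytest.approx(1.0)

    def test_six_point_residualization_oracle(self):
        """Residualize-then-correlate by explicit regression on a binary
        covariate."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 2.5, 2.0, 4.5, 5.0, 6.5])
        g = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        rx = x.copy()
        ry = y.copy()
        for v in (rx, ry):
            for grp in (0.0, 1.0):
                v[g == grp] -= v[g == grp].mean()
        expected = np.corrcoef(rx, ry)[0, 1]
        res = partial_pearson(x, y, g)
        assert res.r == pytest.approx(expected, abs=1e-12)
        assert res.df == 6 - 2 - 1
        t = expected * np.sqrt(3) / np.sqrt(1 - expected**2)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)

    def test_inverse_correlation_matrix_oracle(self):
        """r_xy.z from the inverse of the 3x3 correlation matrix agrees to
        1e-10."""
        rng = np.random.default_rng(7)
        z = rng.normal(size=200)
        x = 0.8 * z + rng.normal(size=200)
        y = -0.5 * z + 0.3 * x + rng.normal(size=200)
        p = np.linalg.inv(np.corrcoef(np.c_[x, y, z].T))
        expected = -p[0, 1] / np.sqrt(p[0, 0] * p[1, 1])
        res = partial_pearson(x, y, z)
        assert res.r == pytest.approx(expected, abs=1e-10)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=50),
                "z": rng.normal(size=50),
            }
        )
        df["y"] = 0.4 * df.x + 0.6 * df.z + rng.normal(size=50)
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        res = partial_pearson(df.x, df.y, df.z)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            partial_pearson(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError, match="rank-deficient"):
            x = np.arange(20.0)
            partial_pearson(x, x + 1, np.c_[x, 2 * x])


class TestColorMismatch:
    def test_identical_standardized_vectors_give_zero(self):
        fur = np.array([1.0, 2.0, 3.0, 4.0])
        env = fur * 10 + 5  # same z-scores
        res = color_mismatch(fur, env, ["c1", "c1", "c2", "c2"])
        assert np.allclose(res.mismatch, 0.0)
        assert res.skewness["c1"] is None

    def test_symmetric_mismatch_near_zero_skew(self):
        rng = np.random.default_rng(0)
        fur = rng.normal(size=4000)
        env = rng.normal(size=4000)
        res = color_mismatch(fur, env, np.repeat("c1", 4000))
        assert abs(res.skewness["c1"]) < 0.1

    def test_configured_asymmetry_orders_clade_skewness(self):
        """A clade built with a heavier one-sided mismatch tail shows the
        larger |skewness| across seeds."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 400
            # clade 1: skewed habitat mismatch; clade 2: symmetric
            m1 = rng.gamma(2.0, 1.0, size=n)
            m2 = rng.normal(0.0, 1.0, size=n)
            fur = np.concatenate([m1, m2])
            env = np.zeros(2 * n)
            env[0] = 1e-9  # avoid zero variance in env
            res = color_mismatch(fur, env, ["c1"] * n + ["c2"] * n)
            wins += abs(res.skewness["c1"]) > abs(res.skewness["c2"])
        assert wins >= 18

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            color_mismatch(np.ones(5), np.arange(5.0), ["a"] * 5)


class TestModelSelection:
    def test_akaike_weights_sum_and_shift_invariance(self):
        aic = np.array([100.0, 101.0, 105.0])
        w = akaike_weights(aic)
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, akaike_weights(aic + 37.0))
        assert list(np.argsort(w)[::-1]) == [0, 1, 2]

    def test_equal_aics_split_evenly(self):
        assert np.allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_candidate_generation_includes_interactions(self):
        sets = candidate_term_sets(("a", "x"), interactions=(("a", "x"),))
        assert ("a", "x") in sets
        assert ("a", "x", "a:x") in sets

    def test_single_candidate_table(self):
        df = synthgen.generate_phenotypes(30, synthgen.phenotype_preset(), seed=0)
        long = synthgen.specimens_to_long(df)
        mt = mixed_model_selection(long, candidates=[("clade",)])
        assert mt.table.delta.iloc[0] == 0.0
        assert mt.table.weight.iloc[0] == pytest.approx(1.0)
        assert mt.n_candidates == 1

    def test_aic_matches_ml_loglik_bookkeeping(self):
        df = synthgen.generate_phenotypes(40, synthgen.phenotype_preset(), seed=3)
        long = synthgen.specimens_to_long(df)
        mt = mixed_model_selection(long, candidates=[("clade", "env_lum")])
        row = mt.table.iloc[0]
        # k = intercept + 2 slopes + random-intercept var + residual var
        assert row.df == 5
        assert row.AIC == pytest.approx(-2 * row.logLik + 2 * 5)

    def test_true_effects_recovered_in_best_model(self):
        """With a genuine clade offset and environment slope, AIC selection
        over {clade, origin, env_lum} subsets keeps both true terms in the
        best model for nearly every seed."""
        preset = synthgen.phenotype_preset()
        cands = candidate_term_sets(("clade", "origin", "env_lum"))
        hits = 0
        for s in range(25):
            df = synthgen.generate_phenotypes(80, preset, seed=100 + s)
            long = synthgen.specimens_to_long(df)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mt = mixed_model_selection(long, candidates=cands)
            if "clade" in mt.best_terms and "env_lum" in mt.best_terms:
                # the clade coefficient must carry the generating sign
                coef = mt.best_coefficients
                clade_rows = [i for i in coef.index if "clade" in i]
                assert coef.loc[clade_rows[0], "estimate"] < 0
                hits += 1
        assert hits >= 22

    def test_weights_sum_over_full_candidate_report(self):
        df = synthgen.generate_phenotypes(40, synthgen.phenotype_preset(), seed=9)
        long = synthgen.specimens_to_long(df)
        cands = candidate_term_sets(("clade", "env_lum"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mt = mixed_model_selection(long, candidates=cands, top=None)
        assert mt.table.weight.sum() == pytest.approx(1.0)
        assert mt.table.delta.is_monotonic_increasing
        for term, imp in mt.importance.items():
            manual = mt.table.loc[
                [term in t for t in mt.table.terms], "weight"
            ].sum()
            assert imp == pytest.approx(manual)
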