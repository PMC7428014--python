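"""Differential testing: normalization, NB-LRT, BH, contrasts, MDS."""

import numpy as np
import pandas as pd
import pytest

from quantm.differential import (
    DesignSpec,
    bh_adjust,
    cns_contrast,
    correlation_matrix,
    differential_variants,
    mds,
    nb_lrt,
    size_factors,
)


def two_group_design(n_per=3):
    samples = tuple(f"{g}{i}" for g in ("A", "B") for i in range(n_per))
    groups = tuple(g for g in ("A", "B") for _ in range(n_per))
    return DesignSpec(samples, groups)


class TestDesign:
    def test_rejects_single_group(self):
        with pytest.raises(ValueError):
            DesignSpec(("a", "b"), ("g", "g"))

    def test_rejects_singleton_group(self):
        with pytest.raises(ValueError):
            DesignSpec(("a", "b", "c"), ("g1", "g1", "g2"))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_column_ratio_exactly_two(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_hand_computed_medians(self):
        # Odd feature count, so the median is an order statistic and the
        # linear-space hand computation applies directly.  Per-feature
        # geometric means: 4, 1, (9*3*3)^(1/3)=~4.327, ~2.52, 6.
        df = pd.DataFrame(
            {"a": [8, 1, 9, 4, 6], "b": [2, 1, 3, 4, 6], "c": [4, 1, 3, 1, 6]},
            dtype=float,
        )
        geo = (df.prod(axis=1)) ** (1 / 3)
        expected = (df.div(geo, axis=0)).median(axis=0)
        sf = size_factors(df)
        assert np.allclose(sf, expected)

    def test_all_features_with_zero_errors(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(df)


class TestNbLrt:
    def test_identical_group_means_give_p_one(self):
        design = two_group_design()
        df = pd.DataFrame(
            [[50] * 6, [10] * 6, [200] * 6], columns=design.samples
        )
        res = nb_lrt(df, design)
        assert (res["stat"] < 1e-6).all()
        assert (res["pvalue"] > 0.999).all()

    def test_all_zero_feature_flagged(self):
        design = two_group_design()
        df = pd.DataFrame([[0] * 6, [10] * 6, [20] * 6], columns=design.samples)
        res = nb_lrt(df, design)
        assert res.iloc[0]["flag"] == "all_zero"
        assert res.iloc[0]["pvalue"] == 1.0

    def test_planted_eightfold_shift_is_hugely_significant(self):
        design = two_group_design()
        rng = np.random.default_rng(5)
        n_null = 40
        mu = rng.uniform(200, 2000, size=n_null)
        r = 10.0  # alpha = 0.1
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_null, 6))
        planted = np.concatenate(
            [rng.poisson(8000, 3), rng.poisson(1000, 3)]
        )[None, :]
        df = pd.DataFrame(
            np.vstack([planted, counts]), columns=design.samples
        )
        res = nb_lrt(df, design)
        assert res.iloc[0]["pvalue"] < 1e-6
        assert res.iloc[0]["log2fc"] == pytest.approx(3.0, abs=0.5)

    def test_poisson_limit_matches_analytic_chi2(self):
        """With dispersion ~0 the NB LRT equals the Poisson LRT closed form."""
        from quantm.differential import _full_model_loglik, _fit_nb_mean, _nb_loglik
        from scipy import stats as sps

        design = two_group_design()
        y = np.array([12.0, 15, 9, 30, 28, 35])
        s = np.ones(6)
        idx = design.indices()
        alpha = 1e-9
        ll_full, _, _ = _full_model_loglik(y, s, idx, alpha)
        q0 = _fit_nb_mean(y, s, alpha)
        ll_red = _nb_loglik(y, s * q0, alpha)
        stat = 2 * (ll_full - ll_red)
        # Poisson LRT closed form: 2 * sum y_g * log(mean_g / grand mean)
        m1, m2, m = y[:3].mean(), y[3:].mean(), y.mean()
        closed = 2 * (y[:3].sum() * np.log(m1 / m) + y[3:].sum() * np.log(m2 / m))
        assert stat == pytest.approx(closed, rel=1e-6)
        assert sps.chi2.sf(stat, 1) == pytest.approx(sps.chi2.sf(closed, 1))


class TestBh:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_stepup_hand_application(self):
        # p(i) * n / i = [.04, .04, .04, .04] after monotone enforcement
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_rank_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1).all() and (adj >= p - 1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCnsContrast:
    def make_results(self):
        return pd.DataFrame(
            {
                "log2fc": [2.0, 1.0, -2.5, 0.5],
                "padj": [0.005, 0.005, 0.001, 0.2],
            },
            index=["up4fold", "up2fold", "down6fold", "ns"],
        )

    def test_fold_change_and_padj_both_required(self):
        out = cns_contrast(self.make_results())
        assert set(out.index) == {"up4fold", "down6fold"}
        assert out.loc["up4fold", "direction"] == "up"
        assert out.loc["down6fold", "direction"] == "down"

    def test_matches_brute_scan(self):
        res = self.make_results()
        out = cns_contrast(res, fc_threshold=3, padj_threshold=0.01)
        brute = {
            i for i in res.index
            if res.loc[i, "padj"] < 0.01 and abs(res.loc[i, "log2fc"]) > np.log2(3)
        }
        assert set(out.index) == brute


class TestDifferentialVariants:
    def test_fold_change_arithmetic(self):
        design = two_group_design()
        cov = pd.DataFrame(np.full((1, 6), 100000.0), columns=design.samples)
        v = pd.DataFrame(
            [[5000, 5000, 5000, 2000, 2000, 2000]], columns=design.samples,
            dtype=float,
        )
        res = differential_variants(v, cov, design)
        assert res.iloc[0]["fold_change"] == pytest.approx(2.5, abs=0.01)
        assert res.iloc[0]["fold_change"] > 1.5

    def test_undetectable_base_not_tested(self):
        design = two_group_design()
        cov = pd.DataFrame(np.full((1, 6), 1000.0), columns=design.samples)
        v = pd.DataFrame([[2, 3, 2, 3, 2, 3]], columns=design.samples, dtype=float)
        res = differential_variants(v, cov, design, min_fraction=0.01)
        assert len(res) == 0

    def test_zero_coverage_group_flagged(self):
        design = two_group_design()
        cov = pd.DataFrame(
            [[1000.0, 1000, 1000, 0, 0, 0]] * 12, columns=design.samples
        )
        v = pd.DataFrame([[50, 50, 50, 0, 0, 0]] * 12, columns=design.samples,
                         dtype=float)
        res = differential_variants(v, cov, design)
        assert (res["flag"] == "zero_coverage_group").all()

    def test_planted_cns_stall_detected(self):
        """0.30 vs 0.02 at coverage 2000 across 4+3 groups of 3 -> padj < 0.01."""
        groups = ["ctx", "cb", "med", "sc", "heart", "liver", "tib"]
        samples = tuple(f"{g}{i}" for g in groups for i in range(3))
        design = DesignSpec(samples, tuple(g for g in groups for _ in range(3)))
        rng = np.random.default_rng(17)
        n = 21
        cov = np.full((30, n), 2000.0)
        is_cns = np.array([g in ("ctx", "cb", "med", "sc") for g in design.groups])
        v = rng.binomial(2000, 0.03, size=(30, n)).astype(float)
        v[0] = np.where(is_cns, rng.binomial(2000, 0.30, n), rng.binomial(2000, 0.02, n))
        res = differential_variants(
            pd.DataFrame(v, columns=samples), pd.DataFrame(cov, columns=samples), design
        )
        assert res.iloc[0]["padj"] < 0.01
        assert bool(res.iloc[0]["significant"])


class TestMds:
    def test_equilateral_triangle(self):
        # three samples at mutual distance d
        d = 5.0
        pts = np.array([[0, 0], [d, 0], [d / 2, d * np.sqrt(3) / 2]])
        coords, _ = mds(pd.DataFrame(pts, index=list("abc")))
        got = np.linalg.norm(
            coords.to_numpy()[:, None, :] - coords.to_numpy()[None, :, :], axis=2
        )
        want = np.full((3, 3), d) - np.eye(3) * d
        assert np.allclose(got, want, atol=1e-9)

    def test_planar_configuration_reproduced_exactly(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        coords, lam = mds(pd.DataFrame(pts))
        got = np.linalg.norm(
            coords.to_numpy()[:, None] - coords.to_numpy()[None, :], axis=2
        )
        want = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        assert np.allclose(got, want, atol=1e-9)

    def test_degenerate_all_equal_at_origin(self):
        coords, _ = mds(pd.DataFrame(np.ones((4, 3))))
        assert np.allclose(coords, 0.0)

    def test_group_separation_visible(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, size=(3, 5))
        b = rng.normal(4, 0.1, size=(3, 5))
        coords, _ = mds(pd.DataFrame(np.vstack([a, b])))
        ca, cb = coords.iloc[:3].mean(), coords.iloc[3:].mean()
        within = max(
            np.linalg.norm(coords.iloc[i] - coords.iloc[j])
            for i in range(3) for j in range(3)
        )
        between = np.linalg.norm(ca - cb)
        assert between > within


class TestCorrelationMatrix:
    def test_duplicate_samples_correlate_perfectly(self):
        df = pd.DataFrame({"a": [1.0, 5, 3], "b": [1.0, 5, 3], "c": [3.0, 1, 9]})
        cm = correlation_matrix(df)
        assert cm.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(cm), 1.0)
        assert np.allclose(cm, cm.T)

    def test_anti_correlated_samples(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [-1.0, -2, -3]})
        assert correlation_matrix(df).loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_sample_errors(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(df)
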