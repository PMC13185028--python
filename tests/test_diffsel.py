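"""Negative-binomial differential selection: size factors, dispersions, Wald."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from poolscreen import (
    CountMatrix,
    SampleInfo,
    bh_adjust,
    estimate_size_factors,
    fit_dispersions,
    normalize,
    wald_test,
)
from poolscreen.diffsel import ALPHA_FLOOR, DiffSelError, DispersionFit, _inverse_trigamma

from conftest import make_matrix


class TestSizeFactors:
    def test_identical_columns_are_unit(self, tiny_library):
        samples = [SampleInfo("a", "c", None, 1), SampleInfo("b", "c", None, 2)]
        col = np.array([10, 20, 30, 40, 50, 60, 7, 9])
        m = make_matrix(tiny_library, samples, np.column_stack([col, col]))
        sf = estimate_size_factors(m, set(tiny_library.safe_harbor_ids), n_ctrl_min=2)
        assert np.allclose(sf.factors, [1.0, 1.0])

    def test_doubled_sample(self, tiny_library):
        """Every control doubled in sample 2 -> factors (1/sqrt2, sqrt2).

        Hand median-of-ratios: the geometric mean of (K, 2K) is K*sqrt(2), so
        every control's ratios are (1/sqrt2, sqrt2).
        """
        samples = [SampleInfo("a", "c", None, 1), SampleInfo("b", "c", None, 2)]
        col = np.array([10, 20, 30, 40, 50, 60, 7, 9])
        m = make_matrix(tiny_library, samples, np.column_stack([col, 2 * col]))
        sf = estimate_size_factors(m, set(tiny_library.safe_harbor_ids), n_ctrl_min=2)
        assert np.allclose(sf.factors, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_single_usable_control_equals_its_ratio_vector(self, tiny_library):
        """With one all-positive control, s_j is that guide's own ratio vector
        (checked against a direct median-of-ratios computation)."""
        samples = [SampleInfo("a", "c", None, 1), SampleInfo("b", "c", None, 2)]
        counts = np.ones((8, 2), dtype=int)
        sh1 = tiny_library.guide_ids.index("SH0001")
        sh2 = tiny_library.guide_ids.index("SH0002")
        counts[sh1] = [8, 18]
        counts[sh2] = [0, 5]  # contains a zero -> excluded
        m = make_matrix(tiny_library, samples, counts)
        with pytest.warns(UserWarning):
            sf = estimate_size_factors(m, set(tiny_library.safe_harbor_ids), n_ctrl_min=2)
        geo = np.sqrt(8 * 18)
        assert np.allclose(sf.factors, [8 / geo, 18 / geo])
        assert sf.n_controls_used == 1

    def test_all_zero_controls_error(self, tiny_library):
        samples = [SampleInfo("a", "c", None, 1), SampleInfo("b", "c", None, 2)]
        counts = np.ones((8, 2), dtype=int)
        for g in ("SH0001", "SH0002"):
            counts[tiny_library.guide_ids.index(g)] = [0, 3]
        m = make_matrix(tiny_library, samples, counts)
        with pytest.raises(DiffSelError, match="cannot normalize"):
            estimate_size_factors(m, set(tiny_library.safe_harbor_ids))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.integers(2, 9),
        seed=st.integers(0, 1000),
    )
    def test_scaling_one_sample_scales_factor_ratios(self, scale, seed):
        """Multiplying one sample's counts by c multiplies the RATIO of its
        size factor to any other sample's by exactly c."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 200, size=(25, 3))
        guide_ids = [f"g{i}" for i in range(25)]
        samples = [SampleInfo(f"s{j}", "c", None, j + 1) for j in range(3)]
        m = CountMatrix(guide_ids, samples, counts)
        controls = set(guide_ids[:10])
        sf1 = estimate_size_factors(m, controls, n_ctrl_min=1)
        scaled = counts.copy()
        scaled[:, 1] *= scale
        m2 = CountMatrix(guide_ids, samples, scaled)
        sf2 = estimate_size_factors(m2, controls, n_ctrl_min=1)
        r1 = sf1.factors[1] / sf1.factors[0]
        r2 = sf2.factors[1] / sf2.factors[0]
        assert r2 == pytest.approx(scale * r1, rel=1e-12)


class TestNormalize:
    def test_unit_factors_identity(self, tiny_library, samples_3v2):
        m = make_matrix(tiny_library, samples_3v2, np.arange(40).reshape(8, 5))
        sf = estimate_size_factors(m, set(tiny_library.safe_harbor_ids), n_ctrl_min=2)
        if np.allclose(sf.factors, 1):
            assert np.array_equal(normalize(m, sf), m.counts)

    def test_doubled_sample_controls_equalized(self, tiny_library):
        samples = [SampleInfo("a", "c", None, 1), SampleInfo("b", "c", None, 2)]
        col = np.array([10, 20, 30, 40, 50, 60, 7, 9])
        m = make_matrix(tiny_library, samples, np.column_stack([col, 2 * col]))
        sf = estimate_size_factors(m, set(tiny_library.safe_harbor_ids), n_ctrl_min=2)
        norm_counts = normalize(m, sf)
        sh = [tiny_library.guide_ids.index(g) for g in ("SH0001", "SH0002")]
        assert np.allclose(norm_counts[sh, 0], norm_counts[sh, 1])


class TestBHAdjust:
    def test_textbook_example(self):
        """p=(.01,.02,.03,.04) -> all 0.04 by the step-up formula."""
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_trivial_cases(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])
        assert bh_adjust([]).size == 0

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # family size m=2 (tested only)
        assert out[0] == pytest.approx(0.02)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_direct_step_up_and_is_monotone(self, p):
        """BH equals the direct min_{j>=i}(p_(j) m/j) formula; order-preserving."""
        p = np.asarray(p)
        out = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        sorted_p = p[order]
        direct_sorted = np.minimum.accumulate(
            (sorted_p * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        direct = np.empty(m)
        direct[order] = np.clip(direct_sorted, 0, 1)
        assert np.allclose(out, direct, atol=1e-12)
        i, j = np.argmin(p), np.argmax(p)
        assert out[i] <= out[j] + 1e-12


def two_group_matrix(counts_a, counts_b):
    """One-guide matrix with unit size factors for Wald-test micro-examples."""
    counts = np.array([list(counts_a) + list(counts_b)])
    samples = [
        SampleInfo(f"a{i}", "c", "A", i + 1) for i in range(len(counts_a))
    ] + [SampleInfo(f"b{i}", "c", "B", i + 1) for i in range(len(counts_b))]
    m = CountMatrix(["g1"], samples, counts)
    sf = type("SF", (), {})
    from poolscreen.diffsel import SizeFactors

    return m, SizeFactors(
        factors=np.ones(len(samples)),
        sample_ids=m.sample_ids,
        control_ids=[],
        n_controls_used=0,
    )


def fixed_dispersion_fit(alpha, n_guides=1, residual_df=3, sigma_prior_sq=0.25):
    a = np.full(n_guides, float(alpha))
    return DispersionFit(
        genewise=a.copy(),
        trend_a0=float(alpha),
        trend_a1=0.0,
        final=a.copy(),
        sigma_prior_sq=sigma_prior_sq,
        base_mean=np.ones(n_guides),
        tested=np.ones(n_guides, dtype=bool),
        at_bound=np.zeros(n_guides, dtype=bool),
        residual_df=residual_df,
    )


class TestWaldTest:
    def test_identical_groups_null(self):
        m, sf = two_group_matrix((100, 100, 100), (100, 100))
        disp = fixed_dispersion_fit(0.05)
        t = wald_test(m, sf, disp, ("A", "B"))
        assert abs(t["log2fc"][0]) < 1e-6
        assert t["wald_p"][0] > 0.99

    def test_noiseless_doubling(self):
        """A=(100,100,100), B=(200,200): the NB MLE of the ratio is the ratio
        of means, so log2fc is 1 exactly (up to solver tolerance)."""
        m, sf = two_group_matrix((100, 100, 100), (200, 200))
        disp = fixed_dispersion_fit(ALPHA_FLOOR)
        t = wald_test(m, sf, disp, ("A", "B"))
        assert t["log2fc"][0] == pytest.approx(1.0, abs=0.01)

    def test_contrast_antisymmetry(self):
        m, sf = two_group_matrix((50, 61, 55), (99, 120))
        disp = fixed_dispersion_fit(0.07)
        fwd = wald_test(m, sf, disp, ("A", "B"))
        rev = wald_test(m, sf, disp, ("B", "A"))
        assert fwd["log2fc"][0] == pytest.approx(-rev["log2fc"][0], abs=1e-9)
        assert fwd["wald_p"][0] == pytest.approx(rev["wald_p"][0], abs=1e-12)

    def test_all_zero_guide_untested(self):
        m, sf = two_group_matrix((0, 0, 0), (0, 0))
        disp = fixed_dispersion_fit(0.05)
        t = wald_test(m, sf, disp, ("A", "B"))
        assert not t["tested"][0]
        assert np.isnan(t["log2fc"][0]) and np.isnan(t["wald_p"][0])

    def test_against_independent_nb_glm_oracle(self):
        """Fixed 3-vs-2 table: p matches an independently coded likelihood
        maximization with a finite-difference Hessian, to 1e-6."""
        counts_a, counts_b, alpha = (50, 60, 55), (10, 12), 0.05
        m, sf = two_group_matrix(counts_a, counts_b)
        disp = fixed_dispersion_fit(alpha)
        t = wald_test(m, sf, disp, ("A", "B"))

        # oracle: full NB log-likelihood in (b0, b1), Nelder-Mead maximization
        k = np.array(counts_a + counts_b, dtype=float)
        x = np.array([0, 0, 0, 1, 1], dtype=float)
        r = 1.0 / alpha

        def negll(beta):
            mu = np.exp(beta[0] + beta[1] * x)
            return -stats.nbinom.logpmf(k, r, r / (r + mu)).sum()

        res = optimize.minimize(
            negll, x0=[np.log(50), -1.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        b1 = res.x[1]
        h = 1e-5
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                e_i, e_j = np.eye(2)[i] * h, np.eye(2)[j] * h
                hess[i, j] = (
                    negll(res.x + e_i + e_j)
                    - negll(res.x + e_i - e_j)
                    - negll(res.x - e_i + e_j)
                    + negll(res.x - e_i - e_j)
                ) / (4 * h * h)
        se_b1 = np.sqrt(np.linalg.inv(hess)[1, 1])
        z_oracle = b1 / se_b1
        p_oracle = 2 * stats.t.sf(abs(z_oracle), disp.effective_df)

        assert t["log2fc"][0] == pytest.approx(b1 / np.log(2), abs=1e-5)
        assert t["se"][0] == pytest.approx(se_b1 / np.log(2), rel=1e-4)
        assert t["wald_p"][0] == pytest.approx(p_oracle, abs=1e-6)


def nb_matrix(rng, n_guides, mean_low, mean_high, alpha, design=(3, 2)):
    """Simulated two-group NB counts with equal group means (pure null)."""
    mu = rng.uniform(mean_low, mean_high, size=n_guides)
    n = sum(design)
    if alpha > 0:
        lam = rng.gamma(1.0 / alpha, scale=alpha * mu[:, None], size=(n_guides, n))
    else:
        lam = np.repeat(mu[:, None], n, axis=1)
    counts = rng.poisson(lam)
    guide_ids = [f"g{i}" for i in range(n_guides)]
    samples = [SampleInfo(f"a{i}", "c", "A", i + 1) for i in range(design[0])] + [
        SampleInfo(f"b{i}", "c", "B", i + 1) for i in range(design[1])
    ]
    return CountMatrix(guide_ids, samples, counts)


class TestDispersions:
    def test_poisson_data_small_dispersion(self):
        """Counts simulated Poisson (true alpha=0): median final alpha <= 0.05."""
        rng = np.random.default_rng(42)
        m = nb_matrix(rng, 1000, 500, 2000, alpha=0.0)
        from poolscreen.diffsel import SizeFactors

        sf = SizeFactors(np.ones(5), m.sample_ids, [], 0)
        labels = [s.group for s in m.samples]
        disp = fit_dispersions(m, sf, labels)
        assert np.nanmedian(disp.final) <= 0.05

    def test_true_dispersion_recovered(self):
        """True alpha=0.1 at means >= 100: median final alpha in [0.05, 0.2]."""
        rng = np.random.default_rng(43)
        m = nb_matrix(rng, 1000, 100, 2000, alpha=0.1)
        from poolscreen.diffsel import SizeFactors

        sf = SizeFactors(np.ones(5), m.sample_ids, [], 0)
        disp = fit_dispersions(m, sf, [s.group for s in m.samples])
        assert 0.05 <= np.nanmedian(disp.final) <= 0.2

    def test_all_zero_guide_untested(self):
        rng = np.random.default_rng(44)
        m = nb_matrix(rng, 50, 50, 100, alpha=0.05)
        counts = m.counts.copy()
        counts[7] = 0
        m2 = CountMatrix(m.guide_ids, m.samples, counts)
        from poolscreen.diffsel import SizeFactors

        sf = SizeFactors(np.ones(5), m2.sample_ids, [], 0)
        disp = fit_dispersions(m2, sf, [s.group for s in m2.samples])
        assert not disp.tested[7]
        assert np.isnan(disp.final[7])

    def test_inverse_trigamma(self):
        from scipy.special import polygamma

        for v in (0.05, 0.25, 1.0, 3.0):
            x = _inverse_trigamma(v)
            assert polygamma(1, x) == pytest.approx(v, rel=1e-9)


def test_null_pvalues_uniform_small():
    """Pure-null NB data: Wald p approximately uniform (KS < 0.05, 3 seeds)."""
    from poolscreen.diffsel import SizeFactors, bh_adjust

    ks = []
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        m = nb_matrix(rng, 1000, 200, 2000, alpha=0.05)
        sf = SizeFactors(np.ones(5), m.sample_ids, [], 0)
        disp = fit_dispersions(m, sf, [s.group for s in m.samples])
        t = wald_test(m, sf, disp, ("A", "B"))
        p = t["wald_p"].dropna().to_numpy()
        ks.append(stats.kstest(p, "uniform").statistic)
    assert np.mean(ks) < 0.05
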