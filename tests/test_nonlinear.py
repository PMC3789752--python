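"""Chaos pipeline: titration, embedding, Lyapunov, dimension, surrogates."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respchaos import fixtures, nonlinear as nl


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def benettin_henon_lle(n=50_000, a=1.4, b=0.3):
    """Jacobian-product Lyapunov exponent of the Hénon map."""
    x, y = 0.1, 0.0
    v = np.array([1.0, 0.0])
    acc = 0.0
    for _ in range(200):
        x, y = 1 - a * x * x + y, b * x
    for _ in range(n):
        jac = np.array([[-2 * a * x, 1.0], [b, 0.0]])
        x, y = 1 - a * x * x + y, b * x
        v = jac @ v
        nv = np.hypot(*v)
        acc += math.log(nv)
        v /= nv
    return acc / n


def naive_correlation_integral(series, tau, m, theiler, radii):
    """All-pairs double loop with Chebyshev norm."""
    y = np.asarray(series, dtype=float)
    n_vec = y.size - (m - 1) * tau
    vecs = [y[i: i + (m - 1) * tau + 1: tau] for i in range(n_vec)]
    counts = np.zeros(len(radii))
    pairs = 0
    for i in range(n_vec):
        for j in range(i + theiler + 1, n_vec):
            d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
            pairs += 1
            for k, r in enumerate(radii):
                if d <= r:
                    counts[k] += 1
    return counts / pairs


def exhaustive_wilcoxon(diffs):
    """Two-sided signed-rank p by full enumeration of 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    stat = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, ranks.sum() - w) <= stat:
            count += 1
    return stat, count / 2**n


# --------------------------------------------------------------------------
# Volterra titration
# --------------------------------------------------------------------------

class TestVolterra:
    def test_logistic_nonlinear_model_wins(self):
        x = fixtures.gen_logistic(250, x0=0.123)
        fit = nl.fit_volterra(x)
        assert fit.sse_nonlinear < fit.sse_linear
        assert nl.detect_nonlinearity(x)

    def test_ar2_linear_null_retained(self):
        hits = sum(
            nl.detect_nonlinearity(fixtures.gen_ar_linear(250, [0.6, -0.3], seed=s))
            for s in range(40)
        )
        assert hits <= 2

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="too short"):
            nl.fit_volterra(np.arange(30, dtype=float))

    def test_constant_series_not_nonlinear(self):
        with pytest.warns(UserWarning):
            assert not nl.detect_nonlinearity(np.ones(100))

    def test_rank_deficient_terms_dropped(self):
        # two identical lags arise for a period-2 series: collinear columns
        y = np.tile([0.2, 0.9], 80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = nl.fit_volterra(y, kappa=4, degree=2)
        assert fit.n_obs > 0


class TestTitration:
    def test_linear_series_nl_zero(self):
        x = fixtures.gen_ar_linear(250, [0.6, -0.3], seed=0)
        res = nl.titrate(x, nl.TitrationConfig(seed=0))
        assert res.NL == 0.0
        assert not res.nonlinear_detected

    def test_logistic_nl_positive(self):
        x = fixtures.gen_logistic(250, x0=0.123)
        res = nl.titrate(x, nl.TitrationConfig(seed=0))
        assert res.NL > 0
        assert res.nonlinear_detected
        assert len(res.per_repeat) == 5

    def test_repeat_average(self):
        x = fixtures.gen_logistic(250, x0=0.37)
        res = nl.titrate(x, nl.TitrationConfig(seed=3, repeats=3))
        assert res.NL == pytest.approx(np.mean(res.per_repeat))


# --------------------------------------------------------------------------
# Embedding selection
# --------------------------------------------------------------------------

class TestEmbedding:
    def test_lag_ar1_analytic(self):
        # AR(1) with phi=0.3: rho(1)=0.3 < 1/e, so the first drop is lag 1
        x = fixtures.gen_ar_linear(20_000, [0.3], seed=1)
        assert nl.estimate_lag(x) == 1

    def test_lag_sinusoid_analytic(self):
        # smallest k with cos(2 pi k / 100) < 1/e is k = 20
        s = np.sin(2 * np.pi * np.arange(3000) / 100)
        assert nl.estimate_lag(s) == 20

    def test_lag_constant_errors(self):
        with pytest.raises(ValueError):
            nl.estimate_lag(np.ones(100))

    def test_lag_never_drops_errors(self):
        # an unreachable threshold exercises the no-drop error path
        x = fixtures.gen_ar_linear(100, [0.6], seed=0)
        with pytest.raises(ValueError, match="manually"):
            nl.estimate_lag(x, threshold=-1.1)

    def test_fnn_logistic_low_dimension(self, logistic_series):
        assert nl.fnn_dimension(logistic_series[:2000], 1) <= 2

    def test_fnn_sinusoid_plane(self):
        s = np.sin(2 * np.pi * np.arange(1000) / 100)
        assert nl.fnn_dimension(s, 25) == 2

    def test_fnn_noise_warns_mmax(self, rng):
        with pytest.warns(UserWarning):
            assert nl.fnn_dimension(rng.normal(size=1000), 1, m_max=6) == 6


# --------------------------------------------------------------------------
# Largest Lyapunov exponent
# --------------------------------------------------------------------------

class TestLLE:
    def test_logistic_ln2(self, logistic_series):
        res = nl.lle_rosenstein(
            logistic_series, nl.EmbeddingSpec(tau_embed=1, m=1, theiler=1)
        )
        assert res.lambda_L == pytest.approx(math.log(2), rel=0.10)

    def test_sinusoid_flat(self):
        s = np.sin(2 * np.pi * np.arange(5000) / 100)
        res = nl.lle_rosenstein(s, nl.EmbeddingSpec(tau_embed=25, m=2))
        assert res.lambda_L <= 0.02

    def test_henon_matches_benettin(self, henon_series):
        oracle = benettin_henon_lle()
        res = nl.lle_rosenstein(
            henon_series, nl.EmbeddingSpec(tau_embed=1, m=2, theiler=2)
        )
        assert abs(res.lambda_L - oracle) / oracle < 0.15

    def test_fit_range_inside_curve(self, logistic_series):
        res = nl.lle_rosenstein(
            logistic_series, nl.EmbeddingSpec(tau_embed=1, m=1, theiler=1)
        )
        lo, hi = res.fit_range
        assert 0 <= lo < hi <= res.steps.size

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            nl.lle_rosenstein(np.arange(6, dtype=float),
                              nl.EmbeddingSpec(tau_embed=1, m=2, theiler=5))


# --------------------------------------------------------------------------
# Correlation integral and dimension
# --------------------------------------------------------------------------

class TestCorrelationIntegral:
    def test_saturates_to_one(self, logistic_series):
        spec = nl.EmbeddingSpec(tau_embed=1, m=2, theiler=0)
        c = nl.correlation_integral(logistic_series[:300], spec, [10.0])
        assert c[0] == 1.0

    def test_vanishes_at_small_r(self, logistic_series):
        spec = nl.EmbeddingSpec(tau_embed=1, m=2, theiler=0)
        c = nl.correlation_integral(logistic_series[:300], spec, [1e-12])
        assert c[0] == 0.0

    @pytest.mark.parametrize("n,theiler", [(100, 0), (100, 3), (200, 1)])
    def test_matches_naive_double_loop(self, logistic_series, n, theiler):
        series = logistic_series[:n]
        radii = np.geomspace(1e-3, 1.5, 12)
        spec = nl.EmbeddingSpec(tau_embed=1, m=2, theiler=theiler)
        fast = nl.correlation_integral(series, spec, radii)
        slow = naive_correlation_integral(series, 1, 2, theiler, radii)
        np.testing.assert_array_equal(fast, slow)

    def test_monotone_in_r(self, henon_series):
        spec = nl.EmbeddingSpec(tau_embed=1, m=2, theiler=2)
        radii = np.geomspace(1e-3, 3.0, 20)
        c = nl.correlation_integral(henon_series[:1500], spec, radii)
        assert np.all(np.diff(c) >= 0)

    def test_bad_radii(self):
        spec = nl.EmbeddingSpec()
        with pytest.raises(ValueError):
            nl.correlation_integral(np.arange(50.0), spec, [0.5, 0.2])


class TestCorrelationDimension:
    def test_uniform_interval_dimension_one(self, rng):
        u = rng.uniform(0, 1, 2000)
        res = nl.correlation_dimension(u, nl.EmbeddingSpec(tau_embed=1, m=1,
                                                           theiler=0))
        assert res.D_corr == pytest.approx(1.0, abs=0.1)

    def test_sinusoid_closed_curve(self):
        s = np.sin(2 * np.pi * np.arange(2000) / 100)
        res = nl.correlation_dimension(s, nl.EmbeddingSpec(tau_embed=25, m=2))
        assert res.D_corr == pytest.approx(1.0, abs=0.2)

    def test_henon_against_gp_oracle(self, henon_series):
        from scipy.spatial.distance import cdist

        ours = nl.correlation_dimension(
            henon_series[:5000], nl.EmbeddingSpec(tau_embed=1, m=2, theiler=2)
        )
        # independent large-n oracle: direct pair counting over fixed
        # mid-range radii via cdist, slope of the ln-ln relation
        y = henon_series
        vecs = np.column_stack([y[:-1], y[1:]])
        radii = np.geomspace(0.005, 0.1, 10)
        counts = np.zeros(radii.size)
        pairs = 0
        theiler = 2
        chunk = 500
        for start in range(0, vecs.shape[0], chunk):
            d = cdist(vecs[start: start + chunk], vecs, metric="chebyshev")
            ii = np.arange(start, min(start + chunk, vecs.shape[0]))[:, None]
            jj = np.arange(vecs.shape[0])[None, :]
            sel = d[jj > ii + theiler]
            pairs += sel.size
            counts += (sel[None, :] <= radii[:, None]).sum(axis=1)
        oracle = np.polyfit(np.log(radii), np.log(counts / pairs), 1)[0]
        assert abs(ours.D_corr - oracle) < 0.05


# --------------------------------------------------------------------------
# Surrogates and the paired test
# --------------------------------------------------------------------------

class TestSurrogates:
    def test_amplitude_spectrum_preserved(self, logistic_series):
        x = logistic_series[:512]
        surr = nl.make_surrogates(x, count=5, seed=0)
        amp = np.abs(np.fft.rfft(x))
        for s in surr:
            np.testing.assert_allclose(np.abs(np.fft.rfft(s)), amp,
                                       rtol=1e-8, atol=1e-12)

    def test_mean_preserved(self, logistic_series):
        x = logistic_series[:500]
        surr = nl.make_surrogates(x, count=3, seed=1)
        np.testing.assert_allclose(surr.mean(axis=1), x.mean(), atol=1e-10)

    def test_nonlinear_structure_destroyed(self, logistic_series):
        x = logistic_series[:250]
        surr = nl.make_surrogates(x, count=20, seed=2)
        hits = sum(nl.detect_nonlinearity(s) for s in surr)
        assert hits <= 1

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n=st.integers(16, 200), seed=st.integers(0, 99))
    def test_spectrum_property(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        s = nl.make_surrogates(x, count=1, seed=seed)[0]
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(s)), np.abs(np.fft.rfft(x)), rtol=1e-8,
            atol=1e-10,
        )


class TestSurrogateTest:
    def test_identical_pairs(self):
        with pytest.warns(UserWarning):
            stat, p = nl.surrogate_test([1.0] * 6, [1.0] * 6)
        assert stat == 0.0 and p == 1.0

    def test_five_positive_differences_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        stat, p = nl.surrogate_test(a, b)
        # one-sided exact 1/32; two-sided doubles it
        assert p == pytest.approx(2 / 32)

    def test_n12_matches_enumeration(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(scale=0.5, size=12)
        stat, p = nl.surrogate_test(a, b)
        stat_o, p_o = exhaustive_wilcoxon(a - b)
        assert stat == pytest.approx(stat_o)
        assert p == pytest.approx(p_o)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            nl.surrogate_test([1.0, 2.0], [1.0, 2.0])
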