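import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from morphoprofile.families import (CANDIDATES, DegenerateDataError,
                                    SupportError, fit_family, loglik,
                                    select_family)


def profile_gamma_mle(y, n_grid=4000):
    """Independent grid-search MLE for gamma: profile over shape, closed-form
    scale given shape."""
    y = np.asarray(y)
    ks = np.exp(np.linspace(np.log(0.05), np.log(500), n_grid))
    scale = y.mean() / ks
    ll = [stats.gamma.logpdf(y, k, scale=s).sum() for k, s in zip(ks, scale)]
    j = int(np.argmax(ll))
    return ks[j], scale[j]


class TestFitFamily:
    def test_gaussian_closed_form(self):
        f = fit_family([-1.0, 0.0, 1.0], "gaussian")
        assert f.params["mu"] == pytest.approx(0.0)
        assert f.params["sigma"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert f.aic == pytest.approx(-2 * f.loglik + 4)

    def test_binomial_pooled_closed_form(self, rng):
        t = rng.integers(50, 300, 40).astype(float)
        k = rng.binomial(t.astype(int), 0.27).astype(float)
        f = fit_family(k, "binomial", trials=t)
        assert f.params["p"] == pytest.approx(k.sum() / t.sum(), rel=1e-9)
        assert f.aic == pytest.approx(-2 * f.loglik + 2)

    def test_gamma_matches_grid_search_oracle(self, rng):
        y = rng.gamma(3.0, 2.0, 2000)
        f = fit_family(y, "gamma")
        k_oracle, s_oracle = profile_gamma_mle(y)
        assert f.params["shape"] == pytest.approx(k_oracle, rel=0.10)
        assert f.params["scale"] == pytest.approx(s_oracle, rel=0.10)

    @pytest.mark.parametrize("family,sampler,scipy_ref", [
        ("weibull", lambda r, n: 2.0 * r.weibull(1.7, n),
         lambda y: stats.weibull_min.fit(y, floc=0)),
        ("logistic", lambda r, n: r.logistic(1.0, 0.5, n),
         lambda y: stats.logistic.fit(y)),
        ("reverse_gumbel", lambda r, n: -r.gumbel(-2.0, 0.7, n),
         lambda y: stats.gumbel_l.fit(y)),
        ("beta", lambda r, n: r.beta(2.0, 5.0, n),
         lambda y: stats.beta.fit(y, floc=0, fscale=1)),
    ])
    def test_mle_agrees_with_scipy(self, rng, family, sampler, scipy_ref):
        """Our profile solvers land on the same optimum as scipy's fit."""
        y = sampler(rng, 1500)
        f = fit_family(y, family)
        ours = loglik(family, f.params, y)
        ref_params = scipy_ref(y)
        ref = {
            "weibull": lambda p: stats.weibull_min.logpdf(y, p[0], scale=p[2]).sum(),
            "logistic": lambda p: stats.logistic.logpdf(y, *p).sum(),
            "reverse_gumbel": lambda p: stats.gumbel_l.logpdf(y, *p).sum(),
            "beta": lambda p: stats.beta.logpdf(y, p[0], p[1]).sum(),
        }[family](ref_params)
        assert ours >= ref - 1e-4 * abs(ref)

    def test_degenerate_data_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_family([2.0, 2.0, 2.0, 2.0], "gamma")
        with pytest.raises(DegenerateDataError, match="3 observations"):
            fit_family([1.0, 2.0], "gaussian")

    def test_support_violation_raises(self):
        with pytest.raises(SupportError):
            fit_family([0.2, -0.1, 0.5, 0.3], "gamma")
        with pytest.raises(SupportError):
            fit_family([0.2, 1.2, 0.5, 0.3], "beta")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10),
       seed=st.integers(0, 10_000))
def test_location_family_fits_are_shift_scale_equivariant(shift, scale, seed):
    """Affine-transforming the data moves the fitted location/scale of a
    location-scale family accordingly."""
    r = np.random.default_rng(seed)
    y = r.logistic(0.0, 1.0, 120)
    base = fit_family(y, "logistic")
    moved = fit_family(y * scale + shift, "logistic")
    assert moved.params["loc"] == pytest.approx(
        base.params["loc"] * scale + shift, rel=1e-5, abs=1e-5 * scale)
    assert moved.params["scale"] == pytest.approx(
        base.params["scale"] * scale, rel=1e-5)


class TestLoglik:
    def test_gaussian_standard_at_zero(self):
        want = -0.5 * np.log(2 * np.pi)
        assert loglik("gaussian", {"mu": 0, "sigma": 1}, [0.0]) == pytest.approx(want)

    def test_reverse_gumbel_translation_invariance(self, rng):
        y = -rng.gumbel(0, 1, 50)
        base = loglik("reverse_gumbel", {"loc": 0.3, "scale": 1.1}, y)
        for c in (-5.0, 0.7, 12.0):
            shifted = loglik("reverse_gumbel", {"loc": 0.3 + c, "scale": 1.1}, y + c)
            assert shifted == pytest.approx(base, rel=1e-12)

    def test_beta_binomial_limits_to_binomial(self, rng):
        t = rng.integers(50, 200, 30).astype(float)
        k = rng.binomial(t.astype(int), 0.4).astype(float)
        lb = loglik("binomial", {"p": 0.4}, k, trials=t)
        lbb = loglik("beta_binomial", {"p": 0.4, "rho": 1e-8}, k, trials=t)
        assert lbb == pytest.approx(lb, abs=1e-4)

    def test_out_of_support_is_minus_inf(self):
        assert loglik("gamma", {"shape": 2, "scale": 1}, [1.0, -1.0]) == -np.inf

    @pytest.mark.parametrize("family,params", [
        ("gamma", {"shape": 3.0, "scale": 2.0}),
        ("inverse_gamma", {"shape": 4.0, "scale": 3.0}),
        ("weibull", {"shape": 1.5, "scale": 2.0}),
        ("beta", {"alpha": 2.0, "beta": 5.0}),
        ("logit_normal", {"mu": 0.4, "sigma": 0.8}),
        ("gaussian", {"mu": 0.0, "sigma": 1.3}),
        ("logistic", {"loc": 0.5, "scale": 0.9}),
        ("reverse_gumbel", {"loc": 1.0, "scale": 0.6}),
    ])
    def test_density_integrates_to_one(self, family, params):
        support = {
            "gamma": (0, np.inf), "inverse_gamma": (0, np.inf),
            "weibull": (0, np.inf), "beta": (0, 1), "logit_normal": (0, 1),
            "gaussian": (-np.inf, np.inf), "logistic": (-np.inf, np.inf),
            "reverse_gumbel": (-np.inf, np.inf),
        }[family]
        val, err = integrate.quad(
            lambda x: np.exp(loglik(family, params, [x])), *support, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_count_pmfs_sum_to_one(self):
        t = 40.0
        ks = np.arange(0, 41, dtype=float)
        for fam, params in [("binomial", {"p": 0.3}),
                            ("beta_binomial", {"p": 0.3, "rho": 0.05})]:
            tot = sum(np.exp(loglik(fam, params, [k], trials=[t])) for k in ks)
            assert tot == pytest.approx(1.0, abs=1e-9)


class TestSelectFamily:
    def test_candidate_sets_follow_data_type(self, rng):
        y = rng.beta(3, 4, 300)
        f = select_family(y, "ratio")
        assert set(f.candidates) == {"beta", "logit_normal"}
        y = rng.gamma(10, 1, 300)
        f = select_family(y, "nonneg")
        assert set(f.candidates) == {"gamma", "inverse_gamma", "weibull"}
        assert CANDIDATES["noise"] == ("gaussian", "logistic", "reverse_gumbel")
        assert CANDIDATES["proportion"] == ("binomial", "beta_binomial")

    def test_weibull_recovered_in_most_repetitions(self):
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            y = 2.0 * r.weibull(1.5, 1000)
            f = select_family(y, "nonneg")
            # AIC bookkeeping agrees with a direct computation per candidate
            for name, d in f.candidates.items():
                if "aic" in d:
                    direct = -2 * loglik(name, d["params"], y) + 2 * 2
                    assert d["aic"] == pytest.approx(direct, rel=1e-9)
            hits += f.spec.name == "weibull"
        assert hits >= 90

    def test_binomial_beats_beta_binomial_without_overdispersion(self):
        wins = 0
        for rep in range(100):
            r = np.random.default_rng(1000 + rep)
            t = r.integers(100, 300, 100).astype(float)
            k = r.binomial(t.astype(int), 0.35).astype(float)
            f = select_family(k, "proportion", trials=t)
            wins += f.spec.name == "binomial"
        assert wins > 50

    def test_nested_pair_loglik_ordering(self, rng):
        t = rng.integers(100, 300, 120).astype(float)
        k = rng.binomial(t.astype(int), rng.beta(20, 40, 120)).astype(float)
        f = select_family(k, "proportion", trials=t)
        lb = f.candidates["binomial"]["loglik"]
        lbb = f.candidates["beta_binomial"]["loglik"]
        assert lbb >= lb - 1e-6

    def test_selection_accuracy_monotone_in_n(self):
        """More data makes AIC pick the true family at least as often."""
        acc = {}
        for n in (50, 200, 1000):
            hits = 0
            for rep in range(40):
                r = np.random.default_rng(77 * n + rep)
                y = r.gamma(4.0, 1.5, n)
                hits += select_family(y, "nonneg").spec.name == "gamma"
            acc[n] = hits / 40
        assert acc[200] >= acc[50] - 0.05
        assert acc[1000] >= acc[200] - 0.05
        assert acc[1000] >= acc[50]
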