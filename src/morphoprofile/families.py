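"""Unimodal distribution families for morphological parameters.

CalMorph-style morphological parameters fall into four data types, each served
by a small set of candidate unimodal families:

=============  =================================================
data type      candidate families
=============  =================================================
nonneg         gamma, inverse_gamma, weibull          (log link)
ratio          beta, logit_normal                     (logit / logit-scale identity link)
noise          gaussian, logistic, reverse_gumbel     (identity link)
proportion     binomial, beta_binomial                (logit link)
=============  =================================================

The best family per parameter is chosen by AIC (``select_family``).  Every
family exposes a *location* parameter on its link scale plus at most one
shared nuisance parameter; this is the parameterization the two-group Wald
test in :mod:`morphoprofile.differential` perturbs.

Fitting is exact-profile maximum likelihood: group locations are solved in
closed form or by a monotone 1-D Newton/bisection given the nuisance
parameter, and the nuisance is solved on its 1-D profile score.  All solvers
are vectorized over a batch axis so that thousands of fits (e.g. permutation
replicates) run as single numpy programs.

``logit_normal`` is a Gaussian on logit-transformed values *with* the change
of variables Jacobian included, so its log-likelihood — and hence its AIC —
is comparable to ``beta`` on the original (0,1) scale.  ``reverse_gumbel`` is
the Gumbel distribution for minima (left-skewed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, polygamma, gammaln, expit, logit

__all__ = [
    "FamilySpec",
    "FamilyFit",
    "FAMILIES",
    "CANDIDATES",
    "get_family",
    "fit_family",
    "select_family",
    "loglik",
    "DegenerateDataError",
    "SupportError",
    "SelectionError",
]

_TINY = 1e-12


class DegenerateDataError(ValueError):
    """All observations equal (or otherwise zero-information data)."""


class SupportError(ValueError):
    """Values outside the family's support."""


class SelectionError(RuntimeError):
    """No candidate family produced a valid fit."""


@dataclass(frozen=True)
class FamilySpec:
    """Identity card of one unimodal family."""

    name: str
    data_type: str            # nonneg | ratio | noise | proportion
    link: str                 # log | logit | identity
    param_names: tuple        # natural-scale parameter names
    n_free: int               # free parameters counted by AIC


@dataclass
class FamilyFit:
    """Maximum-likelihood fit of one family to one sample."""

    spec: FamilySpec
    params: dict
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    # per-candidate diagnostics, populated by select_family
    candidates: dict = field(default_factory=dict)


def _as2d(x):
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def _gsum(W, x):
    """Masked sum over the observation axis."""
    return np.einsum("...n,...n->...", W, x)


def _root1d(f, a, b, fa, fb, iters=30, tol=1e-9):
    """Vectorized Illinois (modified regula falsi) root finder.

    Assumes a decreasing score with fa >= 0 >= fb elementwise; rows whose
    bracket does not change sign converge to the nearer endpoint.
    """
    side = np.zeros_like(a)                    # -1: a updated last, +1: b
    for _ in range(iters):
        denom = fa - fb
        x = np.where(np.abs(denom) > 1e-300, a + fa * (b - a) / denom,
                     0.5 * (a + b))
        x = np.where((x > a) & (x < b), x, 0.5 * (a + b))
        fx = f(x)
        pos = fx > 0
        fa = np.where(pos, fx, np.where(side == 1, 0.5 * fa, fa))
        fb = np.where(pos, np.where(side == -1, 0.5 * fb, fb), fx)
        a = np.where(pos, x, a)
        b = np.where(pos, b, x)
        side = np.where(pos, -1.0, 1.0)
        if np.all(b - a < tol):
            break
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# family implementations
# ---------------------------------------------------------------------------

class _Base:
    spec: FamilySpec
    n_nuis = 1

    # -- log density -------------------------------------------------------
    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        """Per-observation log density; eta is the location on the link scale,
        nuis the shared nuisance (natural scale, broadcastable)."""
        raise NotImplementedError

    # -- profile fit over G groups ------------------------------------------
    @classmethod
    def fit_groups(cls, y, W, trials=None):
        """Return (eta (B,G), nuis (B,) or None, ok (B,)) for group masks W (G,B,n)."""
        raise NotImplementedError

    @classmethod
    def loglik_groups(cls, y, W, eta, nuis, trials=None):
        """Total log-likelihood of the fitted two-group model, (B,).

        Generic path: evaluate per-observation terms; overridden with
        sufficient-statistic forms where that avoids full-array passes.
        """
        loc = np.where(W[1] > 0, eta[:, 1, None], eta[:, 0, None])
        nu = None if nuis is None else nuis[:, None]
        terms = cls.loglik_terms(y, loc, nu, trials)
        V = W[0] + W[1]
        return np.einsum("bn,bn->b", V, np.where(np.isfinite(terms), terms, -1e30))

    # -- observed information ------------------------------------------------
    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        """Observed information (negative log-likelihood Hessian) at the MLE,
        in (eta0, eta1, nuisance) coordinates; shape (B, p, p).

        The two group locations never share observations, so the (0,1)
        block is exactly zero for every family.
        """
        raise NotImplementedError

    @classmethod
    def support_mask(cls, y, trials=None):
        return np.isfinite(y)

    # -- natural-scale params for reporting ---------------------------------
    @classmethod
    def natural_params(cls, eta, nuis):
        raise NotImplementedError

    @classmethod
    def from_natural(cls, params):
        """(eta, nuis) from a natural-parameter dict."""
        raise NotImplementedError


class _Gaussian(_Base):
    spec = FamilySpec("gaussian", "noise", "identity", ("mu", "sigma"), 2)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        s = np.maximum(nuis, _TINY)
        return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * ((y - eta) / s) ** 2

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        n_g = W.sum(axis=-1)                      # (G,B)
        mu = _gsum(W, y) / np.maximum(n_g, _TINY)
        sse = sum(_gsum(W[g], (y - mu[g][..., None]) ** 2) for g in range(len(W)))
        n = n_g.sum(axis=0)
        var = sse / np.maximum(n, _TINY)
        ok = var > _TINY
        return mu.T, np.sqrt(np.maximum(var, _TINY)), ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        # at the MLE the location-scale cross terms vanish
        n_g = W.sum(axis=-1)                       # (G,B)
        n = n_g.sum(axis=0)
        s2 = np.maximum(nuis, _TINY) ** 2
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        I[:, 0, 0] = n_g[0] / s2
        I[:, 1, 1] = n_g[1] / s2
        I[:, 2, 2] = 2.0 * n / s2
        return I

    @classmethod
    def loglik_groups(cls, y, W, eta, nuis, trials=None):
        n_g = W.sum(axis=-1)
        n = n_g.sum(axis=0)
        s2 = np.maximum(nuis, _TINY) ** 2
        sse = np.zeros(eta.shape[0])
        for g in range(2):
            sse += _gsum(W[g], (y - eta[:, g, None]) ** 2)
        return -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * sse / s2

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"mu": eta, "sigma": nuis}

    @classmethod
    def from_natural(cls, p):
        return p["mu"], p["sigma"]

    @classmethod
    def from_natural(cls, p):
        return p["mu"], p["sigma"]


class _LogitNormal(_Base):
    spec = FamilySpec("logit_normal", "ratio", "logit", ("mu", "sigma"), 2)

    @classmethod
    def support_mask(cls, y, trials=None):
        return np.isfinite(y) & (y > 0) & (y < 1)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        yc = np.clip(y, _TINY, 1 - 1e-12)
        t = logit(yc)
        jac = -np.log(yc) - np.log1p(-yc)
        return _Gaussian.loglik_terms(t, eta, nuis) + jac

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        t = logit(np.clip(y, _TINY, 1 - 1e-12))
        eta, s, ok = _Gaussian.fit_groups(t, W)
        return eta, s, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        # Jacobian term is parameter-free: gaussian information on logit scale
        return _Gaussian.observed_info(y, W, eta, nuis)

    @classmethod
    def loglik_groups(cls, y, W, eta, nuis, trials=None):
        yc = np.clip(y, _TINY, 1 - 1e-12)
        t = logit(yc)
        jac = -_gsum(W[0] + W[1], np.log(yc) + np.log1p(-yc))
        return _Gaussian.loglik_groups(t, W, eta, nuis) + jac

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"mu": eta, "sigma": nuis}

    @classmethod
    def from_natural(cls, p):
        return p["mu"], p["sigma"]


class _Logistic(_Base):
    spec = FamilySpec("logistic", "noise", "identity", ("loc", "scale"), 2)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        s = np.maximum(nuis, _TINY)
        z = (y - eta) / s
        az = np.abs(z)
        return -az - 2 * np.log1p(np.exp(-az)) - np.log(s)

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        G = len(W)
        n_g = np.maximum(W.sum(axis=-1), _TINY)
        mu = _gsum(W, y) / n_g                     # (G,B) init: group means
        n = n_g.sum(axis=0)
        sse = sum(_gsum(W[g], (y - mu[g][..., None]) ** 2) for g in range(G))
        var = sse / np.maximum(n, _TINY)
        ok = var > _TINY
        s = np.sqrt(np.maximum(var, _TINY)) * (np.sqrt(3) / np.pi)

        def dl_ds(s):
            tot = np.zeros_like(s)
            for g in range(G):
                z = (y - mu[g][..., None]) / s[..., None]
                tot += _gsum(W[g], -1.0 + z * np.tanh(z / 2)) / s
            return tot

        for it in range(60):
            # location Newton step per group
            delta = 0.0
            for g in range(G):
                z = (y - mu[g][..., None]) / s[..., None]
                t = np.tanh(z / 2)
                u = _gsum(W[g], t) / s
                h = _gsum(W[g], 1.0 - t ** 2) / (2 * s ** 2)
                step = u / np.maximum(h, _TINY)
                mu[g] = mu[g] + step
                delta = np.maximum(delta, np.abs(step))
            # scale: secant step on the profile score in log s
            f0 = dl_ds(s) * s                      # d loglik / d log s
            ls = np.log(s)
            f1 = dl_ds(np.exp(ls + 1e-5)) * np.exp(ls + 1e-5)
            der = (f1 - f0) / 1e-5
            step = np.where(np.abs(der) > _TINY, f0 / der, 0.0)
            step = np.clip(step, -1.0, 1.0)
            s = np.exp(ls - step)
            delta = np.maximum(delta, np.abs(step))
            if np.all(delta < 1e-9):
                break
        return mu.T, s, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        s = np.maximum(nuis, _TINY)
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        h22 = np.zeros(B)
        n = W.sum(axis=-1).sum(axis=0)
        for g in range(2):
            z = (y - eta[:, g, None]) / s[:, None]
            t = np.tanh(z / 2)
            c2 = 1.0 - t ** 2                      # sech^2(z/2)
            St = _gsum(W[g], t)
            Szt = _gsum(W[g], z * t)
            Szc = _gsum(W[g], z * c2)
            Sz2c = _gsum(W[g], z ** 2 * c2)
            Sc = _gsum(W[g], c2)
            I[:, g, g] = Sc / (2 * s ** 2)
            I[:, g, 2] = I[:, 2, g] = (St + Szc / 2) / s ** 2
            h22 += -3.0 * Szt - 0.5 * Sz2c
        I[:, 2, 2] = -(n + h22) / s ** 2
        return I

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"loc": eta, "scale": nuis}

    @classmethod
    def from_natural(cls, p):
        return p["loc"], p["scale"]


_EULER = 0.5772156649015329


class _ReverseGumbel(_Base):
    """Gumbel distribution for minima (left-skewed), identity link on location."""

    spec = FamilySpec("reverse_gumbel", "noise", "identity", ("loc", "scale"), 2)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        s = np.maximum(nuis, _TINY)
        z = np.clip((y - eta) / s, -700, 60)
        return z - np.exp(z) - np.log(s)

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        G = len(W)
        n_g = np.maximum(W.sum(axis=-1), _TINY)
        n = n_g.sum(axis=0)
        mean = _gsum(W, y) / n_g
        sse = sum(_gsum(W[g], (y - mean[g][..., None]) ** 2) for g in range(G))
        var = sse / np.maximum(n, _TINY)
        ok = var > _TINY
        s = np.sqrt(np.maximum(var, _TINY)) * (np.sqrt(6) / np.pi)
        ymax = np.max(y, axis=-1, keepdims=True)
        mu = np.empty_like(mean)

        def locs(s):
            # closed-form location MLE given scale: mu = s*log(mean_g exp(y/s))
            for g in range(G):
                e = np.exp(np.clip((y - ymax) / s[..., None], -700, 0))
                mu[g] = ymax[..., 0] + s * np.log(_gsum(W[g], e) / n_g[g])
            return mu

        def dl_dlogs(s):
            m = locs(s)
            tot = np.zeros_like(s)
            for g in range(G):
                z = np.clip((y - m[g][..., None]) / s[..., None], -700, 60)
                tot += _gsum(W[g], -1.0 - z + z * np.exp(z))
            return tot

        ls = np.log(s)
        for it in range(50):
            f0 = dl_dlogs(np.exp(ls))
            f1 = dl_dlogs(np.exp(ls + 1e-5))
            der = (f1 - f0) / 1e-5
            step = np.where(np.abs(der) > _TINY, f0 / der, 0.0)
            step = np.clip(step, -1.0, 1.0)
            ls = ls - step
            if np.all(np.abs(step) < 1e-11):
                break
        s = np.exp(ls)
        mu = locs(s)
        return mu.T, s, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        s = np.maximum(nuis, _TINY)
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        h22 = np.zeros(B)
        n = W.sum(axis=-1).sum(axis=0)
        for g in range(2):
            z = np.clip((y - eta[:, g, None]) / s[:, None], -700, 60)
            e = np.exp(z)
            Se = _gsum(W[g], e)
            Sze = _gsum(W[g], z * e)
            Sz = _gsum(W[g], np.where(W[g] > 0, z, 0.0))
            Sz2e = _gsum(W[g], z ** 2 * e)
            n_g = W[g].sum(axis=-1)
            I[:, g, g] = Se / s ** 2
            I[:, g, 2] = I[:, 2, g] = (Se - n_g + Sze) / s ** 2
            h22 += 2 * Sz - 2 * Sze - Sz2e
        I[:, 2, 2] = -(n + h22) / s ** 2
        return I

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"loc": eta, "scale": nuis}

    @classmethod
    def from_natural(cls, p):
        return p["loc"], p["scale"]


class _Gamma(_Base):
    spec = FamilySpec("gamma", "nonneg", "log", ("shape", "scale"), 2)

    @classmethod
    def support_mask(cls, y, trials=None):
        return np.isfinite(y) & (y > 0)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        k = np.maximum(nuis, _TINY)
        logy = np.log(np.maximum(y, _TINY))
        return (k * np.log(k) - k * eta - gammaln(k)
                + (k - 1) * logy - k * y * np.exp(-np.clip(eta, -700, 700)))

    @staticmethod
    def _solve_shape(n, C):
        """Solve n*(log k - digamma(k)) = C for k (vectorized Newton)."""
        s = np.maximum(C / np.maximum(n, _TINY), 1e-10)
        k = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
        k = np.clip(k, 1e-3, 1e7)
        for _ in range(40):
            f = n * (np.log(k) - digamma(k)) - C
            fp = n * (1.0 / k - polygamma(1, k))
            step = np.where(np.abs(fp) > _TINY, f / fp, 0.0)
            k = np.clip(k - step, 1e-3, 1e7)
            if np.max(np.abs(step) / k) < 1e-12:
                break
        return k

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        ysafe = np.maximum(y, _TINY)
        logy = np.log(ysafe)
        n_g = np.maximum(W.sum(axis=-1), _TINY)
        mu = np.maximum(_gsum(W, ysafe) / n_g, _TINY)   # empty group -> benign
        n = n_g.sum(axis=0)
        C = (n_g * np.log(mu)).sum(axis=0) - sum(_gsum(Wg, logy) for Wg in W)
        ok = C / np.maximum(n, _TINY) > 1e-10
        k = cls._solve_shape(n, np.maximum(C, _TINY))
        return np.log(mu).T, k, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        # location-shape cross terms vanish at the MLE (mean residuals are 0)
        n_g = W.sum(axis=-1)
        n = n_g.sum(axis=0)
        k = np.maximum(nuis, _TINY)
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        I[:, 0, 0] = k * n_g[0]
        I[:, 1, 1] = k * n_g[1]
        I[:, 2, 2] = n * (polygamma(1, k) - 1.0 / k)
        return I

    @classmethod
    def loglik_groups(cls, y, W, eta, nuis, trials=None):
        k = np.maximum(nuis, _TINY)
        n_g = W.sum(axis=-1)
        n = n_g.sum(axis=0)
        ysafe = np.maximum(y, _TINY)
        slog = _gsum(W[0] + W[1], np.log(ysafe))
        ll = n * (k * np.log(k)) - n * gammaln(k) + (k - 1) * slog
        for g in range(2):
            S = _gsum(W[g], ysafe)
            ll += -k * n_g[g] * eta[:, g] - k * np.exp(-np.clip(eta[:, g], -700, 700)) * S
        return ll

    @classmethod
    def natural_params(cls, eta, nuis):
        mu = np.exp(eta)
        return {"shape": nuis, "scale": mu / nuis}

    @classmethod
    def from_natural(cls, p):
        return np.log(p["shape"] * p["scale"]), p["shape"]


class _InverseGamma(_Base):
    """Inverse gamma; log link on the scale parameter beta (location-like:
    the mean beta/(shape-1) is increasing in beta)."""

    spec = FamilySpec("inverse_gamma", "nonneg", "log", ("shape", "scale"), 2)

    @classmethod
    def support_mask(cls, y, trials=None):
        return np.isfinite(y) & (y > 0)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        a = np.maximum(nuis, _TINY)
        logy = np.log(np.maximum(y, _TINY))
        return (a * eta - gammaln(a) - (a + 1) * logy
                - np.exp(np.clip(eta, -700, 700)) / np.maximum(y, _TINY))

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        # InvGamma(a, b) on y  <=>  Gamma(a, scale=1/b) on 1/y
        x = 1.0 / np.maximum(y, _TINY)
        eta_x, a, ok = _Gamma.fit_groups(x, W)
        # gamma mean mu_x = a/b  =>  log b = log a - eta_x
        eta = np.log(a)[..., None] - eta_x
        return eta, a, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        # d2l/deta2 = -alpha*n_g and d2l/(deta dalpha) = n_g, both exact at MLE
        n_g = W.sum(axis=-1)
        n = n_g.sum(axis=0)
        a = np.maximum(nuis, _TINY)
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        I[:, 0, 0] = a * n_g[0]
        I[:, 1, 1] = a * n_g[1]
        I[:, 0, 2] = I[:, 2, 0] = -n_g[0]
        I[:, 1, 2] = I[:, 2, 1] = -n_g[1]
        I[:, 2, 2] = n * polygamma(1, a)
        return I

    @classmethod
    def loglik_groups(cls, y, W, eta, nuis, trials=None):
        a = np.maximum(nuis, _TINY)
        n_g = W.sum(axis=-1)
        n = n_g.sum(axis=0)
        ysafe = np.maximum(y, _TINY)
        slog = _gsum(W[0] + W[1], np.log(ysafe))
        ll = -n * gammaln(a) - (a + 1) * slog
        for g in range(2):
            S = _gsum(W[g], 1.0 / ysafe)
            ll += a * n_g[g] * eta[:, g] - np.exp(np.clip(eta[:, g], -700, 700)) * S
        return ll

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"shape": nuis, "scale": np.exp(eta)}

    @classmethod
    def from_natural(cls, p):
        return np.log(p["scale"]), p["shape"]


class _Weibull(_Base):
    spec = FamilySpec("weibull", "nonneg", "log", ("shape", "scale"), 2)

    @classmethod
    def support_mask(cls, y, trials=None):
        return np.isfinite(y) & (y > 0)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        k = np.maximum(nuis, _TINY)
        logy = np.log(np.maximum(y, _TINY))
        return (np.log(k) + (k - 1) * logy - k * eta
                - np.exp(np.clip(k * (logy - eta), -700, 60)))

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        logy = np.log(np.maximum(y, _TINY))
        n_g = np.maximum(W.sum(axis=-1), _TINY)
        n = n_g.sum(axis=0)
        Wtot = W.sum(axis=0)
        lbar = _gsum(Wtot, logy) / np.maximum(n, _TINY)
        ly = logy - lbar[..., None]                # center for stability
        slog = np.sqrt(np.maximum(
            _gsum(Wtot, ly ** 2) / np.maximum(n, _TINY) - (_gsum(Wtot, ly) / n) ** 2,
            _TINY))
        ok = slog > 1e-8
        sum_ly = _gsum(Wtot, ly)

        def score(k):
            tot = n / k + sum_ly
            for g in range(len(W)):
                e = np.exp(np.clip(k[..., None] * ly, -700, 60))
                A = _gsum(W[g], e)
                Ap = _gsum(W[g], e * ly)
                tot = tot - n_g[g] * Ap / np.maximum(A, _TINY)
            return tot

        k0 = np.clip(np.pi / (slog * np.sqrt(6)), 1e-2, 1e3)
        lo, hi = k0 / 1.5, k0 * 1.5
        flo, fhi = score(lo), score(hi)
        for _ in range(30):                        # bracket the root
            need_lo = flo < 0
            lo = np.where(need_lo, lo / 2.5, lo)
            flo = np.where(need_lo, score(lo), flo)
            need_hi = fhi > 0
            hi = np.where(need_hi, hi * 2.5, hi)
            fhi = np.where(need_hi, score(hi), fhi)
            if not (np.any(need_lo) or np.any(need_hi)):
                break
        k = _root1d(score, lo, hi, flo, fhi, iters=16, tol=1e-8)
        eta = np.stack([np.log(_gsum(W[g], np.exp(np.clip(k[..., None] * ly, -700, 60)))
                               / n_g[g]) / k + lbar
                        for g in range(len(W))], axis=-1)
        return eta, k, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        k = np.maximum(nuis, _TINY)
        logy = np.log(np.maximum(y, _TINY))
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        h22 = np.zeros(B)
        n = W.sum(axis=-1).sum(axis=0)
        for g in range(2):
            u = np.clip(k[:, None] * (logy - eta[:, g, None]), -700, 60)
            e = np.exp(u)
            Se = _gsum(W[g], e)
            Sue = _gsum(W[g], u * e)
            Su2e = _gsum(W[g], u ** 2 * e)
            n_g = W[g].sum(axis=-1)
            I[:, g, g] = k ** 2 * Se
            I[:, g, 2] = I[:, 2, g] = -(Se - n_g + Sue)
            h22 += -Su2e / k ** 2
        I[:, 2, 2] = n / k ** 2 - h22
        return I

    @classmethod
    def loglik_groups(cls, y, W, eta, nuis, trials=None):
        k = np.maximum(nuis, _TINY)
        n_g = W.sum(axis=-1)
        n = n_g.sum(axis=0)
        logy = np.log(np.maximum(y, _TINY))
        ll = n * np.log(k) + (k - 1) * _gsum(W[0] + W[1], logy)
        for g in range(2):
            u = np.clip(k[:, None] * (logy - eta[:, g, None]), -700, 60)
            ll += -k * n_g[g] * eta[:, g] - _gsum(W[g], np.exp(u))
        return ll

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"shape": nuis, "scale": np.exp(eta)}

    @classmethod
    def from_natural(cls, p):
        return np.log(p["scale"]), p["shape"]


class _Beta(_Base):
    spec = FamilySpec("beta", "ratio", "logit", ("alpha", "beta"), 2)

    @classmethod
    def support_mask(cls, y, trials=None):
        return np.isfinite(y) & (y > 0) & (y < 1)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        phi = np.maximum(nuis, _TINY)
        mu = np.clip(expit(eta), 1e-9, 1 - 1e-9)
        a, b = mu * phi, (1 - mu) * phi
        yc = np.clip(y, _TINY, 1 - 1e-12)
        return (gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1) * np.log(yc) + (b - 1) * np.log1p(-yc))

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        yc = np.clip(y, _TINY, 1 - 1e-12)
        ly, l1y = np.log(yc), np.log1p(-yc)
        n_g = np.maximum(W.sum(axis=-1), _TINY)
        n = n_g.sum(axis=0)
        m_g = (_gsum(W, ly) - _gsum(W, l1y)) / n_g       # mean logit per group
        L1, L0 = _gsum(W, ly), _gsum(W, l1y)             # (G,B)
        mean = _gsum(W, yc) / n_g
        Wtot = W.sum(axis=0)
        mbar = _gsum(Wtot, yc) / np.maximum(n, _TINY)
        var = _gsum(Wtot, (yc - mbar[..., None]) ** 2) / np.maximum(n, _TINY)
        ok = var > _TINY
        phi0 = np.clip(mbar * (1 - mbar) / np.maximum(var, _TINY) - 1, 0.5, 1e6)
        mu_ws = np.clip(mean, 1e-6, 1 - 1e-6)             # warm start across calls

        def inner_mu(phi):
            mu = mu_ws
            for _ in range(14):
                f = digamma(mu * phi) - digamma((1 - mu) * phi) - m_g
                fp = phi * (polygamma(1, mu * phi) + polygamma(1, (1 - mu) * phi))
                step = f / np.maximum(fp, _TINY)
                mu = np.clip(mu - step, 1e-9, 1 - 1e-9)
                if np.max(np.abs(step)) < 1e-11:    # warm starts converge fast
                    break
            mu_ws[...] = mu
            return mu

        def score(lphi):
            phi = np.exp(lphi)
            mu = inner_mu(phi)
            s = (n_g * (digamma(phi) - mu * digamma(mu * phi)
                        - (1 - mu) * digamma((1 - mu) * phi))
                 + mu * L1 + (1 - mu) * L0).sum(axis=0)
            return s * phi                                 # d/d log phi

        lo = np.log(phi0) - 1.0
        hi = np.log(phi0) + 1.0
        flo, fhi = score(lo), score(hi)
        for _ in range(20):
            need_lo = flo < 0
            lo = np.where(need_lo, lo - 1.4, lo)
            flo = np.where(need_lo, score(lo), flo)
            need_hi = fhi > 0
            hi = np.where(need_hi, hi + 1.4, hi)
            fhi = np.where(need_hi, score(hi), fhi)
            if not (np.any(need_lo) or np.any(need_hi)):
                break
        lphi = _root1d(score, lo, hi, flo, fhi, iters=18, tol=1e-9)
        phi = np.exp(lphi)
        mu = inner_mu(phi)
        return logit(mu).T, phi, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        yc = np.clip(y, _TINY, 1 - 1e-12)
        phi = np.maximum(nuis, _TINY)
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        h22 = np.zeros(B)
        for g in range(2):
            mu = np.clip(expit(eta[:, g]), 1e-9, 1 - 1e-9)
            a, b = mu * phi, (1 - mu) * phi
            n_g = W[g].sum(axis=-1)
            L1 = _gsum(W[g], np.log(yc))
            L0 = _gsum(W[g], np.log1p(-yc))
            A = -n_g * digamma(a) + n_g * digamma(b) + L1 - L0
            s = phi * mu * (1 - mu)
            sp_eta = s * (1 - 2 * mu)                  # ds/deta
            t1a, t1b = polygamma(1, a), polygamma(1, b)
            I[:, g, g] = -(sp_eta * A - n_g * s ** 2 * (t1a + t1b))
            hgp = mu * (1 - mu) * A + s * (-n_g * t1a * mu + n_g * t1b * (1 - mu))
            I[:, g, 2] = I[:, 2, g] = -hgp
            h22 += n_g * (polygamma(1, phi) - mu ** 2 * t1a - (1 - mu) ** 2 * t1b)
        I[:, 2, 2] = -h22
        return I

    @classmethod
    def loglik_groups(cls, y, W, eta, nuis, trials=None):
        yc = np.clip(y, _TINY, 1 - 1e-12)
        phi = np.maximum(nuis, _TINY)
        ll = np.zeros(eta.shape[0])
        for g in range(2):
            mu = np.clip(expit(eta[:, g]), 1e-9, 1 - 1e-9)
            a, b = mu * phi, (1 - mu) * phi
            n_g = W[g].sum(axis=-1)
            L1 = _gsum(W[g], np.log(yc))
            L0 = _gsum(W[g], np.log1p(-yc))
            ll += (n_g * (gammaln(phi) - gammaln(a) - gammaln(b))
                   + (a - 1) * L1 + (b - 1) * L0)
        return ll

    @classmethod
    def natural_params(cls, eta, nuis):
        mu = expit(eta)
        return {"alpha": mu * nuis, "beta": (1 - mu) * nuis}

    @classmethod
    def from_natural(cls, p):
        phi = p["alpha"] + p["beta"]
        return logit(p["alpha"] / phi), phi


def _lchoose(t, y):
    return gammaln(t + 1) - gammaln(y + 1) - gammaln(t - y + 1)


class _Binomial(_Base):
    spec = FamilySpec("binomial", "proportion", "logit", ("p",), 1)
    n_nuis = 0

    @classmethod
    def support_mask(cls, y, trials=None):
        ok = np.isfinite(y) & (y >= 0)
        if trials is not None:
            ok = ok & np.isfinite(trials) & (y <= trials)
        return ok

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return _lchoose(trials, y) + y * np.log(p) + (trials - y) * np.log1p(-p)

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        k_g = _gsum(W, y)
        t_g = np.maximum(_gsum(W, trials * np.ones_like(y)), _TINY)
        p = k_g / t_g
        ok = np.all((p > 0) & (p < 1), axis=0)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return logit(p).T, None, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        # logit link: d2l/deta2 = -sum t p (1-p), exact
        B = eta.shape[0]
        I = np.zeros((B, 2, 2))
        for g in range(2):
            p = np.clip(expit(eta[:, g]), 1e-12, 1 - 1e-12)
            T = _gsum(W[g], trials * np.ones_like(y))
            I[:, g, g] = T * p * (1 - p)
        return I

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"p": expit(eta)}

    @classmethod
    def from_natural(cls, p):
        return logit(p["p"]), None


class _BetaBinomial(_Base):
    """Beta-binomial in (p, rho) mean/overdispersion form; internally the
    precision theta = (1-rho)/rho is the profiled nuisance."""

    spec = FamilySpec("beta_binomial", "proportion", "logit", ("p", "rho"), 2)

    @classmethod
    def support_mask(cls, y, trials=None):
        return _Binomial.support_mask(y, trials)

    @classmethod
    def loglik_terms(cls, y, eta, nuis, trials=None):
        th = np.maximum(nuis, 1e-8)
        p = np.clip(expit(eta), 1e-9, 1 - 1e-9)
        a, b = p * th, (1 - p) * th
        return (_lchoose(trials, y)
                + gammaln(y + a) - gammaln(a)
                + gammaln(trials - y + b) - gammaln(b)
                + gammaln(th) - gammaln(trials + th))

    @classmethod
    def fit_groups(cls, y, W, trials=None):
        t = trials * np.ones_like(y)
        n_g = np.maximum(W.sum(axis=-1), _TINY)
        p0 = np.clip(_gsum(W, y) / np.maximum(_gsum(W, t), _TINY), 1e-6, 1 - 1e-6)
        ok = (p0 > 1e-6) & (p0 < 1 - 1e-6)
        ok = np.all(ok, axis=0)

        p_ws = p0.copy()                                   # warm start across calls

        def _dldp_over_th(p, th):
            # (1/theta) * d loglik / d p per group, via digamma sums
            a = p * th
            b = (1 - p) * th
            f = np.stack([_gsum(W[g], digamma(y + a[g][..., None]) -
                                digamma(t - y + b[g][..., None]))
                          for g in range(len(W))])
            return f - n_g * (digamma(a) - digamma(b))

        def inner_p(th, iters=4):
            # secant iteration: one digamma-sum evaluation per step
            p0_ = p_ws
            f0_ = _dldp_over_th(p0_, th)
            p1_ = np.clip(p0_ - np.sign(f0_) * 1e-4, 1e-9, 1 - 1e-9)
            f1_ = _dldp_over_th(p1_, th)
            for _ in range(iters):
                denom = f1_ - f0_
                with np.errstate(divide="ignore", invalid="ignore"):
                    step = np.where(np.abs(denom) > _TINY,
                                    f1_ * (p1_ - p0_) / denom, 0.0)
                step = np.where(np.isfinite(step), step, 0.0)
                if np.max(np.abs(step)) < 1e-11:
                    break
                p2 = np.clip(p1_ - np.clip(step, -0.2, 0.2), 1e-9, 1 - 1e-9)
                p0_, f0_ = p1_, f1_
                p1_ = p2
                f1_ = _dldp_over_th(p1_, th)
            p_ws[...] = p1_
            return p1_

        def score(lth):
            th = np.exp(lth)
            p = inner_p(th)
            tot = np.zeros_like(th)
            for g in range(len(W)):
                a = (p[g] * th)[..., None]
                b = ((1 - p[g]) * th)[..., None]
                tot += _gsum(W[g],
                             p[g][..., None] * (digamma(y + a) - digamma(a))
                             + (1 - p[g][..., None]) * (digamma(t - y + b) - digamma(b))
                             + digamma(th[..., None]) - digamma(t + th[..., None]))
            return tot * th

        # moment estimate of the overdispersion seeds a narrow bracket on
        # log(theta); it is widened per row only where the sign demands it.
        # rho is capped in [2e-5, 0.33]; near-binomial data hits the upper
        # theta boundary and is reported there.
        Wtot = W.sum(axis=0)
        n = np.maximum(Wtot.sum(axis=-1), 2.0)
        pbar = np.clip(_gsum(Wtot, y) / np.maximum(_gsum(Wtot, t), _TINY),
                       1e-6, 1 - 1e-6)
        chi2 = _gsum(Wtot, (y - t * pbar[..., None]) ** 2 /
                     np.maximum(t * pbar[..., None] * (1 - pbar[..., None]), _TINY))
        tbar = np.maximum(_gsum(Wtot, t) / n, 2.0)
        rho0 = np.clip((chi2 / (n - 1.0) - 1.0) / (tbar - 1.0), 3e-5, 0.3)
        LLO, LHI = np.log(2.0), np.log(5e4)
        lth0 = np.clip(np.log((1.0 - rho0) / rho0), LLO, LHI)
        lo = np.maximum(lth0 - 1.2, LLO)
        hi = np.minimum(lth0 + 1.2, LHI)
        flo, fhi = score(lo), score(hi)
        for _ in range(8):
            need_lo = (flo < 0) & (lo > LLO)
            lo = np.where(need_lo, np.maximum(lo - 2.0, LLO), lo)
            flo = np.where(need_lo, score(lo), flo)
            need_hi = (fhi > 0) & (hi < LHI)
            hi = np.where(need_hi, np.minimum(hi + 2.0, LHI), hi)
            fhi = np.where(need_hi, score(hi), fhi)
            if not (np.any(need_lo) or np.any(need_hi)):
                break
        lo_bound = (flo <= 0) & (lo <= LLO + 1e-12)
        hi_bound = (fhi >= 0) & (hi >= LHI - 1e-12)
        lth = _root1d(score, lo, hi, flo, fhi, iters=10, tol=1e-6)
        lth = np.where(lo_bound, LLO, lth)
        lth = np.where(hi_bound, LHI, lth)
        th = np.exp(lth)
        p = inner_p(th, iters=6)
        return logit(p).T, th, ok

    @classmethod
    def observed_info(cls, y, W, eta, nuis, trials=None):
        th = np.maximum(nuis, 1e-8)
        t = trials * np.ones_like(y)
        B = eta.shape[0]
        I = np.zeros((B, 3, 3))
        h22 = np.zeros(B)
        d2_tth = polygamma(1, t + th[:, None])
        for g in range(2):
            p = np.clip(expit(eta[:, g]), 1e-9, 1 - 1e-9)
            a, b = (p * th)[:, None], ((1 - p) * th)[:, None]
            D1a = digamma(y + a) - digamma(a)
            D1b = digamma(t - y + b) - digamma(b)
            D2a = polygamma(1, y + a) - polygamma(1, a)
            D2b = polygamma(1, t - y + b) - polygamma(1, b)
            S1 = _gsum(W[g], D1a - D1b)
            S2ab = _gsum(W[g], D2a + D2b)
            S2w = _gsum(W[g], p[:, None] * D2a - (1 - p[:, None]) * D2b)
            s = th * p * (1 - p)
            sp = s * (1 - 2 * p)
            I[:, g, g] = -(sp * S1 + s ** 2 * S2ab)
            I[:, g, 2] = I[:, 2, g] = -(p * (1 - p) * S1 + s * S2w)
            h22 += _gsum(W[g], p[:, None] ** 2 * D2a + (1 - p[:, None]) ** 2 * D2b
                         + polygamma(1, th[:, None]) - d2_tth)
        I[:, 2, 2] = -h22
        return I

    @classmethod
    def natural_params(cls, eta, nuis):
        return {"p": expit(eta), "rho": 1.0 / (1.0 + nuis)}

    @classmethod
    def from_natural(cls, p):
        return logit(p["p"]), (1.0 - p["rho"]) / p["rho"]


FAMILIES = {
    f.spec.name: f
    for f in (_Gaussian, _Logistic, _ReverseGumbel, _Gamma, _InverseGamma,
              _Weibull, _Beta, _LogitNormal, _Binomial, _BetaBinomial)
}

# candidate families per data type; order is the deterministic tie-break order
CANDIDATES = {
    "nonneg": ("gamma", "inverse_gamma", "weibull"),
    "ratio": ("beta", "logit_normal"),
    "noise": ("gaussian", "logistic", "reverse_gumbel"),
    "proportion": ("binomial", "beta_binomial"),
}


def get_family(name: str):
    try:
        return FAMILIES[name]
    except KeyError:
        raise KeyError(f"unknown family {name!r}; known: {sorted(FAMILIES)}")


# ---------------------------------------------------------------------------
# public single-sample API
# ---------------------------------------------------------------------------

def loglik(name_or_spec, params: dict, values, trials=None) -> float:
    """Sum of log densities (log pmf) of one family at natural-scale params.

    Returns -inf when any value lies outside the family's support.
    """
    name = name_or_spec.name if isinstance(name_or_spec, FamilySpec) else name_or_spec
    fam = get_family(name)
    y = np.asarray(values, dtype=float)
    t = None if trials is None else np.asarray(trials, dtype=float)
    if not np.all(fam.support_mask(y, t)):
        return -np.inf
    eta, nuis = fam.from_natural(params)
    return float(np.sum(fam.loglik_terms(y, eta, nuis, t)))


def fit_family(values, spec, trials=None) -> FamilyFit:
    """Maximum-likelihood fit of one family to one sample.

    Parameters
    ----------
    values : array of observations (successes for count families)
    spec : family name or FamilySpec
    trials : trials per observation, required for count families
    """
    name = spec.name if isinstance(spec, FamilySpec) else spec
    fam = get_family(name)
    y = np.asarray(values, dtype=float)
    t = None if trials is None else np.asarray(trials, dtype=float)
    mask = np.isfinite(y)
    if t is not None:
        mask &= np.isfinite(t)
    y = y[mask]
    t = t[mask] if t is not None else None
    if y.size < 3:
        raise DegenerateDataError(f"need >= 3 observations, got {y.size}")
    if not np.all(fam.support_mask(y, t)):
        bad = np.flatnonzero(~fam.support_mask(y, t))[:5]
        raise SupportError(f"{name}: values outside support at positions {bad.tolist()}")
    if np.ptp(y) == 0:
        raise DegenerateDataError(f"{name}: all {y.size} values equal ({y[0]!r})")

    y2 = y[None, :]
    t2 = None if t is None else t[None, :]
    W = np.ones((1, 1, y.size))
    eta, nuis, ok = fam.fit_groups(y2, W, t2)
    eta0 = eta[:, 0]
    nu = None if nuis is None else nuis
    ll = float(np.sum(fam.loglik_terms(y2, eta0[:, None], None if nu is None else nu[:, None], t2)))
    params = fam.natural_params(float(eta0[0]), None if nu is None else float(nu[0]))
    converged = bool(np.all(ok)) and np.isfinite(ll)
    aic = -2.0 * ll + 2.0 * fam.spec.n_free
    return FamilyFit(fam.spec, params, ll, aic, int(y.size), converged)


def select_family(values, data_type: str, trials=None) -> FamilyFit:
    """Fit all candidate families for ``data_type``; return the minimum-AIC fit.

    Ties (|dAIC| < 1e-9) go to the family with fewer free parameters, then to
    the fixed candidate order.  The returned fit carries per-candidate
    diagnostics in ``.candidates``.
    """
    if data_type not in CANDIDATES:
        raise ValueError(f"unknown data type {data_type!r}; known: {sorted(CANDIDATES)}")
    fits, diag = [], {}
    for name in CANDIDATES[data_type]:
        try:
            f = fit_family(values, name, trials=trials)
            if f.converged:
                fits.append(f)
                diag[name] = {"aic": f.aic, "loglik": f.loglik, "params": f.params}
            else:
                diag[name] = {"error": "did not converge"}
        except (DegenerateDataError, SupportError, FloatingPointError) as e:
            diag[name] = {"error": str(e)}
    if not fits:
        raise SelectionError(f"no candidate family fit the data: {diag}")
    order = {n: i for i, n in enumerate(CANDIDATES[data_type])}
    best = min(fits, key=lambda f: (round(f.aic / 1e-9) * 1e-9, f.spec.n_free,
                                    order[f.spec.name]))
    best.candidates = diag
    return best
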