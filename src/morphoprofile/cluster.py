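"""PCA reduction of significant Z-profiles and Gaussian-mixture clustering.

The mutant x parameter Z-matrix (restricted to parameters significant in at
least one strain) is reduced by PCA — columns centered, not scaled — keeping
the smallest number of components whose cumulative contribution ratio (CCR,
the cumulative fraction of variance explained) reaches a target.  Mutants are
then clustered with Gaussian mixtures fitted by EM under mclust-style
covariance parameterizations:

=====  ==============================================
code   component covariance
=====  ==============================================
EII    shared spherical            lambda I
VII    per-component spherical     lambda_k I
EEI    shared diagonal             diag(lambda)
VVI    per-component diagonal      diag(lambda_k)
EEE    shared full                 Sigma
VVV    per-component full          Sigma_k
=====  ==============================================

Model (code, number of components) selection is by BIC in the
``-2 loglik + df log n`` convention, minimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["PCAModel", "GMMResult", "pca_reduce", "gmm_fit", "gmm_select",
           "posterior_report", "DegenerateComponentError", "COV_MODELS"]

COV_MODELS = ("EII", "VII", "EEI", "VVI", "EEE", "VVV")
_VAR_FLOOR = 1e-6


class DegenerateComponentError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean_: np.ndarray            # column means used for centering
    components_: np.ndarray      # (rank, p) orthonormal loadings
    variances_: np.ndarray       # per-component variance share numerators
    ccr: np.ndarray              # cumulative contribution ratio, rank-long
    k: int                       # retained components
    columns: Optional[list] = None   # parameter ids the axes were fitted on

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def scores(self, X, k=None):
        k = self.k if k is None else k
        return self.transform(X)[..., :k]


def pca_reduce(profile, ccr_target: float = 0.80, k: Optional[int] = None):
    """PCA of a strains x parameters profile matrix.

    ``profile`` may be a DataFrame or array; missing entries are imputed as 0
    (a missing test is treated as no detected change).  Returns
    ``(PCAModel, scores)`` where scores keep the retained k columns.
    """
    if hasattr(profile, "to_numpy"):
        index = profile.index
        X = profile.to_numpy(dtype=float)
    else:
        index = None
        X = np.asarray(profile, dtype=float)
    X = np.where(np.isfinite(X), X, 0.0)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 strains and 2 parameters")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("profile matrix has rank 0 (no variation)")
    s, Vt, U = s[:rank], Vt[:rank], U[:, :rank]
    var = s ** 2
    ccr = np.cumsum(var) / var.sum()
    if k is None:
        k = int(np.searchsorted(ccr, ccr_target - 1e-12) + 1)
    k = min(k, rank)
    model = PCAModel(mean_=mean, components_=Vt, variances_=var, ccr=ccr, k=k)
    scores = U * s
    scores = scores[:, :k]
    if index is not None:
        scores = pd.DataFrame(scores, index=index,
                              columns=[f"PC{i + 1}" for i in range(k)])
    return model, scores


# ---------------------------------------------------------------------------
# Gaussian mixtures
# ---------------------------------------------------------------------------

@dataclass
class GMMResult:
    n_components: int
    model: str
    weights: np.ndarray          # (c,)
    means: np.ndarray            # (c, d)
    covariances: np.ndarray      # (c, d, d), expanded to full form
    resp: np.ndarray             # (n, c) posterior membership probabilities
    loglik: float
    bic: float
    df: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    selection_table: Optional[pd.DataFrame] = None

    @property
    def labels(self):
        return self.resp.argmax(axis=1)


def _df_of(model, c, d):
    cov_df = {"EII": 1, "VII": c, "EEI": d, "VVI": c * d,
              "EEE": d * (d + 1) // 2, "VVV": c * d * (d + 1) // 2}[model]
    return (c - 1) + c * d + cov_df


def _component_logpdf(X, mu, cov):
    d = X.shape[1]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise DegenerateComponentError("singular component covariance")
    z = np.linalg.solve(chol, (X - mu).T)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(z ** 2, axis=0))


def _m_step(X, resp, model):
    n, d = X.shape
    c = resp.shape[1]
    Nk = resp.sum(axis=0)
    if np.any(Nk < 1e-8):
        raise DegenerateComponentError("empty mixture component")
    w = Nk / n
    means = (resp.T @ X) / Nk[:, None]
    covs = np.empty((c, d, d))
    if model in ("VVV", "EEE"):
        full = np.empty((c, d, d))
        for k in range(c):
            diff = X - means[k]
            full[k] = (resp[:, k, None] * diff).T @ diff / Nk[k]
        if model == "EEE":
            pooled = np.einsum("k,kij->ij", Nk / n, full)
            covs[:] = pooled
        else:
            covs = full
        for k in range(c):
            covs[k][np.diag_indices(d)] = np.maximum(np.diag(covs[k]), _VAR_FLOOR)
    else:
        diag = np.empty((c, d))
        for k in range(c):
            diff = X - means[k]
            diag[k] = (resp[:, k] * (diff ** 2).T).sum(axis=1) / Nk[k]
        if model == "EEI":
            diag[:] = (Nk[:, None] * diag).sum(axis=0) / n
        elif model == "EII":
            diag[:] = (Nk[:, None] * diag).sum() / (n * d)
        elif model == "VII":
            diag = np.repeat(diag.mean(axis=1, keepdims=True), d, axis=1)
        diag = np.maximum(diag, _VAR_FLOOR)
        for k in range(c):
            covs[k] = np.diag(diag[k])
    return w, means, covs


def _e_step(X, w, means, covs):
    c = len(w)
    logp = np.empty((X.shape[0], c))
    for k in range(c):
        logp[:, k] = np.log(max(w[k], 1e-300)) + _component_logpdf(X, means[k], covs[k])
    norm = logsumexp(logp, axis=1)
    return np.exp(logp - norm[:, None]), float(norm.sum())


def _kmeanspp_init(X, c, rng):
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(c - 1):
        d2 = np.min([((X - m) ** 2).sum(axis=1) for m in centers], axis=0)
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(X[rng.choice(n, p=p)])
    centers = np.array(centers)
    labels = np.argmin(((X[:, None, :] - centers[None]) ** 2).sum(-1), axis=1)
    resp = np.zeros((n, c))
    resp[np.arange(n), labels] = 1.0
    return resp + 1e-6                      # soften to avoid empty components


def gmm_fit(X, c: int, model: str = "EEI", seed=0, n_starts: int = 20,
            max_iter: int = 500, tol: float = 1e-8) -> GMMResult:
    """EM fit of a c-component Gaussian mixture under one covariance code.

    Runs ``n_starts`` k-means++ initializations and keeps the best final
    log-likelihood.  The per-iteration log-likelihood trace of the winning
    run is retained (EM guarantees it is non-decreasing).
    """
    X = np.asarray(X, dtype=float)
    if hasattr(X, "ndim") and X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if model not in COV_MODELS:
        raise ValueError(f"unknown covariance model {model!r}")
    if n <= c:
        raise ValueError(f"need more points ({n}) than components ({c})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        resp = _kmeanspp_init(X, c, rng)
        resp /= resp.sum(axis=1, keepdims=True)
        trace = []
        ll = -np.inf
        converged = False
        try:
            for _it in range(max_iter):
                w, means, covs = _m_step(X, resp, model)
                resp, ll_new = _e_step(X, w, means, covs)
                trace.append(ll_new)
                if np.isfinite(ll) and ll_new - ll < tol * max(1.0, abs(ll)):
                    converged = True
                    ll = ll_new
                    break
                ll = ll_new
            # a component pinned at the variance floor, or with a
            # near-singular covariance (e.g. fitted to 2 points), is not a
            # valid optimum; its inflated likelihood would corrupt BIC
            if min(np.linalg.eigvalsh(c).min() for c in covs) <= \
                    _VAR_FLOOR * (1 + 1e-9):
                raise DegenerateComponentError(
                    "component covariance at or below the variance floor")
        except DegenerateComponentError:
            continue
        if best is None or ll > best[0]:
            best = (ll, w, means, covs, resp, np.array(trace), converged)
    if best is None:
        raise DegenerateComponentError(
            f"all {n_starts} starts degenerate for c={c}, model={model}")
    ll, w, means, covs, resp, trace, converged = best
    df = _df_of(model, c, d)
    bic = -2.0 * ll + df * np.log(n)
    return GMMResult(c, model, w, means, covs, resp, ll, bic, df, converged,
                     loglik_trace=trace)


def gmm_select(X, c_range=range(1, 10), models=COV_MODELS, seed=0,
               n_starts: int = 20) -> GMMResult:
    """Fit every (components, covariance code) pair; return the minimum-BIC fit.

    Ties go to the fit with fewer free parameters, then to the requested
    order.  The full selection table is attached to the winner.
    """
    rows, fits = [], {}
    for ci, c in enumerate(c_range):
        for mi, model in enumerate(models):
            try:
                g = gmm_fit(X, c, model, seed=seed + 1000 * ci + mi,
                            n_starts=n_starts)
                rows.append({"c": c, "model": model, "loglik": g.loglik,
                             "df": g.df, "bic": g.bic, "error": ""})
                fits[(c, model)] = g
            except (DegenerateComponentError, ValueError) as e:
                rows.append({"c": c, "model": model, "loglik": np.nan,
                             "df": np.nan, "bic": np.nan, "error": str(e)})
    table = pd.DataFrame(rows)
    if not fits:
        raise DegenerateComponentError(f"all candidate fits failed:\n{table}")
    order = {m: i for i, m in enumerate(models)}
    key = min(fits, key=lambda k: (round(fits[k].bic / 1e-9) * 1e-9,
                                   fits[k].df, k[0], order[k[1]]))
    best = fits[key]
    best.selection_table = table
    return best


def posterior_report(g: GMMResult, ids=None, uncertain_below: float = 0.7):
    """Per-strain cluster assignment with its posterior probability."""
    post = g.resp.max(axis=1)
    df = pd.DataFrame({
        "strain": ids if ids is not None else np.arange(len(post)),
        "cluster": g.labels,
        "posterior": post,
        "uncertain": post < uncertain_below,
    })
    return df.set_index("strain")
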