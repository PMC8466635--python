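"""Profile similarity via projection onto wild-type PC axes, and fitness
p/q-values against a wild-type null.

For similarity screening, Z-profiles of the wild-type replicates (each
computed leave-one-out against the remaining replicates, to avoid
self-inclusion bias) define a PCA basis.  Query perturbation profiles —
mutants or drug treatments alike — are projected onto those axes, and the
Pearson correlation over the first k PC scores (k chosen at CCR >= 0.99 by
default) quantifies how similar two perturbations are.

For fitness screening, a strain's growth statistic (e.g. the logarithmic
strain growth-rate coefficient, LSC) is compared to the wild-type
distribution: the one-tailed lower p-value under N(wt_mean, wt_sd^2), with
Storey q-values for multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cluster import PCAModel, pca_reduce
from .data import MorphDataset
from .differential import wald_batch

__all__ = ["SimilarityResult", "FitnessResult", "wt_replicate_z", "wt_axes",
           "project", "profile_correlation", "similarity_matrix", "fitness_pq",
           "storey_qvalues"]


@dataclass
class SimilarityResult:
    ids: list
    k: int
    ccr_at_k: float
    r: pd.DataFrame              # pairwise Pearson correlations


@dataclass
class FitnessResult:
    table: pd.DataFrame          # index strain; columns value, p, q
    pi0: float
    wt_mean: float
    wt_sd: float


# ---------------------------------------------------------------------------
# wild-type axes
# ---------------------------------------------------------------------------

def wt_replicate_z(ds: MorphDataset, fits: dict) -> pd.DataFrame:
    """Leave-one-out Z-profile of every wild-type replicate.

    Each replicate is tested as a single-observation pseudo-mutant against a
    null formed by the remaining wild-type replicates.
    """
    wt = ds.wt_strain_id
    rows = ds.rows_of(wt).index
    n0 = len(rows)
    if n0 < 3:
        raise ValueError(f"need >= 3 wild-type replicates, got {n0}")
    mut = np.eye(n0, dtype=bool)
    params = [p for p in ds.analyzable_params() if p in fits]
    Z = np.full((n0, len(params)), np.nan)
    groups = {}
    for j, pid in enumerate(params):
        groups.setdefault(fits[pid].spec.name, []).append((j, pid))
    for fam_name, items in groups.items():
        P = len(items)
        y = np.repeat(np.stack([ds.param_values(pid, wt).to_numpy()
                                for _, pid in items]), n0, axis=0)
        trials = None
        if ds.meta[items[0][1]].trials_column is not None:
            trials = np.repeat(np.stack([ds.trials_of(pid, wt).to_numpy()
                                         for _, pid in items]), n0, axis=0)
        mm = np.tile(mut, (P, 1))
        r = wald_batch(fam_name, y, mm, trials=trials, min_group=(2, 1))
        for a, (j, _) in enumerate(items):
            Z[:, j] = r["z"][a * n0:(a + 1) * n0]
    return pd.DataFrame(Z, index=rows, columns=pd.Index(params, name="param"))


def wt_axes(wt_z: pd.DataFrame, ccr_target: float = 0.99,
            k: Optional[int] = None) -> PCAModel:
    """PCA basis of the wild-type replicate Z-profiles (centered, unscaled)."""
    if len(wt_z) < 3:
        raise ValueError(f"need >= 3 wild-type replicate profiles, got {len(wt_z)}")
    X = wt_z.to_numpy(dtype=float)
    X = np.where(np.isfinite(X), X, 0.0)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("wild-type replicate profiles have zero variance")
    model, _ = pca_reduce(wt_z, ccr_target=ccr_target, k=k)
    model.columns = list(wt_z.columns)
    return model


def project(queries, axes: PCAModel):
    """Project query Z-profiles onto the wild-type PC axes (first k scores)."""
    cols = getattr(axes, "columns", None)
    if isinstance(queries, pd.DataFrame) and cols is not None:
        missing = [c for c in cols if c not in queries.columns]
        if missing:
            raise ValueError(
                f"query profiles lack {len(missing)} parameters of the axes: "
                f"{missing[:10]}")
        X = queries[cols].to_numpy(dtype=float)
        index = queries.index
    else:
        X = np.asarray(queries, dtype=float)
        index = None
    one = X.ndim == 1
    X = np.atleast_2d(np.where(np.isfinite(X), X, 0.0))
    if X.shape[1] != axes.components_.shape[1]:
        raise ValueError(f"query has {X.shape[1]} parameters, axes expect "
                         f"{axes.components_.shape[1]}")
    S = axes.scores(X)
    if one:
        return S[0]
    if index is not None:
        return pd.DataFrame(S, index=index,
                            columns=[f"PC{i + 1}" for i in range(S.shape[1])])
    return S


def profile_correlation(scores_a, scores_b, k: Optional[int] = None) -> float:
    """Pearson correlation between two profiles over their first k PC scores."""
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if k is None:
        k = min(a.size, b.size)
    if k < 2:
        raise ValueError("need at least 2 PC scores")
    a, b = a[:k], b[:k]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def similarity_matrix(scores: pd.DataFrame, k: Optional[int] = None,
                      ccr_at_k: float = np.nan) -> SimilarityResult:
    """Pairwise profile correlations over the first k PC scores."""
    ids = list(scores.index)
    X = scores.to_numpy(dtype=float)
    k = X.shape[1] if k is None else min(k, X.shape[1])
    R = np.full((len(ids), len(ids)), np.nan)
    for i in range(len(ids)):
        for j in range(i, len(ids)):
            r = profile_correlation(X[i], X[j], k)
            R[i, j] = R[j, i] = r
    return SimilarityResult(ids, k, ccr_at_k,
                            pd.DataFrame(R, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def storey_qvalues(p, lambdas=None):
    """Storey q-values with cubic-smoothed pi0 over a lambda grid.

    pi0 is estimated as the cubic least-squares smooth of
    #{p > lambda} / (m (1 - lambda)) evaluated at the largest lambda,
    capped at 1.  Returns ``(q, pi0)``; missing p-values give missing q.
    """
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q, np.nan
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(pv > lam).mean() / (1.0 - lam) for lam in lambdas])
    if m < 10:
        pi0 = 1.0
    else:
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    order = np.argsort(pv, kind="stable")
    ranks = np.arange(1, m + 1)
    qs = pi0 * m * pv[order] / ranks
    qs = np.minimum.accumulate(qs[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.clip(qs, 0.0, 1.0)
    q[ok] = qv
    return q, pi0


def fitness_pq(values, wt_mean: float, wt_sd: float, ids=None) -> FitnessResult:
    """One-tailed fitness test of each strain against the wild-type Gaussian.

    p is the lower-tail probability of the strain's fitness statistic under
    N(wt_mean, wt_sd^2) — small p means significantly lower fitness than the
    wild type.  q-values follow Storey's procedure.
    """
    if not (wt_sd > 0):
        raise ValueError("wt_sd must be positive")
    v = np.asarray(values, dtype=float)
    p = np.where(np.isfinite(v), norm.cdf((v - wt_mean) / wt_sd), np.nan)
    q, pi0 = storey_qvalues(p)
    table = pd.DataFrame({"value": v, "p": p, "q": q},
                         index=ids if ids is not None else np.arange(v.size))
    table.index.name = "strain"
    return FitnessResult(table, pi0, float(wt_mean), float(wt_sd))
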