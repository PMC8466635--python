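"""Per-mutant Wald Z statistics against the wild-type null, with
permutation-calibrated FDR thresholding.

For every (mutant, parameter) cell a two-group GLM is fitted jointly to the
wild-type replicate pool and the mutant replicates: the location on the
family's link scale is ``beta0 + beta1 * is_mutant`` with scale/shape shared
between groups.  The Wald statistic is ``Z = beta1 / SE(beta1)`` with the
standard error taken from the inverse observed information (central-difference
Hessian of the joint log-likelihood).  A mutant located above the wild type
on the link scale gives Z > 0.

Significance is calibrated by permutation: pseudo-mutants of the same
replicate count are drawn from the wild-type pool (without replacement), the
full Z profile is recomputed for each, and the FDR at a threshold t is the
permutation-expected null rejection count scaled to the mutant grid divided
by the observed rejection count.  One global |Z| threshold is applied across
all strains and parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import MorphDataset
from .families import FamilyFit, get_family, select_family, SelectionError

log = logging.getLogger(__name__)

__all__ = ["ZMatrix", "wald_z", "wald_batch", "z_matrix", "permutation_fdr",
           "select_families"]


@dataclass
class ZMatrix:
    """Mutants x parameters grid of Wald Z-values with significance flags."""

    z: pd.DataFrame
    coef: pd.DataFrame
    se: pd.DataFrame
    flags: Optional[pd.DataFrame] = None
    threshold: float = np.inf
    fdr_level: Optional[float] = None
    n_permutations: int = 0
    seed: Optional[int] = None
    fdr_curve: Optional[pd.DataFrame] = None

    @property
    def strains(self):
        return list(self.z.index)

    @property
    def param_ids(self):
        return list(self.z.columns)

    def flagged_params(self):
        """Parameters significant in at least one strain."""
        if self.flags is None:
            raise ValueError("ZMatrix has no significance flags yet")
        return [p for p in self.z.columns if self.flags[p].any()]

    def n_flagged(self):
        return 0 if self.flags is None else int(self.flags.to_numpy().sum())


# ---------------------------------------------------------------------------
# batched two-group Wald engine
# ---------------------------------------------------------------------------

def _hessian(fun, x, B, p):
    """Central-difference Hessian of fun: (B,p) -> (B,) at x."""
    h = 1e-4 * (1.0 + np.abs(x))
    f0 = fun(x)
    H = np.empty((B, p, p))
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[:, i] += h[:, i]
        xm[:, i] -= h[:, i]
        H[:, i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[:, i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[:, [i, j]] += h[:, [i, j]]
            xmm[:, [i, j]] -= h[:, [i, j]]
            xpm[:, i] += h[:, i]
            xpm[:, j] -= h[:, j]
            xmp[:, i] -= h[:, i]
            xmp[:, j] += h[:, j]
            val = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h[:, i] * h[:, j])
            H[:, i, j] = H[:, j, i] = val
    return H, f0


def wald_batch(family_name, y, mut, valid=None, trials=None,
               min_group=(2, 1), numeric_hessian=False):
    """Vectorized two-group Wald test over a batch of group assignments.

    Parameters
    ----------
    family_name : selected family for this parameter
    y : (n,) or (B,n) observations (successes for count families)
    mut : (B,n) boolean mutant-membership masks
    valid : optional (B,n) mask of usable cells
    trials : trials per observation for count families
    min_group : minimum (wild-type, mutant) group sizes
    numeric_hessian : replace the analytic observed information by a
        central-difference Hessian (cross-validation path)

    Returns a dict of (B,) arrays: coef, se, z, loglik, ok.
    """
    fam = get_family(family_name)
    mut = np.asarray(mut, dtype=bool)
    B, n = mut.shape
    y = np.asarray(y, dtype=float)
    y2 = np.broadcast_to(y if y.ndim == 2 else y[None, :], (B, n))
    t2 = None
    if trials is not None:
        trials = np.asarray(trials, dtype=float)
        t2 = np.broadcast_to(trials if trials.ndim == 2 else trials[None, :], (B, n))

    V = fam.support_mask(y2, t2)
    if valid is not None:
        V = V & np.asarray(valid, dtype=bool)
    if V.all():
        V = V.astype(float)
        yf, tf = y2, t2
    else:
        V = V.astype(float)
        fill = np.nanmedian(np.where(V > 0, y2, np.nan), axis=-1, keepdims=True)
        fill = np.where(np.isfinite(fill), fill, 1.0)
        yf = np.where(V > 0, y2, fill)
        tf = None
        if t2 is not None:
            tf = np.where(V > 0, t2, np.maximum(fill, 1.0) + 1.0)

    W1 = V * mut
    W0 = V * (~mut)
    n0, n1 = W0.sum(-1), W1.sum(-1)
    W = np.stack([W0, W1])
    eta, nuis, ok = fam.fit_groups(yf, W, tf)
    beta0 = eta[:, 0]
    beta1 = eta[:, 1] - eta[:, 0]
    ok = ok & (n0 >= min_group[0]) & (n1 >= min_group[1]) & np.isfinite(beta1)

    has_nuis = nuis is not None
    p = 3 if has_nuis else 2
    ll = fam.loglik_groups(yf, W, eta, nuis, tf)

    if numeric_hessian:
        x = np.column_stack([beta0, beta1] +
                            ([np.log(np.maximum(nuis, 1e-300))] if has_nuis else []))
        x = np.where(np.isfinite(x), x, 0.0)

        def _ll_fn(xmat):
            lc = xmat[:, 0, None] + xmat[:, 1, None] * mut
            nu = np.exp(xmat[:, 2])[:, None] if has_nuis else None
            tm = fam.loglik_terms(yf, lc, nu, tf)
            return np.einsum("bn,bn->b", V, np.where(np.isfinite(tm), tm, -1e30))

        H, _ = _hessian(_ll_fn, x, B, p)
        info = -H
        # numeric path is in (beta0, beta1, log nuis) coordinates
        var_idx = (1, 1)
        cov = _pinv_batch(info)
        var1 = cov[:, var_idx[0], var_idx[1]]
    else:
        info = fam.observed_info(yf, W, eta, nuis, tf)
        cov = _pinv_batch(info)
        # beta1 = eta1 - eta0: Var = V11 + V00 - 2 V01
        var1 = cov[:, 0, 0] + cov[:, 1, 1] - 2 * cov[:, 0, 1]

    ok = ok & np.isfinite(var1) & (var1 > 0)
    se = np.sqrt(np.where(var1 > 0, var1, np.nan))
    z = np.where(ok, beta1 / se, np.nan)
    return {"coef": np.where(ok, beta1, np.nan),
            "se": np.where(ok, se, np.nan),
            "z": z, "loglik": ll, "ok": ok}


def _pinv_batch(info):
    B, p, _ = info.shape
    cov = np.full((B, p, p), np.nan)
    finite = np.all(np.isfinite(info), axis=(1, 2))
    if finite.any():
        try:
            cov[finite] = np.linalg.inv(info[finite])
        except np.linalg.LinAlgError:
            try:
                cov[finite] = np.linalg.pinv(info[finite])
            except np.linalg.LinAlgError:
                for b in np.flatnonzero(finite):
                    try:
                        cov[b] = np.linalg.pinv(info[b])
                    except np.linalg.LinAlgError:
                        pass
    return cov


def wald_z(wt_values, mut_values, fit: FamilyFit, wt_trials=None, mut_trials=None):
    """Two-group Wald test of one mutant sample against the wild-type pool.

    Returns ``(coef, se, z)``; the family comes from ``fit`` (the AIC-selected
    family of this parameter).
    """
    wt = np.asarray(wt_values, dtype=float)
    mu = np.asarray(mut_values, dtype=float)
    if mu.size < 2:
        raise ValueError("need at least 2 mutant replicates")
    if wt.size < 5:
        raise ValueError("need at least 5 wild-type replicates")
    y = np.concatenate([wt, mu])[None, :]
    mut = np.zeros_like(y, dtype=bool)
    mut[0, wt.size:] = True
    trials = None
    if wt_trials is not None:
        trials = np.concatenate([np.asarray(wt_trials, float),
                                 np.asarray(mut_trials, float)])[None, :]
    r = wald_batch(fit.spec.name, y, mut, trials=trials)
    return float(r["coef"][0]), float(r["se"][0]), float(r["z"][0])


# ---------------------------------------------------------------------------
# dataset-level operations
# ---------------------------------------------------------------------------

_FITTABLE = ("nonneg", "ratio", "noise", "proportion")


def select_families(ds: MorphDataset, on: str = "wt"):
    """AIC-select the best family for every analyzable parameter.

    ``on`` chooses the fitting population: ``"wt"`` (the null defines the
    model) or ``"all"`` strains pooled.  CV parameters must have been
    converted to noise first (see :mod:`morphoprofile.noise`).
    """
    fits = {}
    for pid in ds.analyzable_params():
        m = ds.meta[pid]
        if m.data_type == "cv":
            log.warning("select_families: %s is cv; convert to noise first — skipped", pid)
            continue
        col = ds.param_values(pid, None if on == "all" else ds.wt_strain_id)
        tr = ds.trials_of(pid, None if on == "all" else ds.wt_strain_id)
        try:
            fits[pid] = select_family(col.to_numpy(), m.data_type,
                                      trials=None if tr is None else tr.to_numpy())
        except (SelectionError, ValueError) as e:
            log.warning("select_families: %s failed (%s)", pid, e)
    return fits


def _by_family(params, fits):
    groups = {}
    for pid in params:
        groups.setdefault(fits[pid].spec.name, []).append(pid)
    return groups


def z_matrix(ds: MorphDataset, fits: dict) -> ZMatrix:
    """One Wald Z per (mutant strain, analyzable parameter).

    Parameters sharing a selected family are fitted in one stacked batch.
    """
    wt = ds.wt_strain_id
    mutants = ds.mutants
    params = [p for p in ds.analyzable_params() if p in fits]
    col_of = {p: j for j, p in enumerate(params)}
    Z = np.full((len(mutants), len(params)), np.nan)
    C = np.full_like(Z, np.nan)
    E = np.full_like(Z, np.nan)
    n0 = len(ds.rows_of(wt))
    mmax = max((len(ds.rows_of(s)) for s in mutants), default=0)

    def _stack(pids, getter):
        out = np.full((len(pids), len(mutants), n0 + mmax), np.nan)
        for a, pid in enumerate(pids):
            out[a, :, :n0] = getter(pid, wt)
            for i, s in enumerate(mutants):
                v = getter(pid, s)
                out[a, i, n0:n0 + len(v)] = v
        return out.reshape(len(pids) * len(mutants), n0 + mmax)

    for fam_name, pids in _by_family(params, fits).items():
        y = _stack(pids, lambda p, s: ds.param_values(p, s).to_numpy())
        trials = None
        if ds.meta[pids[0]].trials_column is not None:
            trials = _stack(pids, lambda p, s: ds.trials_of(p, s).to_numpy())
        mut = np.zeros_like(y, dtype=bool)
        mut[:, n0:] = True
        r = wald_batch(fam_name, y, mut, trials=trials, min_group=(5, 2))
        for a, pid in enumerate(pids):
            sl = slice(a * len(mutants), (a + 1) * len(mutants))
            Z[:, col_of[pid]] = r["z"][sl]
            C[:, col_of[pid]] = r["coef"][sl]
            E[:, col_of[pid]] = r["se"][sl]
    idx = pd.Index(mutants, name="strain")
    cols = pd.Index(params, name="param")
    return ZMatrix(z=pd.DataFrame(Z, idx, cols), coef=pd.DataFrame(C, idx, cols),
                   se=pd.DataFrame(E, idx, cols))


def permutation_z(ds: MorphDataset, fits: dict, n_perm: int, n_mut: int, seed):
    """Null Z profiles from pseudo-mutants drawn from the WT replicate pool.

    The same ``n_perm`` row subsets are applied to every parameter so each
    permutation replicate is a coherent pseudo-mutant profile; parameters
    sharing a family are recomputed in one stacked batch.
    """
    rng = np.random.default_rng(seed)
    wt = ds.wt_strain_id
    n0 = len(ds.rows_of(wt))
    if n0 <= n_mut:
        raise ValueError(f"WT pool ({n0}) must exceed pseudo-mutant size ({n_mut})")
    mut = np.zeros((n_perm, n0), dtype=bool)
    for b in range(n_perm):
        mut[b, rng.choice(n0, size=n_mut, replace=False)] = True
    params = [p for p in ds.analyzable_params() if p in fits]
    col_of = {p: j for j, p in enumerate(params)}
    Zp = np.full((n_perm, len(params)), np.nan)
    for fam_name, pids in _by_family(params, fits).items():
        P = len(pids)
        y = np.repeat(np.stack([ds.param_values(p, wt).to_numpy() for p in pids]),
                      n_perm, axis=0)
        trials = None
        if ds.meta[pids[0]].trials_column is not None:
            trials = np.repeat(
                np.stack([ds.trials_of(p, wt).to_numpy() for p in pids]),
                n_perm, axis=0)
        mm = np.tile(mut, (P, 1))
        r = wald_batch(fam_name, y, mm, trials=trials, min_group=(5, 2))
        for a, pid in enumerate(pids):
            Zp[:, col_of[pid]] = r["z"][a * n_perm:(a + 1) * n_perm]
    return pd.DataFrame(Zp, columns=pd.Index(params, name="param"))


def permutation_fdr(zm: ZMatrix, ds: MorphDataset, fits: dict,
                    n_perm: int = 2000, alpha: float = 0.05, seed=0,
                    n_mut: Optional[int] = None, perm_z=None) -> ZMatrix:
    """Set significance flags by a permutation estimate of the FDR.

    For each candidate threshold t (the sorted observed |Z| values),
    ``FDR(t) = E_perm[#{|Z_perm| >= t}] * n_strains / #{|Z_obs| >= t}``,
    clipped to [0,1] and monotonized to be non-increasing in t.  The global
    threshold t* is the smallest t with FDR(t) <= alpha.
    """
    if n_mut is None:
        counts = [len(ds.rows_of(s)) for s in ds.mutants]
        n_mut = int(np.median(counts)) if counts else 5
    if perm_z is None:
        perm_z = permutation_z(ds, fits, n_perm, n_mut, seed)
    Zp = perm_z.to_numpy()
    zobs = zm.z.to_numpy()
    obs = np.sort(np.abs(zobs[np.isfinite(zobs)]))
    S = zobs.shape[0]
    perm = np.sort(np.abs(Zp[np.isfinite(Zp)]))
    if obs.size == 0:
        t_star = np.inf
        curve = pd.DataFrame(columns=["t", "fdr"])
    else:
        grid = obs[::-1]                     # decreasing thresholds
        n_obs_ge = np.arange(1, obs.size + 1)            # rejections at grid
        n_perm_ge = perm.size - np.searchsorted(perm, grid, side="left")
        fdr = (n_perm_ge / n_perm) * S / n_obs_ge
        fdr = np.minimum.accumulate(fdr[::-1])[::-1]     # non-increasing in t
        fdr = np.clip(fdr, 0.0, 1.0)
        passing = np.flatnonzero(fdr <= alpha)
        t_star = float(grid[passing[-1]]) if passing.size else np.inf
        curve = pd.DataFrame({"t": grid, "fdr": fdr})
    flags = pd.DataFrame(np.abs(zm.z.to_numpy()) >= t_star,
                         index=zm.z.index, columns=zm.z.columns)
    flags &= zm.z.notna()
    return ZMatrix(z=zm.z, coef=zm.coef, se=zm.se, flags=flags,
                   threshold=t_star, fdr_level=alpha, n_permutations=n_perm,
                   seed=seed, fdr_curve=curve)
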