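"""Decoupling CV parameters from their paired means via LOESS.

Coefficient-of-variation parameters depend nonlinearly on their paired mean
parameter (cell-to-cell variability shrinks with the mean).  To analyze the
variability itself, each CV parameter is regressed on its mean partner with
LOESS (local linear regression, tricube kernel, no robustness iterations) and
replaced by the residual, called the *noise* parameter: observed CV minus
predicted CV.

The smoothing span f (the fraction of points in each local neighborhood) is
chosen per parameter by AIC over a grid 0.10, 0.11, ..., 0.99.  Because a
smoother has no parameter count, the model dimension entering the AIC is the
effective degrees of freedom tr(L), the trace of the linear smoother matrix,
with a Gaussian residual likelihood.  The small-sample (AICc) form of
Hurvich, Simonoff & Tsai (1998) is used,

    AIC(f) = n log(RSS/n) + n + 2 n (tr(L) + 1) / (n - tr(L) - 2),

because the uncorrected penalty is known to undersmooth badly at these
sample sizes (it happily picks the smallest span on pure noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MorphDataset
from .meta import ParameterMeta, MetaTable

log = logging.getLogger(__name__)

__all__ = ["NoiseModel", "SpanError", "fit_loess", "select_span", "to_noise",
           "DEFAULT_SPAN_GRID"]

DEFAULT_SPAN_GRID = np.round(np.arange(0.10, 0.995, 0.01), 2)  # 0.10 .. 0.99


class SpanError(ValueError):
    """Neighborhood too small for local linear regression."""


@dataclass
class NoiseModel:
    """Fitted CV-vs-mean smoother for one parameter pair."""

    cv_param_id: str
    mean_param_id: str
    span: float
    x: np.ndarray                 # observed means (fit order)
    fitted: np.ndarray            # LOESS predictions at x
    residuals: np.ndarray         # observed - fitted
    edf: float                    # tr(L)
    aic: float
    aic_by_span: dict = field(default_factory=dict)

    def predict(self, x_new):
        """Evaluate the fitted curve; linear extrapolation outside the range."""
        order = np.argsort(self.x, kind="stable")
        xs, ys = self.x[order], self.fitted[order]
        xs, keep = np.unique(xs, return_index=True)
        ys = ys[keep]
        x_new = np.asarray(x_new, dtype=float)
        out = np.interp(x_new, xs, ys)
        if len(xs) >= 2:
            lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out = np.where(x_new < xs[0], ys[0] + (x_new - xs[0]) * lo_slope, out)
            out = np.where(x_new > xs[-1], ys[-1] + (x_new - xs[-1]) * hi_slope, out)
        return out


def _smoother_matrix(x, f, _cache=None):
    """Tricube-weighted local-linear smoother matrix L with yhat = L @ y."""
    x = np.asarray(x, dtype=float)
    n = x.size
    q = int(np.ceil(f * n))
    if q < 3:
        raise SpanError(f"span {f} gives neighborhood of {q} < 3 points (n={n})")
    if _cache is not None:
        d, dsort = _cache
    else:
        d = np.abs(x[:, None] - x[None, :])
        dsort = np.sort(d, axis=1)
    h = dsort[:, q - 1]
    h = np.maximum(h, 1e-300)
    u = np.clip(d / h[:, None], 0.0, 1.0)
    w = 1.0 - u * u * u
    w *= w * w
    dx = x[None, :] - x[:, None]
    s0 = w.sum(axis=1)
    s1 = (w * dx).sum(axis=1)
    s2 = (w * dx ** 2).sum(axis=1)
    denom = s0 * s2 - s1 ** 2
    safe = denom > 1e-12 * np.maximum(s0 * s2, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = w * (s2[:, None] - dx * s1[:, None]) / denom[:, None]
        L_mean = w / s0[:, None]                 # fallback: local constant
    return np.where(safe[:, None], L, L_mean)


def fit_loess(cv, mean, f, cv_param_id="cv", mean_param_id="mean",
              _cache=None) -> NoiseModel:
    """Single-span LOESS of cv on mean; residuals define the noise values."""
    cv = np.asarray(cv, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if cv.shape != mean.shape:
        raise ValueError("cv and mean must have equal length")
    if cv.size < 10:
        raise SpanError(f"need at least 10 points, got {cv.size}")
    if not (0 < f <= 1):
        raise ValueError(f"span must lie in (0, 1], got {f}")
    L = _smoother_matrix(mean, f, _cache=_cache)
    fitted = L @ cv
    resid = cv - fitted
    edf = float(np.trace(L))
    n = cv.size
    rss = float(resid @ resid)
    aic = _smoother_aic(n, rss, edf)
    return NoiseModel(cv_param_id, mean_param_id, float(f), mean, fitted,
                      resid, edf, aic)


def _smoother_aic(n, rss, tr):
    """AICc for a linear smoother with effective dimension tr(L)."""
    denom = np.maximum(n - tr - 2.0, 1e-9)
    return n * np.log(np.maximum(rss, 1e-300) / n) + n + 2.0 * n * (tr + 1.0) / denom


def _span_scan(y, x, spans):
    """AIC of the local-linear fit at each span, without materializing L.

    Exploits that only the fitted values, the residual sum of squares and
    the smoother trace (sum of diagonal weights) are needed; spans are
    processed in chunks as stacked array programs.
    """
    n = x.size
    d = np.abs(x[:, None] - x[None, :])
    dsort = np.sort(d, axis=1)
    dx = x[None, :] - x[:, None]
    qs = np.ceil(np.asarray(spans) * n).astype(int)
    aics = np.full(len(spans), np.nan)
    chunk = max(1, int(1.2e6 // (n * n)))
    for start in range(0, len(spans), chunk):
        sel = slice(start, min(start + chunk, len(spans)))
        q = qs[sel]
        h = np.maximum(dsort[:, q - 1].T, 1e-300)        # (S, n)
        u = np.clip(d[None, :, :] / h[:, :, None], 0.0, 1.0)
        w = 1.0 - u * u * u
        w *= w * w                                       # tricube
        s0 = w.sum(axis=-1)
        wdx = w * dx[None]
        s1 = wdx.sum(axis=-1)
        s2 = (wdx * dx[None]).sum(axis=-1)
        T0 = w @ y
        T1 = wdx @ y
        denom = s0 * s2 - s1 ** 2
        safe = denom > 1e-12 * np.maximum(s0 * s2, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            fitted = np.where(safe, (s2 * T0 - s1 * T1) / denom, T0 / s0)
            ldiag = np.where(safe, s2 / denom, 1.0 / s0)
        rss = ((y[None, :] - fitted) ** 2).sum(axis=-1)
        tr = ldiag.sum(axis=-1)
        aics[sel] = _smoother_aic(n, rss, tr)
    return aics


def select_span(cv, mean, grid=None, cv_param_id="cv", mean_param_id="mean") -> NoiseModel:
    """Fit LOESS at every span in ``grid`` and return the minimum-AIC model."""
    grid = DEFAULT_SPAN_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid < 0.10 - 1e-9) | (grid > 0.99 + 1e-9)):
        raise ValueError("span grid must lie within [0.10, 0.99]")
    cv = np.asarray(cv, dtype=float)
    x = np.asarray(mean, dtype=float)
    usable = [float(f) for f in grid if int(np.ceil(f * x.size)) >= 3]
    if not usable or cv.size < 10:
        raise SpanError(
            f"all spans failed: n={cv.size} too small for grid {grid[:3]}...")
    aics = _span_scan(cv, x, usable)
    j = int(np.nanargmin(np.round(np.asarray(aics) / 1e-12) * 1e-12))
    best = fit_loess(cv, mean, usable[j], cv_param_id, mean_param_id)
    best.aic_by_span = dict(zip(usable, aics))
    return best


def to_noise(ds: MorphDataset, grid=None, on: str = "all", models=None):
    """Replace every CV column by its LOESS residual (noise) column.

    ``on`` selects the fitting population: ``"all"`` rows pooled (default;
    mutant means outside the WT range are still interpolated by their own
    fit) or ``"wt"`` (fit on wild-type rows, predict everywhere).
    Passing previously fitted ``models`` (e.g. from a paired dataset sharing
    the wild type) skips refitting and only applies their curves.
    Returns ``(dataset, models)`` where ``models`` maps cv param ids to their
    :class:`NoiseModel` provenance.
    """
    cv_ids = [p for p in ds.param_ids if p in ds.meta and ds.meta[p].data_type == "cv"]
    if not cv_ids:
        return ds, {}
    values = ds.values.copy()
    entries = []
    for e in ds.meta:
        if e.param_id in cv_ids:
            entries.append(ParameterMeta(e.param_id, e.category, "noise",
                                         unimodal=e.unimodal))
        else:
            entries.append(e)
    fitted = dict(models) if models else {}
    models = {}
    for pid in cv_ids:
        partner = ds.meta[pid].mean_partner
        if partner not in values.columns:
            log.warning("to_noise: %s has no partner column %s — skipped", pid, partner)
            continue
        cv_col = ds.values[pid]
        m_col = ds.values[partner]
        if pid in fitted:
            model = fitted[pid]
        else:
            if on == "wt":
                sub = pd.DataFrame({"cv": cv_col.loc[ds.wt_strain_id].to_numpy(),
                                    "m": m_col.loc[ds.wt_strain_id].to_numpy()}).dropna()
            else:
                sub = pd.DataFrame({"cv": cv_col, "m": m_col}).dropna()
            if len(sub) < 10:
                log.warning("to_noise: %s has %d complete pairs (<10) — skipped",
                            pid, len(sub))
                continue
            model = select_span(sub["cv"].to_numpy(), sub["m"].to_numpy(), grid,
                                cv_param_id=pid, mean_param_id=partner)
        pred = model.predict(m_col.to_numpy())
        values[pid] = np.where(np.isfinite(cv_col.to_numpy()) &
                               np.isfinite(m_col.to_numpy()),
                               cv_col.to_numpy() - pred, np.nan)
        models[pid] = model
    out = MorphDataset(values=values, cell_count=ds.cell_count,
                       meta=MetaTable(entries), wt_strain_id=ds.wt_strain_id,
                       trials=ds.trials)
    return out, models
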