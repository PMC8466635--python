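"""Seeded generator of CalMorph-like replicate tables.

The generator emulates the statistical structure the analysis assumes, at the
replicate level (it does not simulate single cells or images):

* each parameter has a data type (nonneg / ratio / cv / proportion) and a
  generative family legal for that type, with parameters drawn once per
  dataset from realistic ranges;
* CV parameters are tied to a mean partner through a smooth monotone
  coupling ``cv = a * (mean/mean0)^power + b`` times multiplicative noise, so
  the documented nonlinear CV-mean dependency holds and LOESS decoupling has
  something to remove;
* proportion parameters are emitted as integer (successes, trials) pairs,
  with trials drawn per replicate as class counts out of the detected cells;
* mutant effects are shifts of the location parameter on its link scale,
  expressed in units of the wild-type link-scale standard deviation, so one
  effect-size knob is comparable across families.

Defaults mirror the study conditions: 490 unimodal parameters split over the
four types, 5 replicates per mutant, detected cell counts in [200, 600], and
a 100-replicate wild-type pool forming the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit, polygamma

from .data import MorphDataset
from .meta import MetaTable, ParameterMeta

__all__ = ["EffectSpec", "GeneratorConfig", "generate_dataset", "plant_clusters",
           "draw_family"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """One planted perturbation: shift the location of ``param_id`` for
    ``strain_id`` by ``effect_size`` WT link-scale SDs."""

    strain_id: str
    param_id: str
    effect_size: float
    cluster_label: Optional[int] = None


_DEFAULT_N_PARAMS = {"nonneg": 220, "ratio": 110, "cv": 110, "proportion": 50}

_LEGAL = {
    "nonneg": ("gamma", "inverse_gamma", "weibull"),
    "ratio": ("beta", "logit_normal"),
    "proportion": ("binomial", "beta_binomial"),
}

_TRIALS_CLASSES = {"n_class_a": 0.55, "n_class_b": 0.30, "n_class_c": 0.15}


@dataclass
class GeneratorConfig:
    n_params: dict = field(default_factory=lambda: dict(_DEFAULT_N_PARAMS))
    n_mutants: int = 32
    n_wt_replicates: int = 100
    n_mut_replicates: int = 5
    families: dict = field(default_factory=dict)   # param_id -> family override
    # cv coupling: cv = a * (mean/mean0)^power + b, times (1 + N(0, noise_sd))
    cv_coupling: tuple = (0.18, 0.02, -0.5)
    cv_noise_sd: float = 0.08
    cell_count_range: tuple = (200, 600)
    dropout_rate: float = 0.0                      # fraction of sub-200-cell rows
    wt_strain_id: str = "WT"
    seed: int = 0

    def __post_init__(self):
        if self.n_mut_replicates < 2:
            raise ConfigError("n_mut_replicates must be >= 2")
        if self.n_params.get("cv", 0) > self.n_params.get("nonneg", 0):
            raise ConfigError("need at least one nonneg partner per cv parameter")
        for pid, fam in self.families.items():
            tp = pid.split("_")[0]
            legal = {"nn": _LEGAL["nonneg"], "ra": _LEGAL["ratio"],
                     "pr": _LEGAL["proportion"]}.get(tp, ())
            if legal and fam not in legal:
                raise ConfigError(f"family {fam!r} illegal for parameter {pid!r}")


# ---------------------------------------------------------------------------
# family draws (natural-scale params as in morphoprofile.families)
# ---------------------------------------------------------------------------

def draw_family(rng, family, params, size, trials=None):
    """Draw ``size`` values from one unimodal family."""
    if family == "gamma":
        return rng.gamma(params["shape"], params["scale"], size)
    if family == "inverse_gamma":
        return 1.0 / rng.gamma(params["shape"], 1.0 / params["scale"], size)
    if family == "weibull":
        return params["scale"] * rng.weibull(params["shape"], size)
    if family == "beta":
        return rng.beta(params["alpha"], params["beta"], size)
    if family == "logit_normal":
        return expit(rng.normal(params["mu"], params["sigma"], size))
    if family == "gaussian":
        return rng.normal(params["mu"], params["sigma"], size)
    if family == "logistic":
        return rng.logistic(params["loc"], params["scale"], size)
    if family == "reverse_gumbel":
        # minimum-Gumbel = negated maximum-Gumbel
        return -(rng.gumbel(-params["loc"], params["scale"], size))
    if family == "binomial":
        return rng.binomial(np.asarray(trials, dtype=int), params["p"]).astype(float)
    if family == "beta_binomial":
        th = (1 - params["rho"]) / params["rho"]
        p = rng.beta(params["p"] * th, (1 - params["p"]) * th, size)
        return rng.binomial(np.asarray(trials, dtype=int), p).astype(float)
    raise ConfigError(f"unknown family {family!r}")


def _link_sd(family, params, mean_trials=None):
    """Approximate per-replicate SD of the link-scale statistic under WT."""
    if family == "gamma" or family == "inverse_gamma":
        return float(np.sqrt(polygamma(1, params["shape"])))
    if family == "weibull":
        return float((np.pi / np.sqrt(6)) / params["shape"])
    if family == "beta":
        a, b = params["alpha"], params["beta"]
        mu, phi = a / (a + b), a + b
        sd_y = np.sqrt(mu * (1 - mu) / (phi + 1))
        return float(sd_y / (mu * (1 - mu)))      # delta method on logit
    if family == "logit_normal":
        return float(params["sigma"])
    if family == "gaussian":
        return float(params["sigma"])
    if family == "logistic":
        return float(params["scale"] * np.pi / np.sqrt(3))
    if family == "reverse_gumbel":
        return float(params["scale"] * np.pi / np.sqrt(6))
    if family == "binomial":
        p, t = params["p"], mean_trials
        return float(np.sqrt(1.0 / (t * p * (1 - p))))
    if family == "beta_binomial":
        p, t, rho = params["p"], mean_trials, params["rho"]
        return float(np.sqrt((1 + rho * (t - 1)) / (t * p * (1 - p))))
    raise ConfigError(f"unknown family {family!r}")


def _shift_location(family, params, delta):
    """Return params with the link-scale location moved by ``delta``."""
    p = dict(params)
    if family in ("gamma", "weibull", "inverse_gamma"):
        p["scale"] = p["scale"] * np.exp(delta)
    elif family == "beta":
        a, b = p["alpha"], p["beta"]
        phi = a + b
        mu = expit(logit(a / phi) + delta)
        p["alpha"], p["beta"] = mu * phi, (1 - mu) * phi
    elif family in ("logit_normal", "gaussian"):
        p["mu"] = p["mu"] + delta
    elif family in ("logistic", "reverse_gumbel"):
        p["loc"] = p["loc"] + delta
    elif family in ("binomial", "beta_binomial"):
        p["p"] = float(expit(logit(p["p"]) + delta))
    else:
        raise ConfigError(f"unknown family {family!r}")
    return p


# ---------------------------------------------------------------------------
# per-parameter generative specs
# ---------------------------------------------------------------------------

def _build_param_specs(cfg: GeneratorConfig, rng):
    """Choose family, natural parameters, category and pairing per parameter."""
    specs = []
    cats = np.array(["actin", "cell", "nucleus"])
    catp = np.array([0.27, 0.48, 0.25])
    trials_cols = list(_TRIALS_CLASSES)

    def cat():
        return str(rng.choice(cats, p=catp))

    n_nn = cfg.n_params.get("nonneg", 0)
    for i in range(n_nn):
        pid = f"nn_{i + 1:03d}"
        fam = cfg.families.get(pid, str(rng.choice(_LEGAL["nonneg"])))
        mean = float(np.exp(rng.uniform(np.log(0.5), np.log(50))))
        if fam == "gamma":
            shape = float(np.exp(rng.uniform(np.log(8), np.log(120))))
            params = {"shape": shape, "scale": mean / shape}
        elif fam == "inverse_gamma":
            shape = float(rng.uniform(6, 40))
            params = {"shape": shape, "scale": mean * (shape - 1)}
        else:
            shape = float(rng.uniform(2.0, 6.0))
            params = {"shape": shape, "scale": mean}
        specs.append(dict(param_id=pid, data_type="nonneg", family=fam,
                          params=params, category=cat()))

    for i in range(cfg.n_params.get("ratio", 0)):
        pid = f"ra_{i + 1:03d}"
        fam = cfg.families.get(pid, str(rng.choice(_LEGAL["ratio"])))
        mu = float(rng.uniform(0.1, 0.9))
        if fam == "beta":
            phi = float(np.exp(rng.uniform(np.log(30), np.log(300))))
            params = {"alpha": mu * phi, "beta": (1 - mu) * phi}
        else:
            params = {"mu": float(logit(mu)), "sigma": float(rng.uniform(0.15, 0.5))}
        specs.append(dict(param_id=pid, data_type="ratio", family=fam,
                          params=params, category=cat()))

    partners = rng.choice(n_nn, size=cfg.n_params.get("cv", 0), replace=False)
    for i, j in enumerate(partners):
        pid = f"cv_{i + 1:03d}"
        specs.append(dict(param_id=pid, data_type="cv", family=None, params={},
                          category=cat(), mean_partner=f"nn_{j + 1:03d}"))

    for i in range(cfg.n_params.get("proportion", 0)):
        pid = f"pr_{i + 1:03d}"
        fam = cfg.families.get(pid, str(rng.choice(_LEGAL["proportion"])))
        p = float(rng.uniform(0.1, 0.9))
        params = {"p": p}
        if fam == "beta_binomial":
            params["rho"] = float(np.exp(rng.uniform(np.log(0.003), np.log(0.03))))
        specs.append(dict(param_id=pid, data_type="proportion", family=fam,
                          params=params, category=cat(),
                          trials_column=trials_cols[i % len(trials_cols)]))
    return specs


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(cfg: GeneratorConfig, effects=()):
    """Generate a seeded replicate-level dataset plus truth tables.

    Returns ``(dataset, truth)`` where ``truth`` is a dict with the planted
    ``effects`` table (strain, param, effect_size, link_sd), per-strain
    ``cluster_labels``, and the per-parameter generative ``param_specs``.

    Each (parameter, strain) block is drawn from its own seeded substream, so
    with a fixed seed the wild-type pool — and every unperturbed mutant
    block — is bit-identical whether or not effects are planted elsewhere.
    """
    rng = np.random.default_rng(cfg.seed)
    specs = _build_param_specs(cfg, rng)
    by_id = {s["param_id"]: s for s in specs}
    for e in effects:
        if e.param_id not in by_id:
            raise ConfigError(f"effect references unknown parameter {e.param_id!r}")
        if not np.isfinite(e.effect_size):
            raise ConfigError(f"non-finite effect size for {e.strain_id}/{e.param_id}")

    strains = [cfg.wt_strain_id] + [f"mut{i + 1:02d}" for i in range(cfg.n_mutants)]
    for e in effects:
        if e.strain_id not in strains:
            raise ConfigError(f"effect references unknown strain {e.strain_id!r}")
    n_reps = {s: (cfg.n_wt_replicates if s == cfg.wt_strain_id
                  else cfg.n_mut_replicates) for s in strains}
    rows = [(s, f"r{j + 1:02d}") for s in strains for j in range(n_reps[s])]
    idx = pd.MultiIndex.from_tuples(rows, names=("strain", "replicate"))
    n_rows = len(idx)

    lo, hi = cfg.cell_count_range
    cells = rng.integers(lo, hi + 1, n_rows)
    if cfg.dropout_rate > 0:
        drop = rng.random(n_rows) < cfg.dropout_rate
        cells = np.where(drop, rng.integers(50, 200, n_rows), cells)
    cell_count = pd.Series(cells.astype(float), index=idx, name="n_cells")

    trials = pd.DataFrame(
        {col: rng.binomial(cells.astype(int), frac).astype(float)
         for col, frac in _TRIALS_CLASSES.items()}, index=idx)

    eff_map = {}
    for e in effects:
        eff_map.setdefault((e.strain_id, e.param_id), 0.0)
        eff_map[(e.strain_id, e.param_id)] += e.effect_size

    mean_cells = 0.5 * (lo + hi)
    values = {}
    truth_rows = []

    def _sub_rng(pj, si):
        return np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(pj, si)))

    # non-cv parameters first (cv needs the partner's realized values)
    for pj, s in enumerate(specs):
        if s["data_type"] == "cv":
            continue
        pid, fam = s["param_id"], s["family"]
        tcol = s.get("trials_column")
        mt = None
        if tcol is not None:
            mt = mean_cells * _TRIALS_CLASSES[tcol]
        sd = _link_sd(fam, s["params"], mean_trials=mt)
        s["link_sd"] = sd
        col = np.empty(n_rows)
        pos = 0
        for si, strain in enumerate(strains):
            m = n_reps[strain]
            delta = eff_map.get((strain, pid), 0.0) * sd
            params = _shift_location(fam, s["params"], delta) if delta else s["params"]
            t = trials[tcol].to_numpy()[pos:pos + m] if tcol else None
            col[pos:pos + m] = draw_family(_sub_rng(pj, si), fam, params, m, trials=t)
            if delta:
                truth_rows.append((strain, pid, eff_map[(strain, pid)], sd))
            pos += m
        values[pid] = col

    a, b, power = cfg.cv_coupling
    mean0 = np.exp(0.5 * (np.log(0.5) + np.log(50)))   # mid of the mean range
    for pj, s in enumerate(specs):
        if s["data_type"] != "cv":
            continue
        pid = s["param_id"]
        partner = values[s["mean_partner"]]
        base = a * (partner / mean0) ** power + b
        # residual scale: multiplicative noise around the coupling curve
        sd = float(np.median(base) * cfg.cv_noise_sd)
        s["link_sd"] = sd
        col = np.empty(n_rows)
        pos = 0
        for si, strain in enumerate(strains):
            m = n_reps[strain]
            eps = _sub_rng(pj, si).normal(0.0, cfg.cv_noise_sd, m)
            seg = base[pos:pos + m] * (1.0 + eps)
            delta = eff_map.get((strain, pid), 0.0) * sd
            if delta:
                seg = seg + delta
                truth_rows.append((strain, pid, eff_map[(strain, pid)], sd))
            col[pos:pos + m] = seg
            pos += m
        values[pid] = np.maximum(col, 1e-6)

    order = [s["param_id"] for s in specs]
    vdf = pd.DataFrame({p: values[p] for p in order}, index=idx)

    meta = MetaTable([ParameterMeta(
        param_id=s["param_id"], category=s["category"], data_type=s["data_type"],
        mean_partner=s.get("mean_partner"), trials_column=s.get("trials_column"),
        unimodal=True) for s in specs])

    ds = MorphDataset(values=vdf, cell_count=cell_count, meta=meta,
                      wt_strain_id=cfg.wt_strain_id, trials=trials)

    labels = {}
    for e in effects:
        if e.cluster_label is not None:
            labels[e.strain_id] = e.cluster_label
    truth = {
        "effects": pd.DataFrame(truth_rows,
                                columns=["strain", "param", "effect_size", "link_sd"]),
        "cluster_labels": pd.Series(labels, dtype="Int64", name="cluster"),
        "param_specs": specs,
    }
    return ds, truth


def plant_clusters(k, n_strains, separation, n_sig_params, seed,
                   param_ids=None, strain_ids=None):
    """Partition strains into ``k`` groups sharing effect-space directions.

    Each group gets a random unit direction over a common set of
    ``n_sig_params`` affected parameters, scaled by ``separation`` (link-scale
    SD units).  Returns ``(effects, labels)``.
    """
    if k > n_strains:
        raise ConfigError("k must not exceed n_strains")
    rng = np.random.default_rng(seed)
    if strain_ids is None:
        strain_ids = [f"mut{i + 1:02d}" for i in range(n_strains)]
    if param_ids is None:
        param_ids = [f"nn_{i + 1:03d}" for i in range(n_sig_params)]
    affected = list(rng.choice(param_ids, size=min(n_sig_params, len(param_ids)),
                               replace=False))
    labels = {s: int(i % k) for i, s in enumerate(strain_ids)}
    effects = []
    for c in range(k):
        v = rng.normal(size=len(affected))
        v = v / np.linalg.norm(v) * separation
        for s in strain_ids:
            if labels[s] != c:
                continue
            for pid, e in zip(affected, v):
                effects.append(EffectSpec(s, pid, float(e), cluster_label=c))
    return effects, pd.Series(labels, name="cluster")
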