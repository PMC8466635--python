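import numpy as np
import pytest

from morphoprofile.differential import (permutation_fdr, permutation_z,
                                        select_families, wald_batch, wald_z,
                                        z_matrix)
from morphoprofile.families import fit_family
from morphoprofile.noise import to_noise
from morphoprofile.data import filter_min_cells
from morphoprofile.synthetic import EffectSpec, GeneratorConfig, generate_dataset


def _prep(ds):
    ds, _ = to_noise(filter_min_cells(ds))
    return ds, select_families(ds)


class TestWaldZ:
    def test_identical_empirical_distributions_give_zero(self, rng):
        wt = rng.normal(0, 1, 10)
        mut = wt[[7, 3, 1, 9, 0, 5, 2, 8, 6, 4]]
        fit = fit_family(wt, "gaussian")
        coef, se, z = wald_z(wt, mut, fit)
        assert coef == pytest.approx(0.0, abs=1e-12)
        assert z == pytest.approx(0.0, abs=1e-10)

    def test_large_shift_direction_and_magnitude(self, rng):
        wt = rng.normal(0, 1, 100)
        mut = np.full(5, 5.0)
        fit = fit_family(wt, "gaussian")
        _, _, z = wald_z(wt, mut, fit)
        assert z > 5

    def test_group_size_preconditions(self, rng):
        fit = fit_family(rng.normal(0, 1, 20), "gaussian")
        with pytest.raises(ValueError, match="mutant"):
            wald_z(rng.normal(0, 1, 20), [1.0], fit)
        with pytest.raises(ValueError, match="wild-type"):
            wald_z([0.0, 1.0, 2.0], [1.0, 2.0], fit)

    @pytest.mark.parametrize("family,sampler", [
        ("gaussian", lambda r, s: r.normal(0, 1, s)),
        ("gamma", lambda r, s: r.gamma(20, 0.5, s)),
        ("beta", lambda r, s: r.beta(5, 15, s)),
    ])
    def test_null_calibration(self, family, sampler):
        """Both groups from the same distribution: Z is close to N(0,1)."""
        r = np.random.default_rng(2_000_000 + len(family) * 131)
        B, n0, n1 = 2000, 100, 5
        y = sampler(r, (B, n0 + n1))
        mut = np.zeros((B, n0 + n1), dtype=bool)
        mut[:, n0:] = True
        res = wald_batch(family, y, mut)
        z = res["z"][np.isfinite(res["z"])]
        assert 0.9 <= z.std() <= 1.1
        assert 0.035 <= np.mean(np.abs(z) > 1.96) <= 0.065

    def test_antisymmetric_under_group_swap(self, rng):
        wt = rng.gamma(10, 1, 40)
        mut = rng.gamma(10, 1.3, 40)
        fit = fit_family(wt, "gamma")
        _, _, z_fwd = wald_z(wt, mut, fit)
        _, _, z_rev = wald_z(mut, wt, fit)
        assert z_fwd == pytest.approx(-z_rev, abs=1e-6)

    def test_matches_pooled_z_for_gaussian(self, rng):
        """Gaussian Wald Z equals the classical pooled two-sample z statistic
        up to the n vs n-2 variance convention."""
        for _ in range(5):
            a = rng.normal(0, 1, 60)
            b = rng.normal(0.4, 1, 50)
            fit = fit_family(a, "gaussian")
            _, _, z = wald_z(a, b, fit)
            n = len(a) + len(b)
            sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / n
            z_ref = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
            assert z == pytest.approx(z_ref, rel=0.02)

    def test_analytic_information_matches_numeric_hessian(self, rng):
        B, n0, n1 = 50, 60, 6
        mut = np.zeros((B, n0 + n1), dtype=bool)
        mut[:, n0:] = True
        t = rng.integers(80, 200, (B, n0 + n1)).astype(float)
        cases = {
            "gaussian": rng.normal(0, 1, (B, n0 + n1)),
            "gamma": rng.gamma(8, 1, (B, n0 + n1)),
            "weibull": 2 * rng.weibull(2.5, (B, n0 + n1)),
            "inverse_gamma": 1 / rng.gamma(9, 1, (B, n0 + n1)),
            "beta": rng.beta(4, 9, (B, n0 + n1)),
            "logit_normal": 1 / (1 + np.exp(-rng.normal(0, .6, (B, n0 + n1)))),
            "logistic": rng.logistic(0, 1, (B, n0 + n1)),
            "reverse_gumbel": -rng.gumbel(0, 1, (B, n0 + n1)),
        }
        for fam, y in cases.items():
            ra = wald_batch(fam, y, mut)
            rn = wald_batch(fam, y, mut, numeric_hessian=True)
            np.testing.assert_allclose(ra["se"], rn["se"], rtol=2e-3,
                                       err_msg=fam)
        for fam in ("binomial", "beta_binomial"):
            k = rng.binomial(t.astype(int), rng.beta(30, 70, (B, n0 + n1))).astype(float)
            ra = wald_batch(fam, k, mut, trials=t)
            rn = wald_batch(fam, k, mut, trials=t, numeric_hessian=True)
            np.testing.assert_allclose(ra["se"], rn["se"], rtol=2e-3, err_msg=fam)


class TestZMatrix:
    def test_grid_shape_and_missingness(self, tiny_study):
        ds, _ = tiny_study
        ds = ds.copy()
        # knock out one parameter for one strain entirely
        ds.values.loc["mut03", "nn_001"] = np.nan
        dsn, fits = _prep(ds)
        zm = z_matrix(dsn, fits)
        assert zm.z.shape == (8, len(dsn.analyzable_params()))
        assert np.isnan(zm.z.loc["mut03", "nn_001"])
        others = zm.z.loc[zm.z.index != "mut03", "nn_001"]
        assert others.notna().all()

    def test_planted_effect_recovered_with_sign(self, tiny_study):
        ds, _ = tiny_study
        cfg = GeneratorConfig(
            n_params={"nonneg": 40, "ratio": 20, "cv": 16, "proportion": 10},
            n_mutants=8, n_wt_replicates=40, seed=2024)
        up = EffectSpec("mut01", "ra_003", 6.0)
        down = EffectSpec("mut02", "nn_021", -6.0)
        ds2, _ = generate_dataset(cfg, [up, down])
        dsn, fits = _prep(ds2)
        zm = z_matrix(dsn, fits)
        assert zm.z.loc["mut01", "ra_003"] > 4
        assert zm.z.loc["mut02", "nn_021"] < -4


@pytest.fixture(scope="module")
def null_run():
    cfg = GeneratorConfig(
        n_params={"nonneg": 30, "ratio": 15, "cv": 10, "proportion": 8},
        n_mutants=6, n_wt_replicates=50, seed=77)
    ds, _ = generate_dataset(cfg)
    dsn, _ = to_noise(filter_min_cells(ds))
    fits = select_families(dsn)
    zm = z_matrix(dsn, fits)
    return dsn, fits, zm


class TestPermutationFDR:
    def test_null_percentile_behavior(self, null_run):
        dsn, fits, zm = null_run
        z = zm.z.to_numpy()
        frac = np.nanmean(np.abs(z) > 1.96)
        assert 0.02 <= frac <= 0.09

    def test_fdr_curve_monotone_and_flags_consistent(self, null_run):
        dsn, fits, zm = null_run
        flagged = permutation_fdr(zm, dsn, fits, n_perm=200, alpha=0.05, seed=5)
        curve = flagged.fdr_curve
        # FDR estimate is non-increasing in the threshold
        assert (np.diff(curve.sort_values("t")["fdr"].to_numpy()) <= 1e-12).all()
        # flag <=> |Z| >= t*
        expect = (zm.z.abs() >= flagged.threshold) & zm.z.notna()
        assert flagged.flags.equals(expect)

    def test_alpha_monotonicity(self, null_run):
        dsn, fits, zm = null_run
        f1 = permutation_fdr(zm, dsn, fits, n_perm=200, alpha=0.02, seed=5)
        f2 = permutation_fdr(zm, dsn, fits, n_perm=200, alpha=0.20, seed=5)
        assert (f2.flags | ~f1.flags).all().all()   # flags(0.02) subset flags(0.2)

    def test_precomputed_perm_z_reused(self, null_run):
        dsn, fits, zm = null_run
        Zp = permutation_z(dsn, fits, 100, 5, seed=9)
        f1 = permutation_fdr(zm, dsn, fits, n_perm=100, alpha=0.05, seed=9)
        f2 = permutation_fdr(zm, dsn, fits, n_perm=100, alpha=0.05, seed=9,
                             perm_z=Zp)
        assert f1.threshold == f2.threshold
        assert f1.flags.equals(f2.flags)

    def test_pool_must_exceed_pseudo_mutant_size(self, null_run):
        dsn, fits, zm = null_run
        with pytest.raises(ValueError, match="exceed"):
            permutation_z(dsn, fits, 10, 50, seed=0)

    def test_strain_dropped_by_filter_absent_from_zmatrix(self):
        cfg = GeneratorConfig(
            n_params={"nonneg": 10, "ratio": 5, "cv": 0, "proportion": 0},
            n_mutants=4, n_wt_replicates=20, seed=3)
        ds, _ = generate_dataset(cfg)
        cc = ds.cell_count.copy()
        cc.loc["mut02"] = 100.0
        ds.cell_count = cc
        dsn, fits = _prep(ds)
        zm = z_matrix(dsn, fits)
        assert "mut02" not in zm.z.index
        assert set(zm.z.index) == {"mut01", "mut03", "mut04"}
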