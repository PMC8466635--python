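import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from morphoprofile.cluster import pca_reduce
from morphoprofile.data import filter_min_cells
from morphoprofile.differential import select_families, z_matrix
from morphoprofile.noise import to_noise
from morphoprofile.screens import (fitness_pq, profile_correlation, project,
                                   similarity_matrix, storey_qvalues,
                                   wt_axes, wt_replicate_z)
from morphoprofile.synthetic import EffectSpec, GeneratorConfig, generate_dataset

SMALL = {"nonneg": 40, "ratio": 10, "cv": 0, "proportion": 10}


def study_z(seed, effects=()):
    # enough WT replicates that the WT PC axes span (nearly) the full
    # parameter space, so projection preserves profile geometry
    cfg = GeneratorConfig(n_params=dict(SMALL), n_mutants=4,
                          n_wt_replicates=80, seed=seed)
    ds, truth = generate_dataset(cfg, effects)
    ds, _ = to_noise(filter_min_cells(ds))
    fits = select_families(ds)
    return ds, fits, z_matrix(ds, fits)


class TestWTAxes:
    def test_needs_three_replicates(self):
        with pytest.raises(ValueError, match=">= 3"):
            wt_axes(pd.DataFrame(np.zeros((2, 5))))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            wt_axes(pd.DataFrame(np.ones((5, 4))))

    def test_replicates_reproduce_their_own_scores(self, rng):
        Z = pd.DataFrame(rng.normal(0, 1, (10, 20)),
                         columns=[f"p{i}" for i in range(20)])
        axes = wt_axes(Z, ccr_target=1.0)
        S1 = project(Z, axes)
        _, S2 = pca_reduce(Z, ccr_target=1.0)
        np.testing.assert_allclose(S1.to_numpy(), S2.to_numpy()[:, :axes.k],
                                   atol=1e-8)

    def test_leave_one_out_profiles_from_study(self):
        ds, fits, _ = study_z(5)
        wz = wt_replicate_z(ds, fits)
        assert wz.shape[0] == 80
        # under the null the replicate Z-profiles are roughly standard
        z = wz.to_numpy()
        assert 0.7 < np.nanstd(z) < 1.4
        axes = wt_axes(wz, ccr_target=0.99)
        assert 1 <= axes.k <= min(wz.shape) - 1
        assert axes.ccr[axes.k - 1] >= 0.99


class TestProject:
    def test_column_mean_profile_maps_to_origin(self, rng):
        Z = pd.DataFrame(rng.normal(0, 1, (8, 12)),
                         columns=[f"p{i}" for i in range(12)])
        axes = wt_axes(Z, ccr_target=0.99)
        s = project(Z.mean(axis=0).to_numpy(), axes)
        np.testing.assert_allclose(s, 0.0, atol=1e-10)

    def test_equal_queries_equal_scores(self, rng):
        Z = pd.DataFrame(rng.normal(0, 1, (8, 12)),
                         columns=[f"p{i}" for i in range(12)])
        axes = wt_axes(Z, ccr_target=0.99)
        q = rng.normal(0, 1, 12)
        np.testing.assert_allclose(project(q, axes), project(q.copy(), axes))

    def test_loading_direction_scores_on_first_axis(self, rng):
        Z = pd.DataFrame(rng.normal(0, 1, (9, 15)))
        axes = wt_axes(Z, ccr_target=1.0)
        v = 3.7 * axes.components_[0]
        s = project(axes.mean_ + v, axes)
        assert s[0] == pytest.approx(3.7, abs=1e-8)
        np.testing.assert_allclose(s[1:], 0.0, atol=1e-8)

    def test_linearity_after_centering_correction(self, rng):
        Z = pd.DataFrame(rng.normal(0, 1, (8, 10)))
        axes = wt_axes(Z, ccr_target=1.0)
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        a, b = 2.0, 3.0
        lhs = project(a * x + b * y, axes)
        # centering is affine: correct by (a+b-1) projections of the origin
        rhs = (a * project(x, axes) + b * project(y, axes)
               - (a + b - 1) * project(np.zeros(10), axes))
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_parameter_mismatch_reported(self, rng):
        Z = pd.DataFrame(rng.normal(0, 1, (6, 8)),
                         columns=[f"p{i}" for i in range(8)])
        axes = wt_axes(Z, ccr_target=0.99)
        bad = pd.DataFrame(rng.normal(0, 1, (2, 5)),
                           columns=[f"p{i}" for i in range(5)])
        with pytest.raises(ValueError, match="lack"):
            project(bad, axes)


class TestProfileCorrelation:
    def test_identical_profiles_unit_correlation(self, rng):
        s = rng.normal(0, 2, 20)
        assert profile_correlation(s, s) == pytest.approx(1.0)

    def test_invariant_to_common_rescaling(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        r1 = profile_correlation(a, b)
        r2 = profile_correlation(5 * a, 5 * b)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_variance_is_missing(self):
        assert np.isnan(profile_correlation(np.ones(5), np.arange(5.0)))

    def test_shared_direction_mutants_correlate(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            pids = [f"nn_{i+1:03d}" for i in range(30)]
            # two mutants share one effect direction, independent noise
            direction = r.normal(0, 1, 30)
            direction = direction / np.linalg.norm(direction) * 10
            effects = [EffectSpec(s, p, float(e))
                       for s in ("mut01", "mut02")
                       for p, e in zip(pids, direction)]
            ds, fits, zm = study_z(300 + seed, effects)
            wz = wt_replicate_z(ds, fits)
            axes = wt_axes(wz, ccr_target=0.99)
            S = project(zm.z, axes)
            r12 = profile_correlation(S.loc["mut01"], S.loc["mut02"])
            hits += r12 > 0.8
        assert hits >= 9

    def test_orthogonal_block_mutants_uncorrelated(self):
        ok = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = [f"nn_{i+1:03d}" for i in range(20)]
            b = [f"nn_{i+21:03d}" for i in range(20)]
            effects = ([EffectSpec("mut01", p, float(e))
                        for p, e in zip(a, r.normal(0, 4, 25))] +
                       [EffectSpec("mut02", p, float(e))
                        for p, e in zip(b, r.normal(0, 4, 25))])
            ds, fits, zm = study_z(600 + seed, effects)
            wz = wt_replicate_z(ds, fits)
            axes = wt_axes(wz, ccr_target=0.99)
            S = project(zm.z, axes)
            r12 = profile_correlation(S.loc["mut01"], S.loc["mut02"])
            ok += abs(r12) < 0.2
        assert ok >= 8

    def test_similarity_matrix_structure(self, rng):
        S = pd.DataFrame(rng.normal(0, 1, (4, 6)),
                         index=["a", "b", "c", "d"])
        res = similarity_matrix(S, k=6)
        R = res.r.to_numpy()
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert np.nanmax(np.abs(R)) <= 1.0 + 1e-12


class TestFitness:
    def test_p_at_wt_mean_is_half(self):
        res = fitness_pq([1.0], wt_mean=1.0, wt_sd=0.2)
        assert res.table["p"].iloc[0] == pytest.approx(0.5)

    def test_p_at_lower_quantile(self):
        res = fitness_pq([1.0 - 1.6449 * 0.2], wt_mean=1.0, wt_sd=0.2)
        assert res.table["p"].iloc[0] == pytest.approx(0.05, abs=1e-4)

    def test_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            fitness_pq([1.0], 0.0, 0.0)

    def test_null_qvalues_control_false_positives(self):
        fp_rates, pi0s = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = r.normal(1.0, 0.1, 100)
            res = fitness_pq(vals, 1.0, 0.1)
            fp_rates.append((res.table["q"] < 0.05).mean())
            pi0s.append(res.pi0)
        assert np.mean(fp_rates) <= 0.05
        assert np.median(pi0s) > 0.8

    def test_q_monotone_in_p(self, rng):
        p = rng.random(200)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_q_relates_to_bh(self, rng):
        """Storey q-values equal BH-adjusted p scaled by pi0 (up to the
        monotonicity pass), hence never fall below BH x pi0."""
        p = np.concatenate([rng.random(150), rng.random(50) * 1e-3])
        q, pi0 = storey_qvalues(p)
        bh = stats.false_discovery_control(p, method="bh")
        assert (q >= bh * pi0 - 1e-9).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=12, max_size=120))
    def test_qvalues_are_valid_for_any_pvector(self, pvals):
        """q-values always lie in [0,1], are monotone in p, and never fall
        below their own p-value scaled by pi0/m... at minimum stay ordered."""
        p = np.asarray(pvals)
        q, pi0 = storey_qvalues(p)
        assert np.all((q >= 0) & (q <= 1))
        assert 0 < pi0 <= 1
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_missing_values_propagate(self):
        res = fitness_pq([0.9, np.nan, 1.1], 1.0, 0.1)
        assert np.isnan(res.table["p"].iloc[1])
        assert np.isnan(res.table["q"].iloc[1])
        assert np.isfinite(res.table["q"]).sum() == 2
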