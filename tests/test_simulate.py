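"""Synthetic-data generator: determinism, recovery, trends, validation."""

import numpy as np
import pandas as pd
import pytest

from plscog import PLSCorrelation
from plscog.connectome import compute_connectivity
from plscog.simulate import (
    LatentGroundTruth,
    add_accumulation_trend,
    generate_battery,
    generate_cohort,
    generate_latent_dataset,
    generate_roi_timeseries,
    population_pls_solution,
    random_ground_truth,
    remove_accumulation_trend,
)


class TestLatentDataset:
    def test_same_seed_identical_dataset(self):
        truth = random_ground_truth(10, 6, 5, effect=2.0, seed=99)
        a = generate_latent_dataset(truth)
        b = generate_latent_dataset(truth)
        assert np.array_equal(a.edges.values, b.edges.values)
        assert a.cognition.scores.equals(b.cognition.scores)

    def test_strong_effect_recovers_planted_saliences(self):
        cos_u, cos_v = [], []
        for seed in range(10):
            truth = random_ground_truth(100, 15, 13, effect=5.0, seed=seed)
            d = generate_latent_dataset(truth)
            res = PLSCorrelation(d.edges, d.cognition).fit()
            cos_u.append(abs(float(res.brain_saliences[:, 0] @ truth.u_true[:, 0])))
            cos_v.append(abs(float(res.behavior_saliences[:, 0] @ truth.v_true[:, 0])))
        assert np.mean(cos_u) > 0.9
        assert np.mean(cos_v) > 0.9

    def test_recovery_monotone_in_effect(self):
        """Mean |cos(u_hat, u_true)| over 50 seeds is non-decreasing in effect."""
        means = []
        for effect in (0.0, 1.0, 5.0):
            cos = []
            for seed in range(50):
                truth = random_ground_truth(26, 10, 8, effect=effect, seed=1000 + seed)
                d = generate_latent_dataset(truth)
                res = PLSCorrelation(d.edges, d.cognition).fit()
                cos.append(abs(float(res.brain_saliences[:, 0] @ truth.u_true[:, 0])))
            means.append(np.mean(cos))
        assert means[0] <= means[1] <= means[2]

    def test_rank_two_truth_validates_and_generates(self):
        truth = random_ground_truth(30, 8, 6, effect=[4.0, 2.0], rank=2, seed=5)
        assert truth.rank == 2
        d = generate_latent_dataset(truth)
        assert d.latent_scores.shape == (30, 2)
        res = PLSCorrelation(d.edges, d.cognition).fit()
        # two planted components dominate the spectrum
        assert res.covariance_explained[:2].sum() > 0.5

    def test_validation_errors(self):
        good = random_ground_truth(10, 5, 4, effect=1.0, seed=0)
        with pytest.raises(ValueError, match="unit-norm"):
            LatentGroundTruth(2 * good.u_true, good.v_true, good.effect, 1.0, 1.0,
                              10, 5, 4, 0)
        with pytest.raises(ValueError, match="effect"):
            LatentGroundTruth(good.u_true, good.v_true, np.array([-1.0]), 1.0, 1.0,
                              10, 5, 4, 0)
        with pytest.raises(ValueError, match="SD"):
            LatentGroundTruth(good.u_true, good.v_true, good.effect, 0.0, 1.0,
                              10, 5, 4, 0)
        with pytest.raises(ValueError, match="edges"):
            LatentGroundTruth(good.u_true[:-1], good.v_true, good.effect, 1.0, 1.0,
                              10, 5, 4, 0)

    def test_connectome_stack_view(self):
        truth = random_ground_truth(6, 5, 4, effect=1.0, seed=3)
        d = generate_latent_dataset(truth)
        stack = d.connectomes()
        assert stack.matrices.shape == (6, 5, 5)
        assert np.allclose(np.diagonal(stack.matrices, axis1=1, axis2=2), 1.0)

    def test_population_solution_matches_large_sample_fit(self):
        """Dual route: closed-form population loadings vs an n=50,000 fit."""
        truth = random_ground_truth(50_000, 10, 8, effect=5.0, seed=42)
        pop = population_pls_solution(truth)
        d = generate_latent_dataset(truth)
        res = PLSCorrelation(d.edges, d.cognition).fit()
        flip = np.sign(float(res.behavior_saliences[:, 0] @ pop.behavior_saliences[:, 0]))
        assert np.allclose(
            flip * res.behavior_loadings[:, 0], pop.behavior_loadings[:, 0], atol=0.02
        )
        assert res.singular_values[0] == pytest.approx(pop.singular_values[0], abs=0.02)


class TestRoiTimeseries:
    def test_uncorrelated_regions_small_sample_correlation(self):
        ts = generate_roi_timeseries(12, 400, within_r=0.0, between_r=0.0, seed=0)
        mat = compute_connectivity(ts)
        off = np.abs(mat[~np.eye(12, dtype=bool)])
        assert off.mean() < 2 / np.sqrt(400)

    def test_two_community_block_structure(self):
        comm = np.repeat([0, 1], 5)
        ts = generate_roi_timeseries(
            10, 2000, community_assignment=comm, within_r=0.9, between_r=0.0, seed=1
        )
        mat = compute_connectivity(ts)
        same = (comm[:, None] == comm[None, :]) & ~np.eye(10, dtype=bool)
        within = mat[same].mean()
        between = mat[(comm[:, None] != comm[None, :])].mean()
        assert within - between > 0.5

    def test_single_region(self):
        ts = generate_roi_timeseries(1, 50, seed=0)
        assert compute_connectivity(ts).shape == (1, 1)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="between_r"):
            generate_roi_timeseries(5, 100, within_r=0.2, between_r=0.5, seed=0)
        with pytest.raises(ValueError, match="positive definite"):
            generate_roi_timeseries(
                20, 100,
                community_assignment=np.arange(20) % 4,
                within_r=0.1, between_r=-0.5, seed=0,
            )


class TestAccumulationTrend:
    def test_zero_rate_is_identity(self, rng):
        ts = pd.DataFrame(rng.standard_normal((40, 3)))
        out = add_accumulation_trend(ts, uptake_rate=0.0, curvature=0.0)
        assert np.allclose(out.to_numpy(), ts.to_numpy())

    def test_positive_rate_gives_positive_slope_everywhere(self, rng):
        ts = pd.DataFrame(rng.standard_normal((100, 4)) * 0.1)
        out = add_accumulation_trend(ts, uptake_rate=5.0, curvature=1.0)
        t = np.linspace(0, 1, 100)
        for col in out:
            slope = np.polyfit(t, out[col], 1)[0]
            assert slope > 0

    def test_decreasing_trend_rejected(self, rng):
        ts = pd.DataFrame(rng.standard_normal((20, 2)))
        with pytest.raises(ValueError, match="decreasing"):
            add_accumulation_trend(ts, uptake_rate=1.0, curvature=-2.0)

    def test_detrend_removes_pure_quadratic(self):
        t = np.linspace(0, 1, 50)
        ts = pd.DataFrame({"a": 3 * t**2 + 2 * t + 1, "b": -t**2})
        out = remove_accumulation_trend(ts, poly_order=2)
        assert np.abs(out.to_numpy()).max() < 1e-8

    def test_detrend_white_noise_only_removes_mean_component(self, rng):
        noise = rng.standard_normal((500, 3))
        noise -= noise.mean(axis=0)
        out = remove_accumulation_trend(pd.DataFrame(noise), poly_order=2)
        # residual differs from input only by the fitted low-order component,
        # which is tiny for long white-noise series
        assert np.abs(out.to_numpy() - noise).max() < 0.5
        assert np.abs(out.to_numpy().mean(axis=0)).max() < 1e-10

    def test_round_trip_recovers_connectivity(self):
        """Planted fluctuations + strong uptake trend, then detrend:
        the correlation matrix matches the trend-free version closely."""
        comm = np.repeat([0, 1], 4)
        ts = generate_roi_timeseries(
            8, 500, community_assignment=comm, within_r=0.6, between_r=0.1, seed=7
        )
        trended = add_accumulation_trend(ts, uptake_rate=20.0, curvature=5.0)
        recovered = remove_accumulation_trend(trended, poly_order=2)
        clean = compute_connectivity(ts)
        redone = compute_connectivity(recovered)
        assert np.abs(clean - redone).max() < 0.05

    def test_too_short_series_rejected(self, rng):
        ts = pd.DataFrame(rng.standard_normal((3, 2)))
        with pytest.raises(ValueError, match="timepoints"):
            remove_accumulation_trend(ts, poly_order=2)


class TestBatteryAndCohort:
    def test_battery_scores_14_variables(self):
        cog = generate_battery(n_subjects=26, seed=1)
        assert cog.n_variables == 14
        assert cog.n_subjects == 26
        assert (cog.variables["scale"].isin(["continuous", "ordinal"])).all()

    def test_battery_within_test_correlation(self):
        cog = generate_battery(n_subjects=4000, seed=2, within_test_r=0.5)
        r = np.corrcoef(cog.scores["HVLT_total_recall"], cog.scores["HVLT_delayed_recall"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_battery_deterministic(self):
        a = generate_battery(n_subjects=26, seed=5)
        b = generate_battery(n_subjects=26, seed=5)
        assert a.scores.equals(b.scores)

    def test_cohort_deterministic_and_flagged(self):
        a = generate_cohort(28, seed=9)
        b = generate_cohort(28, seed=9)
        assert a.equals(b)
        assert (a["exclusion_reason"] != "").sum() == 2
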