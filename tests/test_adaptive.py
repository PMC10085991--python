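"""Explore/exploit scoring, seed selection, campaign bookkeeping, and
trajectory descriptors."""

import numpy as np
import pandas as pd
import pytest

from ctdyn.adaptive import (
    CampaignResult,
    SeedingParams,
    contact_frequencies,
    contact_frequency,
    min_distance,
    p_obs,
    rmsd_series,
    run_campaign,
    running_average,
    score_frames,
    select_seeds,
    trajectory_descriptors,
)
from ctdyn.errors import EmptyInputError, InvalidArgumentError
from ctdyn.synthetic import default_double_well, simulate_toy_dynamics


def frames_from(d_values, descriptors=None):
    d = np.asarray(d_values, float)
    desc = d if descriptors is None else np.asarray(descriptors, float)
    return pd.DataFrame({"D": d, "descriptor0": desc})


def toy_engine(landscape=None, dt=0.05):
    land = landscape or default_double_well()

    def engine(x0, n_steps, seed):
        return simulate_toy_dynamics(land, x0=x0, n_steps=n_steps, dt=dt, seed=seed)

    return engine


class TestScoreFrames:
    def test_output_is_probability_distribution(self):
        frames = frames_from(np.linspace(30, 70, 200))
        p = score_frames(frames, SeedingParams())
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exploit_maximum_at_target(self):
        frames = frames_from([30.0, 44.0, 55.0, 70.0])
        p = score_frames(frames, SeedingParams(w1=1.0, w2=0.0, d_target=44.0))
        assert np.argmax(p) == 1

    def test_exploit_monotone_in_target_distance(self):
        d = np.array([44.0, 46.0, 50.0, 58.0, 70.0])
        p = score_frames(frames_from(d), SeedingParams(w1=1.0, w2=0.0, d_target=44.0))
        assert np.all(np.diff(p) <= 1e-15)

    def test_explore_rare_bin_gets_double_probability(self):
        # descriptor bins: A observed twice, B once -> P(B) = 2 P(A)
        frames = frames_from([50.0, 50.0, 50.0], descriptors=[10.0, 10.0, 20.0])
        p = score_frames(
            frames, SeedingParams(w1=0.0, w2=1.0, descriptor_bin_width=2.0)
        )
        assert p[2] == pytest.approx(2 * p[0], rel=1e-12)
        assert p[0] == p[1]

    def test_explore_monotone_in_bin_count(self):
        # adding more observations of A's bin can only lower A's probability
        base = frames_from([50.0] * 4, descriptors=[10.0, 10.0, 20.0, 30.0])
        more = frames_from([50.0] * 5, descriptors=[10.0, 10.0, 10.0, 20.0, 30.0])
        params = SeedingParams(w1=1.0, w2=1.0, distance_bounds=(30.0, 70.0))
        p_base = score_frames(base, params)
        p_more = score_frames(more, params)
        assert p_more[0] < p_base[0]

    def test_identical_frames_uniform(self):
        frames = frames_from([50.0] * 7)
        p = score_frames(frames, SeedingParams())
        np.testing.assert_allclose(p, 1 / 7)

    def test_p_obs_includes_own_observation(self):
        frames = frames_from([1.0, 100.0], descriptors=[1.0, 100.0])
        po = p_obs(frames, bin_width=2.0)
        assert np.all(po >= 1 / len(frames))

    def test_empty_frames_raises(self):
        with pytest.raises(EmptyInputError):
            score_frames(frames_from([]), SeedingParams())

    def test_invalid_weights_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SeedingParams(w1=0.0, w2=0.0)


class TestSelectSeeds:
    def test_deterministic_from_seed(self):
        p = np.full(100, 0.01)
        a = select_seeds(p, 10, seed=5)
        b = select_seeds(p, 10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_zero_probability_never_selected(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        for s in range(100):
            assert set(select_seeds(p, 2, seed=s)) == {0, 1}

    def test_dominant_frame_selected_first(self):
        p = np.array([0.99] + [0.01 / 9] * 9)
        first = sum(select_seeds(p, 1, seed=s)[0] == 0 for s in range(1000))
        assert first >= 970

    def test_too_many_seeds_rejected(self):
        p = np.array([0.5, 0.5, 0.0])
        with pytest.raises(InvalidArgumentError):
            select_seeds(p, 3, seed=0)


class TestCampaign:
    def test_bookkeeping_five_epochs_ten_trajectories(self):
        result = run_campaign(
            toy_engine(), SeedingParams(), epochs=5, trajs_per_epoch=10,
            steps_per_traj=50, x0=60.0, seed=1,
        )
        assert result.frames["traj"].nunique() == 50
        # frames conserved: epochs * trajs * frames_per_traj (51 incl. start)
        assert len(result.frames) == 5 * 10 * 51
        assert len(result.seeds) == 5

    def test_epoch_one_starts_from_initial_state(self):
        result = run_campaign(
            toy_engine(), SeedingParams(), epochs=2, trajs_per_epoch=4,
            steps_per_traj=20, x0=60.0, seed=2,
        )
        first = result.frames[result.frames["epoch"] == 1]
        starts = first[first["frame"] == 0]["D"]
        np.testing.assert_allclose(starts, 60.0)
        np.testing.assert_allclose(result.seeds[0]["start"], 60.0)

    def test_reproducible_from_seed(self):
        kw = dict(epochs=3, trajs_per_epoch=5, steps_per_traj=30, x0=60.0, seed=9)
        a = run_campaign(toy_engine(), SeedingParams(), **kw)
        b = run_campaign(toy_engine(), SeedingParams(), **kw)
        assert a.frames.equals(b.frames)

    def test_naive_mode_restarts_from_x0_every_epoch(self):
        result = run_campaign(
            toy_engine(), SeedingParams(), epochs=3, trajs_per_epoch=3,
            steps_per_traj=20, x0=60.0, seed=4, adaptive=False,
        )
        starts = result.frames[result.frames["frame"] == 0]["D"]
        np.testing.assert_allclose(starts, 60.0)

    def test_enrichment_fraction(self):
        frames = frames_from([40.0, 44.0, 48.0, 60.0])
        res = CampaignResult(
            frames=frames, seeds=[], probabilities=[], params=SeedingParams()
        )
        assert res.enrichment(window=5.0) == 0.75


class TestDescriptors:
    def test_min_distance_simple_pair(self):
        assert min_distance([[0.0, 0.0, 0.0]], [[0.0, 0.0, 3.0]]) == 3.0

    def test_rmsd_identity_is_zero(self, rng):
        coords = rng.normal(size=(5, 8, 3))
        assert rmsd_series(np.repeat(coords[:1], 4, axis=0))[3] == 0.0

    def test_rmsd_vs_start_and_mean(self):
        # two frames offset by a rigid 3 A shift along z
        f0 = np.zeros((4, 3))
        f1 = f0 + np.array([0.0, 0.0, 3.0])
        coords = np.stack([f0, f1])
        np.testing.assert_allclose(rmsd_series(coords), [0.0, 3.0])
        np.testing.assert_allclose(
            rmsd_series(coords, reference=coords.mean(axis=0)), [1.5, 1.5]
        )

    def test_running_average_constant_unchanged(self):
        x = np.full(20, 2.5)
        np.testing.assert_array_equal(running_average(x, 7), x)

    def test_running_average_centered(self):
        x = np.arange(9, dtype=float)
        out = running_average(x, 3)
        np.testing.assert_allclose(out[1:-1], x[1:-1])  # interior exact
        assert out[0] == pytest.approx(0.5)

    def test_trajectory_descriptors_bundle(self, rng):
        coords = rng.normal(scale=2.0, size=(30, 10, 3))
        desc = trajectory_descriptors(coords, set_a=[0, 1], set_b=[8, 9], window=5)
        assert desc.min_distance.shape == (30,)
        assert desc.rmsd_vs_start[0] == 0.0
        assert desc.smoothed["rmsd_vs_mean"].shape == (30,)

    def test_empty_point_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            min_distance(np.empty((0, 3)), [[0.0, 0.0, 0.0]])


class TestContacts:
    @pytest.mark.parametrize("dist, expected", [(3.0, 1.0), (4.0, 0.0)])
    def test_static_pair(self, dist, expected):
        a = np.zeros((10, 1, 3))
        b = np.zeros((10, 1, 3))
        b[:, 0, 2] = dist
        assert contact_frequency(a, b, cutoff=3.5) == expected

    def test_fractional_occupancy_37_of_100(self):
        a = np.zeros((100, 1, 3))
        b = np.zeros((100, 1, 3))
        b[:, 0, 2] = 5.0
        b[:37, 0, 2] = 3.0  # within cutoff in exactly 37 frames
        assert contact_frequency(a, b, cutoff=3.5) == pytest.approx(0.37)

    def test_many_pairs(self):
        a = np.zeros((4, 1, 3))
        near = a.copy()
        near[:, 0, 0] = 3.0
        far = a.copy()
        far[:, 0, 0] = 9.0
        out = contact_frequencies({"near": (a, near), "far": (a, far)})
        assert out["near"] == 1.0
        assert out["far"] == 0.0

    def test_no_frames_raises(self):
        with pytest.raises(EmptyInputError):
            contact_frequency(np.empty((0, 1, 3)), np.empty((0, 1, 3)))

    def test_bad_cutoff_rejected(self):
        with pytest.raises(InvalidArgumentError):
            contact_frequency(np.zeros((1, 1, 3)), np.zeros((1, 1, 3)), cutoff=0.0)
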