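"""Generator-level checks: seeded determinism, degenerate-noise limits,
and agreement of empirical statistics with their closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from ctdyn.dose_response import fit_4pl, four_pl
from ctdyn.errors import InvalidArgumentError
from ctdyn.nmr import compute_csp
from ctdyn.synthetic import (
    BurstModel,
    EmissionModel,
    NmrGroundTruth,
    TitrationGroundTruth,
    ToyLandscape,
    TwoStateKinetics,
    simulate_bursts,
    simulate_peaklists,
    simulate_titration,
    simulate_toy_dynamics,
    simulate_traces,
)

KIN = TwoStateKinetics(k_high_to_low=1.0, k_low_to_high=1.0)
EMISSION = EmissionModel(
    mean_donor_per_state=(600.0, 280.0),
    mean_acceptor_per_state=(400.0, 720.0),
    channel_noise_sd=25.0,
    photobleach_rate=0.05,
)
BURSTS = BurstModel()
TITRATION = TitrationGroundTruth(
    bottom=0.0,
    top=1.0,
    ec50=1e-8,
    hill=1.0,
    concentrations=tuple(10.0 ** np.arange(-9.5, -6.99, 0.5)),
    replicates=3,
    noise_sd=0.03,
)
WELL = ToyLandscape(
    well_centers=(50.0,), well_depths=(100.0,), well_widths=(5.0,),
    diffusion_coefficient=50.0, thermal_energy=1.0,
)


class TestDeterminism:
    def test_traces_bit_identical(self):
        a = simulate_traces(KIN, EMISSION, 5, 10.0, 0.1, seed=42)
        b = simulate_traces(KIN, EMISSION, 5, 10.0, 0.1, seed=42)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)
        for pa, pb in zip(a.state_paths, b.state_paths):
            np.testing.assert_array_equal(pa, pb)

    def test_bursts_bit_identical(self):
        a = simulate_bursts(BURSTS, 200, seed=7)
        b = simulate_bursts(BURSTS, 200, seed=7)
        assert a.bursts.equals(b.bursts)
        np.testing.assert_array_equal(a.true_efficiency, b.true_efficiency)

    def test_titration_and_peaklists_and_dynamics_bit_identical(self, nmr_truth):
        assert simulate_titration(TITRATION, seed=3).equals(
            simulate_titration(TITRATION, seed=3)
        )
        r1, p1 = simulate_peaklists(nmr_truth, seed=3, shift_noise_sd=0.001)
        r2, p2 = simulate_peaklists(nmr_truth, seed=3, shift_noise_sd=0.001)
        assert r1.equals(r2) and p1.equals(p2)
        t1 = simulate_toy_dynamics(WELL, 50.0, 500, seed=5)
        t2 = simulate_toy_dynamics(WELL, 50.0, 500, seed=5)
        np.testing.assert_array_equal(t1.positions, t2.positions)


class TestTraces:
    def test_degenerate_noise_frames_equal_state_means(self):
        quiet = EmissionModel(
            mean_donor_per_state=(600.0, 280.0),
            mean_acceptor_per_state=(400.0, 720.0),
            channel_noise_sd=0.0,
            photobleach_rate=0.0,
        )
        sim = simulate_traces(KIN, quiet, 3, 5.0, 0.1, seed=0)
        for tr, path in zip(sim.traces, sim.state_paths):
            np.testing.assert_array_equal(tr.donor, np.array([600.0, 280.0])[path])
            np.testing.assert_array_equal(tr.acceptor, np.array([400.0, 720.0])[path])

    def test_detailed_balance_occupancy_half(self):
        # symmetric rates: stationary high-state fraction is 1/2; the
        # 3-standard-error band accounts for frame-to-frame correlation
        # of the two-state chain (AR(1) with rho = 1 - 2*k*dt)
        quiet = EmissionModel(
            mean_donor_per_state=(600.0, 280.0),
            mean_acceptor_per_state=(400.0, 720.0),
        )
        sim = simulate_traces(
            KIN, quiet, n_traces=100, duration=100.0, frame_time=0.1, seed=9
        )
        frames = np.concatenate(sim.state_paths)
        assert frames.size == 100_000
        p = 0.1  # per-frame switch probability each way
        rho = 1 - 2 * p
        se = np.sqrt(0.25 / frames.size * (1 + rho) / (1 - rho))
        assert abs(frames.mean() - 0.5) < 3 * se

    def test_dwell_lengths_geometric(self):
        kin = TwoStateKinetics(k_high_to_low=0.5, k_low_to_high=0.5)
        quiet = EmissionModel(
            mean_donor_per_state=(600.0, 280.0),
            mean_acceptor_per_state=(400.0, 720.0),
        )
        sim = simulate_traces(kin, quiet, 200, 120.0, 0.1, seed=2)
        # collect complete (uncensored) dwells straight from the true paths
        lengths = []
        for path in sim.state_paths:
            change = np.flatnonzero(np.diff(path)) + 1
            bounds = np.concatenate([[0], change, [path.size]])
            runs = np.diff(bounds)
            lengths.extend(runs[1:-1])
        lengths = np.asarray(lengths, float)
        assert lengths.size > 10_000
        mean_expected = 1 / (0.5 * 0.1)  # 20 frames
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(lengths.mean() - mean_expected) < 3 * se

    def test_photobleach_times_exponential(self):
        rate = 0.2
        em = EmissionModel(
            mean_donor_per_state=(600.0, 280.0),
            mean_acceptor_per_state=(400.0, 720.0),
            photobleach_rate=rate,
        )
        sim = simulate_traces(KIN, em, 10_000, 1.0, 0.1, seed=11)
        ks = stats.kstest(sim.bleach_times, "expon", args=(0, 1 / rate))
        assert ks.pvalue > 0.01

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            simulate_traces(KIN, EMISSION, 1, -1.0, 0.1)
        with pytest.raises(InvalidArgumentError):
            simulate_traces(KIN, EMISSION, 1, 1.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            TwoStateKinetics(k_high_to_low=0.0, k_low_to_high=1.0)


class TestBursts:
    def test_symmetric_rates_give_half_efficiency(self):
        model = BurstModel(
            photon_rate_donor_per_state=(25_000.0, 25_000.0),
            photon_rate_acceptor_per_state=(25_000.0, 25_000.0),
        )
        sim = simulate_bursts(model, 100, seed=0)
        np.testing.assert_allclose(sim.true_efficiency, 0.5)

    def test_poisson_mean_total_photons(self):
        sim = simulate_bursts(BURSTS, 5000, seed=1)
        durations = sim.bursts["duration"].to_numpy()
        rate_sum = np.where(
            sim.true_state == 1,
            BURSTS.photon_rate_donor_per_state[1] + BURSTS.photon_rate_acceptor_per_state[1],
            BURSTS.photon_rate_donor_per_state[0] + BURSTS.photon_rate_acceptor_per_state[0],
        )
        expected = float(np.sum(rate_sum * durations))
        total = float((sim.bursts["f_donor"] + sim.bursts["f_acceptor"]).sum())
        assert abs(total - expected) < 3 * np.sqrt(expected)  # Poisson sd

    def test_counts_are_integers(self):
        sim = simulate_bursts(BURSTS, 50, seed=2)
        assert sim.bursts["f_donor"].dtype.kind == "i"
        assert sim.bursts["f_acceptor"].dtype.kind == "i"

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            BurstModel(background_rate_donor=-1.0)


class TestTitration:
    def test_noiseless_points_on_curve(self):
        truth = TitrationGroundTruth(
            bottom=0.1, top=0.9, ec50=1e-8, hill=1.3,
            concentrations=TITRATION.concentrations, replicates=2, noise_sd=0.0,
        )
        df = simulate_titration(truth, seed=0)
        expected = four_pl(df["concentration_M"], 0.1, 0.9, 1e-8, 1.3)
        np.testing.assert_allclose(df["response"], expected, rtol=0, atol=1e-15)

    def test_asymptotes(self):
        assert four_pl(1e6 * 1e-8, 0.0, 1.0, 1e-8, 1.0) == pytest.approx(1.0, abs=1e-5)
        assert four_pl(1e-8 / 1e6, 0.0, 1.0, 1e-8, 1.0) == pytest.approx(0.0, abs=1e-5)

    def test_roundtrip_fit_recovers_ec50(self):
        truth = TitrationGroundTruth(
            bottom=0.0, top=1.0, ec50=5.5e-9, hill=1.0,
            concentrations=TITRATION.concentrations, replicates=1, noise_sd=0.0,
        )
        fit = fit_4pl(simulate_titration(truth, seed=0))
        assert fit.ec50 == pytest.approx(5.5e-9, rel=1e-4)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TitrationGroundTruth(
                bottom=0, top=1, ec50=1e-8, hill=1, concentrations=()
            )


class TestPeaklists:
    def test_zero_perturbation_round_trip(self, nmr_truth):
        flat = NmrGroundTruth(
            residues=nmr_truth.residues,
            base_dh=nmr_truth.base_dh,
            base_dn=nmr_truth.base_dn,
            delta_dh=(0.0,) * len(nmr_truth.residues),
            delta_dn=(0.0,) * len(nmr_truth.residues),
            intensity_scaling=(1.0,) * len(nmr_truth.residues),
            missing_residues=nmr_truth.missing_residues,
        )
        ref, probe = simulate_peaklists(flat, seed=0)
        profile = compute_csp(ref, probe)
        np.testing.assert_allclose(profile["csp_ppm"], 0.0)

    def test_requested_perturbation_reproduced(self, nmr_truth):
        ref, probe = simulate_peaklists(nmr_truth, seed=0)
        profile = compute_csp(ref, probe).set_index("residue")
        expected = np.sqrt(0.02**2 + (0.10 / 5) ** 2)
        for r in (350, 351, 353):
            assert profile.loc[r, "csp_ppm"] == pytest.approx(expected, abs=1e-12)
        assert profile.loc[348, "csp_ppm"] == 0.0

    def test_missing_residues_absent(self, nmr_truth):
        ref, probe = simulate_peaklists(nmr_truth, seed=0)
        assert 352 not in set(ref["residue"])
        assert 352 not in set(probe["residue"])

    def test_duplicate_residues_rejected(self):
        with pytest.raises(InvalidArgumentError):
            NmrGroundTruth(
                residues=(350, 350),
                base_dh=(8.0, 8.1),
                base_dn=(115.0, 116.0),
                delta_dh=(0.0, 0.0),
                delta_dn=(0.0, 0.0),
                intensity_scaling=(1.0, 1.0),
            )


class TestToyDynamics:
    def test_stationary_variance_matches_ou_limit(self):
        # Gaussian well: curvature at the bottom is depth/width^2, so the
        # harmonic (Ornstein-Uhlenbeck) stationary variance is kT*w^2/depth
        land = WELL  # depth 100 kT: anharmonic correction ~0.75%
        traj = simulate_toy_dynamics(land, 50.0, 200_000, dt=5e-4, seed=13)
        x = traj.positions[1000:]  # discard relaxation
        expected = land.thermal_energy * 5.0**2 / 100.0
        assert np.var(x) == pytest.approx(expected, rel=0.10)

    def test_zero_thermal_energy_descends_to_nearest_well(self):
        land = ToyLandscape(
            well_centers=(40.0, 60.0), well_depths=(7.0, 7.0),
            well_widths=(5.0, 5.0), diffusion_coefficient=50.0,
            thermal_energy=0.0,
        )
        traj = simulate_toy_dynamics(land, 55.0, 2000, dt=0.01, seed=0)
        assert traj.positions[-1] == pytest.approx(60.0, abs=0.05)
        assert np.all(np.isfinite(traj.positions))

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            ToyLandscape(
                well_centers=(50.0,), well_depths=(1.0,), well_widths=(5.0,),
                diffusion_coefficient=0.0,
            )
        with pytest.raises(InvalidArgumentError):
            simulate_toy_dynamics(WELL, 50.0, 10, dt=0.0)
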