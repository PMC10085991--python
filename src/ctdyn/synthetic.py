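"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* TIRF-style two-channel intensity traces with two-state switching,
  per-channel noise and donor photobleaching (100 ms/frame acquisition);
* confocal photon-burst tables binned at 1000 μs;
* 4PL titration response tables over pM–μM concentration grids;
* assigned NMR peak lists for the receptor C-terminal residues 347-413
  with localized perturbations and intensity scaling;
* toy overdamped-Langevin trajectories carrying a Cys-Cys-distance-like
  scalar observable spanning roughly 30-70 Å.

All generators are pure functions of (parameters, seed): repeated calls
are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import four_pl
from .errors import InvalidArgumentError
from .fret import IntensityTrace

__all__ = [
    "TwoStateKinetics",
    "EmissionModel",
    "BurstModel",
    "TitrationGroundTruth",
    "NmrGroundTruth",
    "ToyLandscape",
    "TraceSimulation",
    "BurstSimulation",
    "ToyTrajectory",
    "simulate_traces",
    "simulate_efficiency_traces",
    "simulate_bursts",
    "simulate_titration",
    "simulate_peaklists",
    "simulate_toy_dynamics",
    "default_double_well",
]

# State order used throughout: index 0 = low-FRET, index 1 = high-FRET.
STATE_LOW, STATE_HIGH = 0, 1


@dataclass(frozen=True)
class TwoStateKinetics:
    """Two-state exchange between a low-FRET and a high-FRET state.

    Rates are continuous-time (s⁻¹) but the generator switches once per
    frame with probability k * frame_time, so dwell lengths are exactly
    geometric with mean 1 / (k * frame_time) frames.
    """

    k_high_to_low: float
    k_low_to_high: float
    initial_state_prob_high: float | None = None

    def __post_init__(self) -> None:
        for k in (self.k_high_to_low, self.k_low_to_high):
            if not (np.isfinite(k) and k > 0):
                raise InvalidArgumentError("rates must be strictly positive and finite")
        p = self.initial_state_prob_high
        if p is not None and not (0.0 <= p <= 1.0):
            raise InvalidArgumentError("initial_state_prob_high must be in [0, 1]")

    def stationary_prob_high(self) -> float:
        return self.k_low_to_high / (self.k_low_to_high + self.k_high_to_low)


@dataclass(frozen=True)
class EmissionModel:
    """Per-state channel intensities for TIRF traces.

    ``mean_donor_per_state`` / ``mean_acceptor_per_state`` are indexed
    (low, high). Channel noise is additive Gaussian (EMCCD readout-
    dominated regime); photobleaching of the donor is an absorbing event
    after which both channels emit background only.
    """

    mean_donor_per_state: tuple[float, ...]
    mean_acceptor_per_state: tuple[float, ...]
    channel_noise_sd: float = 0.0
    photobleach_rate: float = 0.0
    background_per_channel: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.mean_donor_per_state, float)
        a = np.asarray(self.mean_acceptor_per_state, float)
        if d.shape != a.shape or d.ndim != 1:
            raise InvalidArgumentError("per-state means must be equal-length 1-D")
        if np.any(d < 0) or np.any(a < 0):
            raise InvalidArgumentError("channel means must be nonnegative")
        if np.any(d + a <= 0):
            raise InvalidArgumentError("per-state total intensity must be positive")
        if self.channel_noise_sd < 0 or self.photobleach_rate < 0:
            raise InvalidArgumentError("noise sd and bleach rate must be nonnegative")
        if self.background_per_channel < 0:
            raise InvalidArgumentError("background must be nonnegative")

    @property
    def n_states(self) -> int:
        return len(self.mean_donor_per_state)

    def efficiency_per_state(self) -> np.ndarray:
        d = np.asarray(self.mean_donor_per_state, float)
        a = np.asarray(self.mean_acceptor_per_state, float)
        return a / (a + d)


@dataclass(frozen=True)
class BurstModel:
    """Confocal burst generator: Poisson photons during exponential bursts.

    Rates are counts/s per channel, indexed (low, high) like
    EmissionModel; ``state_prob_high`` picks the state of each burst.
    Photons are binned every ``bin_time`` (fixed 1000 μs in acquisition).
    """

    photon_rate_donor_per_state: tuple[float, ...] = (20_000.0, 10_000.0)
    photon_rate_acceptor_per_state: tuple[float, ...] = (20_000.0, 30_000.0)
    background_rate_donor: float = 0.0
    background_rate_acceptor: float = 0.0
    burst_duration_mean: float = 2e-3
    bin_time: float = 1e-3
    state_prob_high: float = 0.5

    def __post_init__(self) -> None:
        rates = np.concatenate(
            [
                np.asarray(self.photon_rate_donor_per_state, float),
                np.asarray(self.photon_rate_acceptor_per_state, float),
                [self.background_rate_donor, self.background_rate_acceptor],
            ]
        )
        if np.any(rates < 0):
            raise InvalidArgumentError("photon rates must be nonnegative")
        if not self.bin_time > 0:
            raise InvalidArgumentError("bin_time must be positive")
        if not self.burst_duration_mean > 0:
            raise InvalidArgumentError("burst_duration_mean must be positive")
        if not 0.0 <= self.state_prob_high <= 1.0:
            raise InvalidArgumentError("state_prob_high must be in [0, 1]")

    def efficiency_per_state(self) -> np.ndarray:
        d = np.asarray(self.photon_rate_donor_per_state, float)
        a = np.asarray(self.photon_rate_acceptor_per_state, float)
        return a / (a + d)


@dataclass(frozen=True)
class TitrationGroundTruth:
    """Generative twin of a 4PL concentration-response experiment."""

    bottom: float
    top: float
    ec50: float
    hill: float
    concentrations: tuple[float, ...]
    replicates: int = 1
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise InvalidArgumentError("ec50 must be positive")
        c = np.asarray(self.concentrations, float)
        if c.size == 0:
            raise InvalidArgumentError("concentration list must be non-empty")
        if np.any(c <= 0):
            raise InvalidArgumentError("concentrations must be positive")
        if np.any(np.diff(c) < 0):
            raise InvalidArgumentError("concentrations must be sorted ascending")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class NmrGroundTruth:
    """Per-residue ground truth for an HSQC peak-list pair.

    Residues cover the C-terminal construct range 347-413; prolines and
    unassigned residues are listed in ``missing_residues`` and appear in
    neither peak list.
    """

    residues: tuple[int, ...]
    base_dh: tuple[float, ...]
    base_dn: tuple[float, ...]
    delta_dh: tuple[float, ...]
    delta_dn: tuple[float, ...]
    intensity_scaling: tuple[float, ...]
    base_intensity: tuple[float, ...] | None = None
    missing_residues: frozenset[int] = frozenset()
    residue_range: tuple[int, int] = (347, 413)

    def __post_init__(self) -> None:
        res = np.asarray(self.residues, int)
        if len(set(res.tolist())) != len(res):
            raise InvalidArgumentError("duplicate residues in ground truth")
        lo, hi = self.residue_range
        if np.any(res < lo) or np.any(res > hi):
            raise InvalidArgumentError(f"residues must lie within [{lo}, {hi}]")
        n = len(res)
        for name in ("base_dh", "base_dn", "delta_dh", "delta_dn", "intensity_scaling"):
            if len(getattr(self, name)) != n:
                raise InvalidArgumentError(f"{name} must match residues in length")
        if self.base_intensity is not None and len(self.base_intensity) != n:
            raise InvalidArgumentError("base_intensity must match residues in length")
        scale = np.asarray(self.intensity_scaling, float)
        if np.any(scale <= 0):
            raise InvalidArgumentError("intensity scalings must be positive")


@dataclass(frozen=True)
class ToyLandscape:
    """1-D free-energy landscape of Gaussian wells on the distance axis.

    U(x) = -Σ_i depth_i * exp(-(x - center_i)² / (2 width_i²))

    The position x plays the role of the inter-label (Cys-Cys) distance
    observable in Å; the conformation descriptor defaults to the scalar
    position itself.
    """

    well_centers: tuple[float, ...]
    well_depths: tuple[float, ...]
    well_widths: tuple[float, ...]
    diffusion_coefficient: float = 50.0  # Å²/ns
    thermal_energy: float = 1.0  # kT units

    def __post_init__(self) -> None:
        if len(self.well_centers) < 1:
            raise InvalidArgumentError("need at least one well")
        if not (
            len(self.well_centers) == len(self.well_depths) == len(self.well_widths)
        ):
            raise InvalidArgumentError("well arrays must have equal length")
        if not self.diffusion_coefficient > 0:
            raise InvalidArgumentError("diffusion coefficient must be positive")
        if not self.thermal_energy >= 0:
            raise InvalidArgumentError("thermal energy must be nonnegative")
        if np.any(np.asarray(self.well_widths) <= 0):
            raise InvalidArgumentError("well widths must be positive")

    def potential(self, x):
        x = np.asarray(x, float)
        u = np.zeros_like(x)
        for c, d, w in zip(self.well_centers, self.well_depths, self.well_widths):
            u -= d * np.exp(-((x - c) ** 2) / (2 * w**2))
        return u

    def force(self, x):
        x = np.asarray(x, float)
        f = np.zeros_like(x)
        for c, d, w in zip(self.well_centers, self.well_depths, self.well_widths):
            f -= d * (x - c) / w**2 * np.exp(-((x - c) ** 2) / (2 * w**2))
        return f

    def descriptor(self, x) -> np.ndarray:
        """Conformation descriptor per frame (default: the position)."""
        return np.atleast_2d(np.asarray(x, float)).T


def default_double_well() -> ToyLandscape:
    """Double well on the distance axis with minima near 40 Å and 60 Å,
    spanning the sampled 30-70 Å range of the all-atom campaigns.

    Well depths of 7 kT put spontaneous barrier crossings well beyond a
    single short trajectory, the regime adaptive seeding is designed for
    (MD trajectories are far shorter than the conformational exchange
    they sample).
    """
    return ToyLandscape(
        well_centers=(40.0, 60.0),
        well_depths=(7.0, 7.0),
        well_widths=(5.0, 5.0),
        diffusion_coefficient=50.0,
        thermal_energy=1.0,
    )


# --------------------------------------------------------------------------
# trace generators


@dataclass
class TraceSimulation:
    """Simulated TIRF traces plus their generative ground truth."""

    traces: list[IntensityTrace]
    state_paths: list[np.ndarray]
    bleach_frames: list[int | None]
    bleach_times: np.ndarray
    frame_time: float

    def __iter__(self):
        return iter(self.traces)


def _simulate_state_paths(
    kinetics: TwoStateKinetics,
    n_traces: int,
    n_frames: int,
    frame_time: float,
    rng: np.random.Generator,
) -> np.ndarray:
    p_hl = min(kinetics.k_high_to_low * frame_time, 1.0)
    p_lh = min(kinetics.k_low_to_high * frame_time, 1.0)
    p0_high = (
        kinetics.initial_state_prob_high
        if kinetics.initial_state_prob_high is not None
        else kinetics.stationary_prob_high()
    )
    paths = np.empty((n_traces, n_frames), dtype=np.int8)
    state = (rng.random(n_traces) < p0_high).astype(np.int8)
    u = rng.random((n_traces, n_frames))
    for t in range(n_frames):
        paths[:, t] = state
        switch_p = np.where(state == STATE_HIGH, p_hl, p_lh)
        state = np.where(u[:, t] < switch_p, 1 - state, state).astype(np.int8)
    return paths


def _check_trace_args(n_traces: int, duration: float, frame_time: float) -> int:
    if n_traces < 1:
        raise InvalidArgumentError("n_traces must be >= 1")
    if not (duration > 0 and frame_time > 0):
        raise InvalidArgumentError("duration and frame_time must be positive")
    if duration < frame_time:
        raise InvalidArgumentError("duration must be >= frame_time")
    return int(np.floor(duration / frame_time))


def simulate_traces(
    kinetics: TwoStateKinetics,
    emission: EmissionModel,
    n_traces: int,
    duration: float,
    frame_time: float = 0.1,
    seed: int = 0,
) -> TraceSimulation:
    """Simulate two-channel TIRF intensity traces with two-state switching.

    Photobleaching is a donor-absorbing event: the bleach time is
    exponential with ``emission.photobleach_rate`` and frames at or after
    it emit background only in both channels (the trace keeps its full
    length; ``bleach_frames`` marks the first bleached frame). Channel
    noise is additive Gaussian; intensities are floored at zero.
    """
    n_frames = _check_trace_args(n_traces, duration, frame_time)
    rng = np.random.default_rng(seed)
    paths = _simulate_state_paths(kinetics, n_traces, n_frames, frame_time, rng)

    if emission.photobleach_rate > 0:
        bleach_times = rng.exponential(1.0 / emission.photobleach_rate, n_traces)
    else:
        bleach_times = np.full(n_traces, np.inf)
    bleach_frames: list[int | None] = [
        int(np.ceil(bt / frame_time)) if bt < n_frames * frame_time else None
        for bt in bleach_times
    ]

    d_means = np.asarray(emission.mean_donor_per_state, float)
    a_means = np.asarray(emission.mean_acceptor_per_state, float)
    bg = emission.background_per_channel
    traces = []
    for i in range(n_traces):
        donor = d_means[paths[i]] + bg
        acceptor = a_means[paths[i]] + bg
        if bleach_frames[i] is not None:
            donor[bleach_frames[i] :] = bg
            acceptor[bleach_frames[i] :] = bg
        if emission.channel_noise_sd > 0:
            donor = donor + rng.normal(0, emission.channel_noise_sd, n_frames)
            acceptor = acceptor + rng.normal(0, emission.channel_noise_sd, n_frames)
            donor = np.maximum(donor, 0.0)
            acceptor = np.maximum(acceptor, 0.0)
        traces.append(
            IntensityTrace(donor, acceptor, frame_time, trace_id=f"trace{i:05d}")
        )
    return TraceSimulation(
        traces=traces,
        state_paths=[paths[i] for i in range(n_traces)],
        bleach_frames=bleach_frames,
        bleach_times=bleach_times,
        frame_time=frame_time,
    )


def simulate_efficiency_traces(
    kinetics: TwoStateKinetics | None,
    efficiency_means: tuple[float, ...],
    efficiency_sds: tuple[float, ...],
    n_traces: int,
    duration: float,
    frame_time: float = 0.1,
    total_intensity: float = 1000.0,
    seed: int = 0,
) -> TraceSimulation:
    """Simulate traces whose *per-frame efficiency* is Gaussian per state.

    E_t ~ N(mean[state], sd[state]) clipped to [0, 1]; the two channels
    are then acceptor = T*E_t, donor = T*(1-E_t) at constant total
    intensity T, so the efficiency noise is specified directly in FRET
    units. Pass ``kinetics=None`` for a single static state (the first
    entry of the means).
    """
    n_frames = _check_trace_args(n_traces, duration, frame_time)
    means = np.asarray(efficiency_means, float)
    sds = np.asarray(efficiency_sds, float)
    if means.shape != sds.shape:
        raise InvalidArgumentError("efficiency means/sds must match in length")
    if np.any(sds < 0):
        raise InvalidArgumentError("efficiency sds must be nonnegative")
    rng = np.random.default_rng(seed)
    if kinetics is None:
        paths = np.zeros((n_traces, n_frames), dtype=np.int8)
    else:
        paths = _simulate_state_paths(kinetics, n_traces, n_frames, frame_time, rng)

    traces = []
    for i in range(n_traces):
        e = rng.normal(means[paths[i]], sds[paths[i]])
        e = np.clip(e, 0.0, 1.0)
        traces.append(
            IntensityTrace(
                donor=total_intensity * (1.0 - e),
                acceptor=total_intensity * e,
                frame_time=frame_time,
                trace_id=f"trace{i:05d}",
            )
        )
    return TraceSimulation(
        traces=traces,
        state_paths=[paths[i] for i in range(n_traces)],
        bleach_frames=[None] * n_traces,
        bleach_times=np.full(n_traces, np.inf),
        frame_time=frame_time,
    )


# --------------------------------------------------------------------------
# bursts


@dataclass
class BurstSimulation:
    """Simulated confocal burst table plus generative ground truth."""

    bursts: pd.DataFrame  # burst_id, f_donor, f_acceptor, duration
    true_efficiency: np.ndarray
    true_state: np.ndarray


def simulate_bursts(
    model: BurstModel, n_bursts: int, seed: int = 0
) -> BurstSimulation:
    """Simulate photon bursts: exponential durations, Poisson photons."""
    if n_bursts < 1:
        raise InvalidArgumentError("n_bursts must be >= 1")
    rng = np.random.default_rng(seed)
    durations = rng.exponential(model.burst_duration_mean, n_bursts)
    # at least one acquisition bin per burst
    durations = np.maximum(
        np.ceil(durations / model.bin_time) * model.bin_time, model.bin_time
    )
    states = (rng.random(n_bursts) < model.state_prob_high).astype(int)
    d_rate = np.asarray(model.photon_rate_donor_per_state, float)[states]
    a_rate = np.asarray(model.photon_rate_acceptor_per_state, float)[states]
    f_donor = rng.poisson(d_rate * durations) + rng.poisson(
        model.background_rate_donor * durations
    )
    f_acceptor = rng.poisson(a_rate * durations) + rng.poisson(
        model.background_rate_acceptor * durations
    )
    bursts = pd.DataFrame(
        {
            "burst_id": np.arange(n_bursts),
            "f_donor": f_donor.astype(int),
            "f_acceptor": f_acceptor.astype(int),
            "duration": durations,
        }
    )
    return BurstSimulation(
        bursts=bursts,
        true_efficiency=model.efficiency_per_state()[states],
        true_state=states,
    )


# --------------------------------------------------------------------------
# titrations


def simulate_titration(truth: TitrationGroundTruth, seed: int = 0) -> pd.DataFrame:
    """Responses = 4PL(truth) + Gaussian noise, one row per replicate point.

    Returns a DataFrame with columns (concentration_M, replicate, response).
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(truth.concentrations, float)
    rows = []
    for r in range(truth.replicates):
        resp = four_pl(conc, truth.bottom, truth.top, truth.ec50, truth.hill)
        if truth.noise_sd > 0:
            resp = resp + rng.normal(0, truth.noise_sd, conc.size)
        rows.append(
            pd.DataFrame(
                {"concentration_M": conc, "replicate": r, "response": resp}
            )
        )
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# NMR peak lists


def simulate_peaklists(
    truth: NmrGroundTruth,
    seed: int = 0,
    shift_noise_sd: float = 0.0,
    intensity_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (reference, perturbed) HSQC peak lists.

    The perturbed list is base + perturbation with intensities scaled
    per residue; residues flagged missing appear in neither list.
    Optional Gaussian noise on shifts (ppm) and relative intensity.
    """
    rng = np.random.default_rng(seed)
    res = np.asarray(truth.residues, int)
    keep = ~np.isin(res, list(truth.missing_residues))
    res = res[keep]
    base_dh = np.asarray(truth.base_dh, float)[keep]
    base_dn = np.asarray(truth.base_dn, float)[keep]
    ddh = np.asarray(truth.delta_dh, float)[keep]
    ddn = np.asarray(truth.delta_dn, float)[keep]
    scale = np.asarray(truth.intensity_scaling, float)[keep]
    base_i = (
        np.asarray(truth.base_intensity, float)[keep]
        if truth.base_intensity is not None
        else np.full(res.size, 1.0)
    )

    def noisy(x, sd):
        sd = np.broadcast_to(np.asarray(sd, float), x.shape)
        return x + rng.normal(0, sd) if np.any(sd > 0) else x

    ref = pd.DataFrame(
        {
            "residue": res,
            "dH_ppm": noisy(base_dh, shift_noise_sd),
            "dN_ppm": noisy(base_dn, shift_noise_sd),
            "intensity": np.abs(noisy(base_i, intensity_noise_sd * base_i)),
        }
    )
    probe = pd.DataFrame(
        {
            "residue": res,
            "dH_ppm": noisy(base_dh + ddh, shift_noise_sd),
            "dN_ppm": noisy(base_dn + ddn, shift_noise_sd),
            "intensity": np.abs(noisy(base_i * scale, intensity_noise_sd * base_i)),
        }
    )
    return ref, probe


# --------------------------------------------------------------------------
# toy dynamics


@dataclass
class ToyTrajectory:
    """Frames of an overdamped-Langevin run on the toy landscape."""

    positions: np.ndarray  # Å, one per emitted frame
    descriptors: np.ndarray  # (n_frames, k)
    dt: float  # ns between emitted frames
    x0: float

    @property
    def D(self) -> np.ndarray:
        """Distance observable per frame (alias of positions)."""
        return self.positions

    def __len__(self) -> int:
        return len(self.positions)


def simulate_toy_dynamics(
    landscape: ToyLandscape,
    x0: float,
    n_steps: int,
    dt: float = 0.05,
    seed: int = 0,
    stride: int = 1,
) -> ToyTrajectory:
    """Euler-Maruyama integration of overdamped Langevin dynamics.

        x_{t+1} = x_t + (D0/kT) F(x_t) dt + sqrt(2 D0 dt) ξ_t

    with D0 the diffusion coefficient and F = -dU/dx. Frames are emitted
    every ``stride`` steps (the initial position is frame 0). At zero
    thermal energy the update reduces to deterministic gradient descent
    with mobility D0 (per unit energy).
    """
    if not dt > 0:
        raise InvalidArgumentError("dt must be positive")
    if n_steps < 1:
        raise InvalidArgumentError("n_steps must be >= 1")
    if stride < 1:
        raise InvalidArgumentError("stride must be >= 1")
    rng = np.random.default_rng(seed)
    d0 = landscape.diffusion_coefficient
    kt = landscape.thermal_energy
    mobility = d0 / kt if kt > 0 else d0
    noise_scale = np.sqrt(2 * d0 * dt) if kt > 0 else 0.0

    x = float(x0)
    out = [x]
    xi = rng.standard_normal(n_steps) if noise_scale > 0 else np.zeros(n_steps)
    for t in range(n_steps):
        x = x + mobility * float(landscape.force(x)) * dt + noise_scale * xi[t]
        if (t + 1) % stride == 0:
            out.append(x)
    positions = np.asarray(out)
    return ToyTrajectory(
        positions=positions,
        descriptors=landscape.descriptor(positions),
        dt=dt * stride,
        x0=float(x0),
    )
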