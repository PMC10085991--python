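"""Explore/exploit adaptive-sampling controller and trajectory descriptors.

Trajectories are run in epochs; each epoch's starting frames are drawn
from all previously observed frames with probability

    P(frame_i) ∝ W1 * (1 - |D_norm(target) - D_norm(frame_i)|)
               + W2 * (1 / P_obs(frame_i))

where D is a scalar distance observable (here the Cys-Cys inter-label
distance tracking the smFRET dyes), D_norm its min-max rescaling to
[0, 1] over the accumulated pool, and P_obs the normalized count of the
frame's conformation descriptor bin (so 1/P_obs up-weights rarely seen
conformations). With W1 = W2 the exploit and explore components are
balanced equally. The production campaign geometry is five epochs of ten
trajectories each.

Descriptor utilities for campaign analysis live here too: minimum
inter-set distance, RMSD versus the starting frame and versus the
trajectory average, centered running averages, and residue-pair contact
frequencies at a distance cutoff (default 3.5 Å).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, InvalidArgumentError

CONTACT_CUTOFF = 3.5  # Å
D_TARGET_HIGH_FRET = 44.0  # Å, Cys-Cys distance of the high-FRET state


@dataclass(frozen=True)
class SeedingParams:
    """Weights and discretization of the seeding heuristic."""

    w1: float = 1.0  # exploit weight
    w2: float = 1.0  # explore weight
    d_target: float = D_TARGET_HIGH_FRET
    descriptor_bin_width: float = 2.0
    n_seeds_per_epoch: int = 10
    distance_bounds: tuple[float, float] | None = None  # min-max normalization

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or (self.w1 == 0 and self.w2 == 0):
            raise InvalidArgumentError("weights must be >= 0 and not both zero")
        if not np.isfinite(self.d_target):
            raise InvalidArgumentError("d_target must be finite")
        if self.n_seeds_per_epoch < 1:
            raise InvalidArgumentError("n_seeds_per_epoch must be >= 1")
        if not self.descriptor_bin_width > 0:
            raise InvalidArgumentError("descriptor_bin_width must be positive")
        if self.distance_bounds is not None:
            lo, hi = self.distance_bounds
            if not hi > lo:
                raise InvalidArgumentError("distance bounds must satisfy hi > lo")


def _descriptor_matrix(frames: pd.DataFrame) -> np.ndarray:
    cols = [c for c in frames.columns if c.startswith("descriptor")]
    if not cols:
        raise InvalidArgumentError("frames need >= 1 'descriptor*' column")
    return frames[cols].to_numpy(float)


def p_obs(frames: pd.DataFrame, bin_width: float) -> np.ndarray:
    """Normalized observation count of each frame's conformation bin.

    Descriptor columns are discretized on a fixed grid of width
    ``bin_width``; P_obs = (count of the frame's bin) / (total frames).
    A frame always counts its own bin, so P_obs >= 1/total and 1/P_obs
    is finite.
    """
    desc = _descriptor_matrix(frames)
    bins = np.floor(desc / bin_width).astype(np.int64)
    _, inverse, counts = np.unique(
        bins, axis=0, return_inverse=True, return_counts=True
    )
    return counts[inverse] / len(frames)


def score_frames(frames: pd.DataFrame, params: SeedingParams) -> np.ndarray:
    """Seeding probability per frame (nonnegative, sums to 1).

    ``frames`` must carry a distance column ``D`` and one or more
    ``descriptor*`` columns. Distances (and the target) are min-max
    rescaled to [0, 1] over the pool (or over ``params.distance_bounds``)
    before the exploit term, keeping both terms commensurate.
    """
    if len(frames) == 0:
        raise EmptyInputError("no frames to score")
    d = frames["D"].to_numpy(float)
    if params.distance_bounds is not None:
        lo, hi = params.distance_bounds
    else:
        lo, hi = float(d.min()), float(d.max())
    span = hi - lo
    if span <= 0:
        d_norm = np.zeros_like(d)
        t_norm = 0.0
    else:
        d_norm = np.clip((d - lo) / span, 0.0, 1.0)
        t_norm = float(np.clip((params.d_target - lo) / span, 0.0, 1.0))

    exploit = 1.0 - np.abs(t_norm - d_norm)
    explore = 1.0 / p_obs(frames, params.descriptor_bin_width)
    raw = params.w1 * exploit + params.w2 * explore
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total <= 0:
        warnings.warn("all scores zero after clipping; falling back to uniform")
        return np.full(len(d), 1.0 / len(d))
    return raw / total


def select_seeds(probabilities, n_seeds: int, seed: int = 0) -> np.ndarray:
    """Sample ``n_seeds`` frame indices without replacement, proportional
    to probability; reproducible from ``seed``."""
    p = np.asarray(probabilities, float)
    if n_seeds < 1:
        raise InvalidArgumentError("n_seeds must be >= 1")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise InvalidArgumentError("probabilities must be a distribution")
    if n_seeds > np.count_nonzero(p):
        raise InvalidArgumentError(
            "n_seeds exceeds the number of frames with nonzero probability"
        )
    rng = np.random.default_rng(seed)
    return rng.choice(len(p), size=n_seeds, replace=False, p=p)


@dataclass
class CampaignResult:
    """All frames, per-epoch seeds, and scoring tables of a campaign."""

    frames: pd.DataFrame  # epoch, traj, frame, D, descriptor*
    seeds: list[pd.DataFrame]  # per epoch: the seed frames used
    probabilities: list[np.ndarray | None]  # per epoch: scores over the pool
    params: SeedingParams

    def enrichment(self, window: float = 5.0, d_target: float | None = None) -> float:
        """Fraction of all frames within ``window`` of the target distance."""
        t = self.params.d_target if d_target is None else d_target
        d = self.frames["D"].to_numpy(float)
        return float(np.mean(np.abs(d - t) <= window))


def run_campaign(
    engine,
    params: SeedingParams,
    epochs: int = 5,
    trajs_per_epoch: int = 10,
    steps_per_traj: int = 200,
    x0: float = 60.0,
    seed: int = 0,
    adaptive: bool = True,
) -> CampaignResult:
    """Run an adaptive-sampling campaign on a pluggable dynamics engine.

    ``engine(x0, n_steps, seed)`` must return an object with ``D`` (1-D
    array of the distance observable) and ``descriptors`` ((n, k) array);
    the toy Langevin integrator of :mod:`ctdyn.synthetic` satisfies this.

    Epoch 1 starts every trajectory from ``x0``; later epochs start from
    frames drawn by :func:`score_frames`/:func:`select_seeds` over the
    accumulated pool. With ``adaptive=False`` every epoch restarts from
    ``x0`` (the equal-budget naive control). Fully reproducible from
    (params, seed).
    """
    if epochs < 1 or trajs_per_epoch < 1:
        raise InvalidArgumentError("epochs and trajs_per_epoch must be >= 1")
    ss = np.random.SeedSequence(seed)
    traj_seeds = [
        int(s) % (2**31 - 1)
        for s in ss.generate_state(epochs * trajs_per_epoch + epochs)
    ]
    pool: list[pd.DataFrame] = []
    seeds_used: list[pd.DataFrame] = []
    probs: list[np.ndarray | None] = []
    k = 0
    for epoch in range(1, epochs + 1):
        if epoch == 1 or not adaptive:
            starts = np.full(trajs_per_epoch, float(x0))
            seed_table = pd.DataFrame(
                {"epoch": epoch, "start": starts, "source_index": -1}
            )
            probs.append(None)
        else:
            accumulated = pd.concat(pool, ignore_index=True)
            p = score_frames(accumulated, params)
            idx = select_seeds(
                p, params.n_seeds_per_epoch, seed=traj_seeds[-epoch]
            )
            chosen = accumulated.iloc[idx]
            # cycle the selected seeds over the epoch's trajectories
            starts = chosen["D"].to_numpy(float)[
                np.arange(trajs_per_epoch) % len(idx)
            ]
            seed_table = chosen.assign(epoch=epoch, source_index=idx)
            probs.append(p)
        seeds_used.append(seed_table)

        for traj in range(trajs_per_epoch):
            t = engine(starts[traj], steps_per_traj, traj_seeds[k])
            k += 1
            d = np.asarray(t.D, float)
            desc = np.asarray(t.descriptors, float)
            rec = pd.DataFrame(
                {
                    "epoch": epoch,
                    "traj": (epoch - 1) * trajs_per_epoch + traj,
                    "frame": np.arange(len(d)),
                    "D": d,
                }
            )
            for j in range(desc.shape[1]):
                rec[f"descriptor{j}"] = desc[:, j]
            pool.append(rec)

    return CampaignResult(
        frames=pd.concat(pool, ignore_index=True),
        seeds=seeds_used,
        probabilities=probs,
        params=params,
    )


# --------------------------------------------------------------------------
# trajectory descriptors


def min_distance(points_a: np.ndarray, points_b: np.ndarray):
    """Minimum pairwise distance between two labelled point sets.

    Accepts (n, 3) single-frame sets or (n_frames, n, 3) stacks (then a
    per-frame series is returned).
    """
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("point sets must be non-empty")
    if a.ndim == 2 and b.ndim == 2:
        return float(cdist(a, b).min())
    if a.ndim == 3 and b.ndim == 3:
        return np.array([float(cdist(fa, fb).min()) for fa, fb in zip(a, b)])
    raise InvalidArgumentError("point sets must both be (n,3) or (T,n,3)")


def rmsd_series(coords: np.ndarray, reference: np.ndarray | None = None):
    """RMSD of each frame against a reference structure.

    ``coords`` is (n_frames, n_atoms, 3); the reference defaults to the
    first frame. No superposition is applied (observables are assumed
    pre-aligned).
    """
    c = np.asarray(coords, float)
    if c.ndim != 3 or c.shape[0] < 1:
        raise InvalidArgumentError("coords must be (n_frames, n_atoms, 3)")
    ref = c[0] if reference is None else np.asarray(reference, float)
    dev = c - ref[None]
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=1))


def running_average(series, window: int):
    """Centered moving average; edges use the available part of the window."""
    x = np.asarray(series, float)
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    if window == 1 or x.size == 0:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


@dataclass
class TrajectoryDescriptors:
    """Per-frame geometric summaries of one trajectory."""

    min_distance: np.ndarray
    rmsd_vs_start: np.ndarray
    rmsd_vs_mean: np.ndarray
    smoothed: dict = field(default_factory=dict)


def trajectory_descriptors(
    coords: np.ndarray,
    set_a,
    set_b,
    window: int = 1,
) -> TrajectoryDescriptors:
    """Compute the standard campaign descriptors for one trajectory.

    Parameters
    ----------
    coords : (n_frames, n_atoms, 3) array
    set_a, set_b : atom index arrays for the two labelled groups whose
        minimum inter-set distance is tracked (e.g. the two Cys sites)
    window : frames in the centered running-average smoother
    """
    c = np.asarray(coords, float)
    if c.ndim != 3:
        raise InvalidArgumentError("coords must be (n_frames, n_atoms, 3)")
    a_idx = np.asarray(set_a, int)
    b_idx = np.asarray(set_b, int)
    md = min_distance(c[:, a_idx], c[:, b_idx])
    r_start = rmsd_series(c)
    r_mean = rmsd_series(c, reference=c.mean(axis=0))
    smoothed = {
        "min_distance": running_average(md, window),
        "rmsd_vs_start": running_average(r_start, window),
        "rmsd_vs_mean": running_average(r_mean, window),
    }
    return TrajectoryDescriptors(
        min_distance=md,
        rmsd_vs_start=r_start,
        rmsd_vs_mean=r_mean,
        smoothed=smoothed,
    )


def contact_frequency(
    points_a: np.ndarray, points_b: np.ndarray, cutoff: float = CONTACT_CUTOFF
) -> float:
    """Fraction of frames whose minimum inter-set distance is <= cutoff."""
    if not cutoff > 0:
        raise InvalidArgumentError("cutoff must be positive")
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    if a.ndim == 2:
        a = a[None]
    if b.ndim == 2:
        b = b[None]
    if a.shape[0] == 0:
        raise EmptyInputError("no frames")
    d = min_distance(a, b)
    return float(np.mean(np.atleast_1d(d) <= cutoff))


def contact_frequencies(pairs: dict, cutoff: float = CONTACT_CUTOFF) -> pd.Series:
    """Contact frequency for many residue pairs.

    ``pairs`` maps a pair label to (points_a, points_b) per-frame stacks.
    """
    return pd.Series(
        {name: contact_frequency(a, b, cutoff) for name, (a, b) in pairs.items()},
        name="contact_frequency",
    )
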