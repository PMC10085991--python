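"""Raw smFRET observables: intensity traces, per-frame efficiencies,
normalized histograms, and confocal photon bursts.

The per-frame FRET efficiency of a surface-immobilized molecule is

    E_t = I_A(t) / (I_A(t) + I_D(t))

with I_A and I_D the acceptor and donor intensities. Efficiencies are
pooled over every usable (pre-photobleach) frame of every trace into a
fixed 100-bin histogram on [0, 1] (bin width 0.01) whose heights are
normalized by the total number of frames. For free-diffusion (confocal)
data, the apparent efficiency of a photon burst is computed on
background-corrected counts,

    E = (f_A - b_A) / ((f_A - b_A) + (f_D - b_D)),

and only bursts with at least ``threshold`` raw photons (default 40,
summed over both channels) enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, EmptyResultError, InvalidArgumentError

N_BINS = 100
BIN_EDGES = np.linspace(0.0, 1.0, N_BINS + 1)
BIN_CENTERS = 0.5 * (BIN_EDGES[:-1] + BIN_EDGES[1:])
BURST_PHOTON_THRESHOLD = 40


@dataclass
class IntensityTrace:
    """Two-channel intensity time series for one immobilized molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_time: float
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise InvalidArgumentError("donor/acceptor must be 1-D arrays")
        if len(self.donor) != len(self.acceptor) or len(self.donor) < 1:
            raise InvalidArgumentError(
                "donor and acceptor must have equal length >= 1"
            )
        if not self.frame_time > 0:
            raise InvalidArgumentError("frame_time must be positive")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class FretTrace:
    """Per-frame FRET efficiency with invalid frames masked as NaN.

    ``efficiency`` has one entry per usable (pre-bleach) frame; frames with
    non-positive total intensity are NaN and excluded downstream.
    """

    efficiency: np.ndarray
    frame_time: float
    usable_length: int
    trace_id: str = "trace"

    @property
    def values(self) -> np.ndarray:
        """Valid efficiencies only (NaN frames dropped)."""
        e = self.efficiency
        return e[np.isfinite(e)]


@dataclass
class FretHistogram:
    """Normalized 100-bin FRET-efficiency histogram on [0, 1]."""

    heights: np.ndarray
    n_frames: int
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != (N_BINS,):
            raise InvalidArgumentError(f"expected {N_BINS} bins")
        if np.any(self.heights < 0):
            raise InvalidArgumentError("heights must be nonnegative")
        if abs(self.heights.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("heights must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "height": self.heights,
            }
        )


def compute_fret(
    trace: IntensityTrace, bleach_frame: int | None = None
) -> FretTrace:
    """Convert an intensity trace to per-frame FRET efficiency.

    E_t = acceptor / (acceptor + donor), clamped to [0, 1]. Frames at or
    after ``bleach_frame`` are dropped; frames with non-positive total
    intensity are marked NaN (invalid) and excluded from histograms.

    Raises
    ------
    EmptyResultError
        If no usable frame has positive total intensity.
    """
    usable = len(trace) if bleach_frame is None else int(bleach_frame)
    usable = max(0, min(usable, len(trace)))
    donor = trace.donor[:usable]
    acceptor = trace.acceptor[:usable]
    total = donor + acceptor
    valid = total > 0
    if not valid.any():
        raise EmptyResultError(
            f"trace {trace.trace_id!r}: no frame with positive total intensity"
        )
    eff = np.full(usable, np.nan)
    eff[valid] = np.clip(acceptor[valid] / total[valid], 0.0, 1.0)
    return FretTrace(
        efficiency=eff,
        frame_time=trace.frame_time,
        usable_length=usable,
        trace_id=trace.trace_id,
    )


def detect_photobleach(
    trace: IntensityTrace,
    drop_fraction: float = 0.5,
    min_post_frames: int = 5,
    reference_level: float | None = None,
) -> int | None:
    """Locate a single photobleaching change-point on total intensity.

    The candidate split minimizing the within-segment sum of squares is
    accepted as a bleach only if the post-drop mean stays below
    ``drop_fraction`` of the pre-drop mean over at least
    ``min_post_frames`` frames. Returns the first post-bleach frame index,
    or None when no persistent drop exists.

    If ``reference_level`` is given (the expected unbleached intensity)
    and the trace is already below ``drop_fraction * reference_level``
    from its first frame, frame 0 is returned: the molecule bleached
    before acquisition and the trace is unusable.
    """
    if len(trace) < 4:
        raise InvalidArgumentError("photobleach detection needs >= 4 frames")
    total = trace.total
    if reference_level is not None and np.mean(total) < drop_fraction * reference_level:
        return 0

    n = len(total)
    cum = np.concatenate([[0.0], np.cumsum(total)])
    cum2 = np.concatenate([[0.0], np.cumsum(total**2)])

    def sse(lo: int, hi: int) -> float:  # [lo, hi)
        m = hi - lo
        s = cum[hi] - cum[lo]
        s2 = cum2[hi] - cum2[lo]
        return s2 - s * s / m

    best_split, best_cost = None, sse(0, n)
    for t in range(1, n):
        cost = sse(0, t) + sse(t, n)
        if cost < best_cost - 1e-12:
            best_cost, best_split = cost, t
    if best_split is None:
        return None
    pre_mean = total[:best_split].mean()
    post = total[best_split:]
    if len(post) < min_post_frames:
        return None
    if pre_mean <= 0 or np.mean(post) >= drop_fraction * pre_mean:
        return None
    if np.any(post >= pre_mean * (1 - (1 - drop_fraction) / 2)):
        # drop is not persistent: some post frames recover
        return None
    return best_split


def build_histogram(fret_traces) -> FretHistogram:
    """Pool valid frames of one or many FretTraces into the 0.01-bin
    normalized histogram.

    Bins are half-open [lo, hi) with the final bin closed at 1.0; heights
    are frame counts divided by the total number of valid frames.
    """
    if isinstance(fret_traces, FretTrace):
        fret_traces = [fret_traces]
    values = []
    for ft in fret_traces:
        arr = ft.values if isinstance(ft, FretTrace) else np.asarray(ft, float)
        arr = arr[np.isfinite(arr)]
        values.append(arr)
    pooled = np.concatenate(values) if values else np.empty(0)
    if pooled.size == 0:
        raise EmptyInputError("no usable frames to histogram")
    counts, _ = np.histogram(pooled, bins=BIN_EDGES)
    return FretHistogram(heights=counts / pooled.size, n_frames=int(pooled.size))


def burst_efficiencies(
    bursts: pd.DataFrame,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    threshold: int = BURST_PHOTON_THRESHOLD,
) -> pd.DataFrame:
    """Apparent FRET efficiency per photon burst with inclusion mask.

    Bursts whose raw photon sum f_donor + f_acceptor falls below
    ``threshold`` are excluded. Efficiency is computed on
    background-corrected counts; if exactly one corrected channel is
    negative the efficiency is clamped to the nearest boundary, and
    bursts with both corrected channels <= 0 are excluded.

    Parameters
    ----------
    bursts : DataFrame with integer columns ``f_donor`` and ``f_acceptor``
        (per-burst photon counts). Optional columns ``b_donor`` /
        ``b_acceptor`` override the scalar backgrounds.
    """
    fd = np.asarray(bursts["f_donor"], dtype=float)
    fa = np.asarray(bursts["f_acceptor"], dtype=float)
    if np.any(fd < 0) or np.any(fa < 0):
        raise InvalidArgumentError("raw photon counts must be nonnegative")
    bd = np.asarray(bursts.get("b_donor", background_donor), dtype=float)
    ba = np.asarray(bursts.get("b_acceptor", background_acceptor), dtype=float)

    cd = fd - bd
    ca = fa - ba
    total_raw = fd + fa
    included = total_raw >= threshold

    eff = np.full(len(fd), np.nan)
    both_dead = (cd <= 0) & (ca <= 0)
    included &= ~both_dead
    ok = ~both_dead
    with np.errstate(invalid="ignore", divide="ignore"):
        eff[ok] = ca[ok] / (ca[ok] + cd[ok])
    # one negative corrected channel: clamp to the nearest boundary
    eff[ok & (ca < 0)] = 0.0
    eff[ok & (cd < 0)] = 1.0
    eff = np.clip(eff, 0.0, 1.0)

    out = bursts.copy()
    out["efficiency"] = eff
    out["included"] = included
    return out
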