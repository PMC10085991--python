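"""FRET-state identification, dwell-time kinetics, and occupancy analysis.

Two complementary routes quantify the conformational equilibrium seen in
smFRET data:

* a hidden Markov model with Gaussian emissions on the per-frame
  efficiency (Baum-Welch fit, Viterbi idealization) yields state paths
  and dwell times;
* a single- or double-Gaussian fit to the normalized 0.01-bin histogram
  yields state centers, widths (FWHM = 2*sqrt(2 ln 2)*sigma) and
  occupancies, defined as mixture *area* fractions.

When fitting weakly populated low-FRET states the low component's center
can be held fixed (the TIRF analysis pins it at E = 0.38 at low
G-protein concentrations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .errors import (
    DegenerateFitWarning,
    EmptyInputError,
    FitNotConvergedWarning,
    InvalidArgumentError,
)
from .fret import BIN_CENTERS, FretHistogram, FretTrace

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.35482...


def _as_sequences(fret_traces) -> list[np.ndarray]:
    out = []
    for ft in fret_traces:
        arr = ft.values if isinstance(ft, FretTrace) else np.asarray(ft, float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            out.append(arr)
    return out


class FretHmm(BaseEstimator):
    """Gaussian-emission HMM over per-frame FRET efficiencies.

    Baum-Welch maximum likelihood with k-means initialization and
    seed-controlled restarts (best likelihood kept); states are relabeled
    in ascending order of emission mean, so state 0 is the lowest-FRET
    state. ``predict`` returns the Viterbi path per trace.

    Attributes (after fit)
    ----------------------
    means_, sds_ : per-state emission parameters, ascending means
    transmat_ : per-frame transition probabilities (row-stochastic)
    startprob_ : initial distribution
    log_likelihood_ : best achieved log likelihood
    converged_ : bool, Baum-Welch met its tolerance
    degenerate_ : bool, two emission means closer than ``min_separation``
    """

    def __init__(
        self,
        n_states: int = 2,
        n_restarts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-6,
        min_separation: float = 0.05,
        resolvability_sigma: float = 2.0,
        random_state: int | None = 0,
    ):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.min_separation = min_separation
        self.resolvability_sigma = resolvability_sigma
        self.random_state = random_state

    def fit(self, fret_traces, y=None):
        if self.n_states < 2:
            raise InvalidArgumentError("n_states must be >= 2")
        seqs = _as_sequences(fret_traces)
        if not seqs:
            raise EmptyInputError("no usable traces")
        X = np.concatenate(seqs).reshape(-1, 1)
        lengths = [len(s) for s in seqs]

        best = None
        rng = np.random.default_rng(self.random_state)
        for r in range(self.n_restarts):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                km = KMeans(
                    n_clusters=self.n_states, n_init=3, random_state=sub_seed
                ).fit(X)
            model = GaussianHMM(
                n_components=self.n_states,
                covariance_type="diag",
                n_iter=self.max_iter,
                tol=self.tol,
                init_params="",  # we initialize everything ourselves
                params="stmc",
                random_state=sub_seed,
            )
            model.startprob_ = np.full(self.n_states, 1.0 / self.n_states)
            model.transmat_ = np.full(
                (self.n_states, self.n_states), 0.05 / max(self.n_states - 1, 1)
            )
            np.fill_diagonal(model.transmat_, 0.95)
            model.means_ = km.cluster_centers_.copy()
            var = max(float(np.var(X)) / self.n_states, 1e-6)
            model.covars_ = np.full((self.n_states, 1), var)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, lengths)
            score = model.monitor_.history[-1]
            if best is None or score > best[0]:
                best = (score, model)

        score, model = best
        order = np.argsort(model.means_.ravel())
        self.means_ = model.means_.ravel()[order]
        self.sds_ = np.sqrt(model.covars_.ravel()[order])
        self.transmat_ = model.transmat_[np.ix_(order, order)]
        self.startprob_ = model.startprob_[order]
        self.log_likelihood_ = float(score)
        self.converged_ = bool(model.monitor_.converged)
        self.loglik_history_ = np.asarray(model.monitor_.history, float)
        self._order = order
        self._model = model
        if not self.converged_:
            warnings.warn(
                "Baum-Welch did not converge within max_iter",
                FitNotConvergedWarning,
                stacklevel=2,
            )
        gaps = np.diff(self.means_)
        # resolvable only if neighbouring means differ by more than both an
        # absolute floor and a multiple of the pooled emission width
        pooled_sd = 0.5 * (self.sds_[:-1] + self.sds_[1:])
        thresh = np.maximum(self.min_separation, self.resolvability_sigma * pooled_sd)
        self.degenerate_ = bool(np.any(gaps < thresh))
        if self.degenerate_:
            warnings.warn(
                f"emission means separated by less than {self.min_separation}: "
                "states may be merged/unresolvable",
                DegenerateFitWarning,
                stacklevel=2,
            )
        return self

    def predict(self, fret_traces) -> list[np.ndarray]:
        """Viterbi state path per trace (labels follow ascending means)."""
        relabel = np.empty_like(self._order)
        relabel[self._order] = np.arange(len(self._order))
        paths = []
        for seq in _as_sequences(fret_traces):
            raw = self._model.predict(seq.reshape(-1, 1))
            paths.append(relabel[raw])
        return paths


def fit_hmm(
    fret_traces, n_states: int = 2, seed: int | None = 0, **kwargs
) -> tuple[FretHmm, list[np.ndarray]]:
    """Fit a FretHmm and return (model, Viterbi idealizations)."""
    est = FretHmm(n_states=n_states, random_state=seed, **kwargs).fit(fret_traces)
    return est, est.predict(fret_traces)


# --------------------------------------------------------------------------
# dwell times


@dataclass
class DwellSet:
    """State-labelled dwell durations with boundary-censoring flags."""

    dwells: pd.DataFrame  # trace, state, n_frames, duration_s, censored
    frame_time: float

    def mean_dwell(self, state: int) -> float:
        """Mean dwell (s) of uncensored dwells in ``state``."""
        d = self.dwells
        sel = d[(d["state"] == state) & (~d["censored"])]
        return float(sel["duration_s"].mean()) if len(sel) else np.nan

    def uncensored(self) -> pd.DataFrame:
        return self.dwells[~self.dwells["censored"]]


def extract_dwells(idealizations, frame_time: float) -> DwellSet:
    """Convert state paths into dwell records.

    Maximal constant runs become dwells of duration n_frames*frame_time;
    the first and last run of every trace are flagged censored (their
    true length is truncated by the observation window) and excluded
    from mean dwell times.
    """
    if isinstance(idealizations, np.ndarray) and idealizations.ndim == 1:
        idealizations = [idealizations]
    rows = []
    any_frames = False
    for i, path in enumerate(idealizations):
        path = np.asarray(path)
        if path.size == 0:
            continue
        any_frames = True
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [path.size]])
        n_runs = len(starts)
        for j, (s, e) in enumerate(zip(starts, ends)):
            rows.append(
                {
                    "trace": i,
                    "state": int(path[s]),
                    "n_frames": int(e - s),
                    "duration_s": (e - s) * frame_time,
                    "censored": j == 0 or j == n_runs - 1,
                }
            )
    if not any_frames:
        raise EmptyInputError("no frames in any idealization")
    return DwellSet(dwells=pd.DataFrame(rows), frame_time=frame_time)


# --------------------------------------------------------------------------
# Gaussian occupancy fits


@dataclass
class DoubleGaussianFit:
    """Mixture-of-Gaussians fit to a FRET histogram (1 or 2 components).

    ``occupancies`` are area fractions (probability masses), summing to 1.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    occupancies: np.ndarray
    fwhm: np.ndarray
    converged: bool
    degenerate: bool

    @property
    def low(self) -> int:
        return int(np.argmin(self.centers))

    @property
    def high(self) -> int:
        return int(np.argmax(self.centers))


class GaussianHistogramFit(BaseEstimator):
    """Weighted nonlinear least-squares Gaussian-mixture fit on a
    normalized 100-bin FRET histogram.

    The model is height(x) = sum_i a_i * N(x; c_i, s_i) * 0.01 evaluated
    at bin centers; occupancies are the normalized areas a_i / sum a.
    Residuals carry Poisson-motivated weights 1/sqrt(max(h, floor)) with
    floor = 1/n_frames, which stabilizes empty bins.

    Parameters
    ----------
    n_components : 1 or 2
    fix_low_center : float or None
        Hold the low component's center exactly at this value.
    degenerate_weight : float
        A component with occupancy below this (or centers closer than
        ``min_separation``) flags the fit near-degenerate.
    """

    def __init__(
        self,
        n_components: int = 2,
        fix_low_center: float | None = None,
        min_separation: float = 0.05,
        degenerate_weight: float = 0.05,
    ):
        self.n_components = n_components
        self.fix_low_center = fix_low_center
        self.min_separation = min_separation
        self.degenerate_weight = degenerate_weight

    def fit(self, hist, y=None):
        if isinstance(hist, FretHistogram):
            h = hist.heights
            n_frames = hist.n_frames
        else:
            h = np.asarray(hist, float)
            n_frames = None
        if h.shape != BIN_CENTERS.shape:
            raise InvalidArgumentError("expected a 100-bin histogram")
        x = BIN_CENTERS
        binw = x[1] - x[0]
        floor = 1.0 / n_frames if n_frames else 1e-4
        wts = 1.0 / np.sqrt(np.maximum(h, floor))
        k = self.n_components
        if k not in (1, 2):
            raise InvalidArgumentError("n_components must be 1 or 2")

        c0 = self._init_centers(x, h, k)
        s0 = np.full(k, 0.06)
        a0 = np.full(k, 1.0 / k)

        fixed = self.fix_low_center
        # free parameter vector: [centers (maybe minus fixed low), sigmas, amps]
        def unpack(p):
            if fixed is None:
                c = p[:k]
                rest = p[k:]
            else:
                c = np.concatenate([[fixed], p[: k - 1]])
                rest = p[k - 1 :]
            s = rest[:k]
            a = rest[k:]
            return c, s, a

        def model(c, s, a):
            out = np.zeros_like(x)
            for ci, si, ai in zip(c, s, a):
                out = out + ai * binw * np.exp(
                    -((x - ci) ** 2) / (2 * si**2)
                ) / (si * np.sqrt(2 * np.pi))
            return out

        def resid(p):
            c, s, a = unpack(p)
            return (model(c, s, a) - h) * wts

        if fixed is None:
            p0 = np.concatenate([c0, s0, a0])
            lo = np.concatenate([np.zeros(k), np.full(k, 1e-3), np.zeros(k)])
            hi = np.concatenate([np.ones(k), np.full(k, 0.5), np.full(k, 10.0)])
        else:
            p0 = np.concatenate([c0[1:], s0, a0])
            lo = np.concatenate([np.zeros(k - 1), np.full(k, 1e-3), np.zeros(k)])
            hi = np.concatenate([np.ones(k - 1), np.full(k, 0.5), np.full(k, 10.0)])

        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        c, s, a = unpack(sol.x)
        if a.sum() <= 0:
            raise InvalidArgumentError("fit collapsed: zero total area")
        # order components by center, low first (the fixed center stays put
        # by construction: it is the lowest by design when used as intended)
        order = np.argsort(c)
        self.centers_ = np.asarray(c)[order]
        self.sigmas_ = np.asarray(s)[order]
        amps = np.asarray(a)[order]
        self.weights_ = amps / amps.sum()
        self.occupancies_ = self.weights_.copy()
        self.fwhm_ = FWHM_FACTOR * self.sigmas_
        self.converged_ = bool(sol.success)
        self.degenerate_ = bool(
            (k == 2)
            and (
                np.min(self.weights_) < self.degenerate_weight
                or np.diff(self.centers_)[0] < self.min_separation
            )
        )
        if not self.converged_:
            warnings.warn(
                "Gaussian histogram fit did not converge",
                FitNotConvergedWarning,
                stacklevel=2,
            )
        if self.degenerate_:
            warnings.warn(
                "second component is unresolved or nearly empty",
                DegenerateFitWarning,
                stacklevel=2,
            )
        return self

    @staticmethod
    def _init_centers(x, h, k):
        if k == 1:
            return np.array([x[np.argmax(h)]])
        # seed one center per half, biased toward local maxima
        mid = len(x) // 2
        lo = x[:mid][np.argmax(h[:mid])] if h[:mid].max() > 0 else 0.3
        hi = x[mid:][np.argmax(h[mid:])] if h[mid:].max() > 0 else 0.7
        return np.array([lo, hi])

    def to_result(self) -> DoubleGaussianFit:
        return DoubleGaussianFit(
            centers=self.centers_,
            sigmas=self.sigmas_,
            weights=self.weights_,
            occupancies=self.occupancies_,
            fwhm=self.fwhm_,
            converged=self.converged_,
            degenerate=self.degenerate_,
        )


def fit_double_gaussian(
    hist, fix_low_center: float | None = None
) -> DoubleGaussianFit:
    """Two-Gaussian occupancy fit to a 0.01-bin FRET histogram."""
    est = GaussianHistogramFit(n_components=2, fix_low_center=fix_low_center)
    return est.fit(hist).to_result()


def fit_single_gaussian(hist) -> DoubleGaussianFit:
    """One-Gaussian fit (center, sigma, FWHM) to a FRET histogram."""
    return GaussianHistogramFit(n_components=1).fit(hist).to_result()


def occupancy_curve(
    histograms,
    fix_low_center: float | None = None,
    split: float = 0.55,
) -> pd.DataFrame:
    """Per-condition low/high occupancies from double-Gaussian fits.

    ``histograms`` maps condition labels (e.g. concentrations) to
    FretHistograms. Components are classified low/high by their fitted
    center relative to ``split`` (between the ~0.4 low-FRET and ~0.7
    high-FRET populations), so a condition whose mass sits entirely in
    one population reports occupancy (1, 0) even when the two fitted
    components share that peak. Failed fits are marked per condition,
    not raised.
    """
    rows = []
    for cond, hist in (
        histograms.items() if isinstance(histograms, dict) else histograms
    ):
        row = {"condition": cond}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_double_gaussian(hist, fix_low_center=fix_low_center)
            is_low = fit.centers < split
            occ_low = float(fit.occupancies[is_low].sum())

            def side_center(mask):
                if not mask.any():
                    return np.nan
                w = fit.occupancies[mask]
                return float(np.average(fit.centers[mask], weights=w)) if w.sum() > 0 else np.nan

            row.update(
                occ_low=occ_low,
                occ_high=1.0 - occ_low,
                center_low=side_center(is_low),
                center_high=side_center(~is_low),
                converged=fit.converged,
                degenerate=fit.degenerate,
            )
        except Exception as exc:  # propagate fit failures as flags
            row.update(
                occ_low=np.nan,
                occ_high=np.nan,
                center_low=np.nan,
                center_high=np.nan,
                converged=False,
                degenerate=True,
                error=str(exc),
            )
        rows.append(row)
    if not rows:
        raise EmptyInputError("no histograms given")
    return pd.DataFrame(rows)
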