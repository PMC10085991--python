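"""Four-parameter logistic (4PL) dose-response fitting and the cell-assay
normalization arithmetic (fold change, expression-normalized slope,
ΔpEC50 and relative Emax).

The response model is

    R(c) = bottom + (top - bottom) / (1 + (EC50 / c)^hill)

fitted by bounded trust-region least squares on the log10-concentration
axis. pEC50 = -log10(EC50 in molar). Replicates are fitted jointly
(pooled), preserving the error structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InvalidArgumentError, NoSignalError

HILL_BOUNDS = (0.3, 5.0)


def four_pl(c, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the four-parameter logistic at concentrations ``c``."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with standard errors."""

    bottom: float
    top: float
    ec50: float
    hill: float
    pec50: float
    se: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, c):
        return four_pl(c, self.bottom, self.top, self.ec50, self.hill)


class FourPLRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the four-parameter logistic.

    Parameters
    ----------
    hill_bounds : (lo, hi)
        Bounds on the free Hill slope.
    fixed_hill : float or None
        When given, the Hill slope is held at this value.
    flat_tol : float
        Relative response variance below which the data are declared
        signal-free and ``NoSignalError`` is raised.

    Attributes (after fit)
    ----------------------
    bottom_, top_, ec50_, hill_, pec50_ : fitted parameters
    se_ : dict of parameter standard errors from the Jacobian
    converged_ : bool
    """

    def __init__(
        self,
        hill_bounds: tuple[float, float] = HILL_BOUNDS,
        fixed_hill: float | None = None,
        flat_tol: float = 1e-12,
    ):
        self.hill_bounds = hill_bounds
        self.fixed_hill = fixed_hill
        self.flat_tol = flat_tol

    def fit(self, X, y):
        """Fit to concentrations X (mol/L, shape (n,) or (n, 1)) and
        responses y. Replicates are simply additional rows."""
        c = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != y.shape:
            raise InvalidArgumentError("concentrations and responses must align")
        mask = np.isfinite(c) & np.isfinite(y) & (c > 0)
        c, y = c[mask], y[mask]
        if np.unique(c).size < 4:
            raise InvalidArgumentError("need >= 4 distinct concentrations")
        scale = max(np.ptp(y), abs(np.mean(y)), 1.0)
        if np.var(y) <= self.flat_tol * scale**2:
            raise NoSignalError("responses are flat: no concentration dependence")

        logc = np.log10(c)
        order = np.argsort(logc)
        y_lo = float(np.mean(y[order[: max(1, order.size // 6)]]))
        y_hi = float(np.mean(y[order[-max(1, order.size // 6) :]]))
        # initial EC50: concentration whose mean response crosses half-max
        half = 0.5 * (y_lo + y_hi)
        crossing = np.interp(
            half,
            np.sort([y_lo, y_hi]),
            [logc.min(), logc.max()] if y_hi >= y_lo else [logc.max(), logc.min()],
        )
        log_ec50_0 = float(np.clip(crossing, logc.min(), logc.max()))

        fixed_hill = self.fixed_hill
        h_lo, h_hi = self.hill_bounds

        def unpack(p):
            if fixed_hill is None:
                b, t, le, h = p
            else:
                b, t, le = p
                h = fixed_hill
            return b, t, 10.0**le, h

        def resid(p):
            b, t, e, h = unpack(p)
            return four_pl(c, b, t, e, h) - y

        pad = 1.0  # allow EC50 one decade beyond the measured grid
        if fixed_hill is None:
            p0 = [y_lo, y_hi, log_ec50_0, 1.0]
            lower = [-np.inf, -np.inf, logc.min() - pad, h_lo]
            upper = [np.inf, np.inf, logc.max() + pad, h_hi]
        else:
            p0 = [y_lo, y_hi, log_ec50_0]
            lower = [-np.inf, -np.inf, logc.min() - pad]
            upper = [np.inf, np.inf, logc.max() + pad]

        sol = least_squares(resid, p0, bounds=(lower, upper), method="trf")
        b, t, e, h = unpack(sol.x)
        self.bottom_, self.top_, self.ec50_, self.hill_ = b, t, e, h
        self.pec50_ = -np.log10(e)
        self.converged_ = bool(sol.success)
        self.se_ = self._standard_errors(sol, fixed_hill)
        self.n_obs_ = int(c.size)
        return self

    @staticmethod
    def _standard_errors(sol, fixed_hill):
        names = (
            ["bottom", "top", "log10_ec50", "hill"]
            if fixed_hill is None
            else ["bottom", "top", "log10_ec50"]
        )
        m, n = sol.jac.shape
        dof = max(m - n, 1)
        try:
            cov = (
                np.linalg.pinv(sol.jac.T @ sol.jac)
                * 2
                * sol.cost
                / dof
            )
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(n, np.nan)
        return dict(zip(names, se))

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return four_pl(c, self.bottom_, self.top_, self.ec50_, self.hill_)


def fit_4pl(series, fixed_hill: float | None = None) -> FourPLFit:
    """Fit a 4PL to a titration series.

    ``series`` is either a DataFrame with columns ``concentration_M`` and
    ``response`` (replicates pooled), or a (concentrations, responses)
    tuple of arrays.
    """
    if isinstance(series, pd.DataFrame):
        c = series["concentration_M"].to_numpy()
        y = series["response"].to_numpy()
    else:
        c, y = series
    est = FourPLRegressor(fixed_hill=fixed_hill).fit(c, y)
    return FourPLFit(
        bottom=est.bottom_,
        top=est.top_,
        ec50=est.ec50_,
        hill=est.hill_,
        pec50=est.pec50_,
        se=est.se_,
        converged=est.converged_,
    )


def normalize_foldchange(luminescence, baseline_window, response_window) -> float:
    """Fold change of a luminescence timecourse.

    mean(response window) / mean(baseline window), with windows given as
    index arrays, boolean masks or slices into ``luminescence``.
    """
    lum = np.asarray(luminescence, dtype=float)
    base = lum[baseline_window]
    resp = lum[response_window]
    if base.size == 0 or resp.size == 0:
        raise InvalidArgumentError("both windows must be non-empty")
    denom = float(np.mean(base))
    if denom == 0:
        raise ZeroDivisionError("baseline mean is zero")
    return float(np.mean(resp)) / denom


def expression_slope(
    expression, response, reference_slope: float | None = None
) -> tuple[float, float | None]:
    """Least-squares slope of response vs surface expression.

    Returns (slope, percent_wt) where percent_wt = 100 * slope /
    reference_slope (None when no reference is given). Used for the
    expression-normalized cAMP level of constitutive-signaling assays.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise InvalidArgumentError("need >= 2 (expression, response) pairs")
    slope = float(np.polyfit(x, y, 1)[0])
    percent = 100.0 * slope / reference_slope if reference_slope else None
    return slope, percent


def compare_fits(test: FourPLFit, reference: FourPLFit) -> tuple[float, float]:
    """(ΔpEC50, relative Emax) of a test fit against a reference fit.

    ΔpEC50 = pEC50_test - pEC50_ref; relative Emax = span_test/span_ref.
    """
    if abs(reference.span) < 1e-12:
        raise ZeroDivisionError("reference fit has ~zero span")
    return test.pec50 - reference.pec50, test.span / reference.span
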