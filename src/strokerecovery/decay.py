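"""One-phase exponential decay fits for recovery-score curves.

The recovery score of a group of animals is modelled as a one-phase
exponential approach to a plateau,

    y(t) = plateau + (y0 - plateau) * exp(-k * (t - 3)),

with the time origin at day 3 post-stroke so that ``y0`` is the day-3
intercept (0% by construction of the score).  Fits are bounded least squares
(``k >= 0``) with a multi-start over log-spaced rate constants.  Whether one
shared curve describes several groups is tested with the extra
sum-of-squares F test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitConvergenceError

__all__ = [
    "DecayFitResult",
    "FTestResult",
    "OnePhaseDecay",
    "fit_one_phase_decay",
    "extra_ss_f_test",
]


@dataclass(frozen=True)
class DecayFitResult:
    """Parameters and goodness of fit of a one-phase decay."""

    y0: float
    plateau: float
    k: float
    rss: float
    df: int
    n: int

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.k * (t - 3.0))


class OnePhaseDecay(BaseEstimator, RegressorMixin):
    """Least-squares one-phase-decay regressor.

    Parameters
    ----------
    t0 : float
        Time origin; ``y0`` is the fitted value at ``t = t0`` (default day 3).
    k_max : float
        Upper bound on the rate constant per day.
    n_starts : int
        Multi-start grid size; initial rate constants are log-spaced over
        ``[1e-3, 1]`` per day.

    Attributes
    ----------
    y0_, plateau_, k_ : float
        Fitted parameters (``k_ >= 0``).
    rss_ : float
        Residual sum of squares.
    df_ : int
        Residual degrees of freedom, ``n - 3`` for a free fit.
    n_ : int
        Number of points fitted.
    """

    def __init__(self, t0: float = 3.0, k_max: float = 10.0, n_starts: int = 7):
        self.t0 = t0
        self.k_max = k_max
        self.n_starts = n_starts

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        n = t.size
        if n < 4:
            raise ValueError(f"need at least 4 points for a 3-parameter fit, got {n}")
        if np.any(t < self.t0):
            raise ValueError(f"all days must be >= t0 ({self.t0})")

        self.n_ = n
        self.df_ = n - 3

        if np.ptp(y) == 0.0:  # degenerate flat series: exact fit, k unidentified
            self.y0_ = self.plateau_ = float(y[0])
            self.k_ = 0.0
            self.rss_ = 0.0
            return self

        dt = t - self.t0

        def resid(theta):
            y0, plateau, k = theta
            return plateau + (y0 - plateau) * np.exp(-k * dt) - y

        # y0/plateau guesses from the earliest/latest observations
        y0_guess = float(y[np.argmin(t)])
        plat_guess = float(y[np.argmax(t)])
        lower = [-np.inf, -np.inf, 0.0]
        upper = [np.inf, np.inf, self.k_max]

        best = None
        for k0 in np.logspace(-3, 0, self.n_starts):
            try:
                res = optimize.least_squares(
                    resid, [y0_guess, plat_guess, k0], bounds=(lower, upper),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
            except Exception:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, res)
        if best is None or not best[1].success:
            cand = None
            if best is not None:
                y0, plateau, k = best[1].x
                cand = DecayFitResult(float(y0), float(plateau), float(k),
                                      best[0], self.df_, n)
            raise FitConvergenceError("one-phase decay fit did not converge", best=cand)

        y0, plateau, k = best[1].x
        self.y0_ = float(y0)
        self.plateau_ = float(plateau)
        self.k_ = float(k)
        self.rss_ = best[0]
        return self

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau_ + (self.y0_ - self.plateau_) * np.exp(-self.k_ * (t - self.t0))

    def result(self) -> DecayFitResult:
        return DecayFitResult(self.y0_, self.plateau_, self.k_, self.rss_, self.df_, self.n_)


def fit_one_phase_decay(points: Mapping[float, float] | tuple) -> DecayFitResult:
    """Fit a one-phase decay to ``{day: score}`` (or ``(t, y)`` arrays)."""
    if isinstance(points, Mapping):
        t = np.array(sorted(points), dtype=float)
        y = np.array([points[d] for d in sorted(points)], dtype=float)
    else:
        t, y = points
    return OnePhaseDecay().fit(t, y).result()


@dataclass(frozen=True)
class FTestResult:
    """Extra sum-of-squares F test outcome."""

    f: float
    df_num: int
    df_den: int
    p: float
    degenerate: bool = False


def extra_ss_f_test(shared: DecayFitResult,
                    separate: Sequence[DecayFitResult]) -> FTestResult:
    """Does one shared curve fit all groups as well as per-group curves?

    Compares the pooled fit (``shared``) against the per-group fits over the
    identical data partition::

        F = ((rss_shared - rss_sep) / (df_shared - df_sep)) / (rss_sep / df_sep)

    with ``rss_sep``/``df_sep`` summed over groups; the p-value comes from
    the F distribution.  A perfect separate fit with a worse shared fit is a
    degenerate perfect separation and returns ``p = 0`` flagged.
    """
    rss_sep = sum(f.rss for f in separate)
    df_sep = sum(f.df for f in separate)
    if shared.df <= df_sep:
        raise ValueError("shared fit must have more residual degrees of freedom")
    df_num = shared.df - df_sep
    extra = max(shared.rss - rss_sep, 0.0)
    if rss_sep == 0.0:
        if extra == 0.0:  # every fit perfect: no evidence either way
            return FTestResult(0.0, df_num, df_sep, 1.0, degenerate=True)
        return FTestResult(float("inf"), df_num, df_sep, 0.0, degenerate=True)
    f = (extra / df_num) / (rss_sep / df_sep)
    p = float(stats.f.sf(f, df_num, df_sep))
    return FTestResult(float(f), df_num, df_sep, p)
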