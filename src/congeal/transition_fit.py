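"""Generalized-logistic fits of divergence transitions.

AFD as a function of log10(theta) is fitted with the two-parameter logistic
y = 1 / (1 + exp(-a (x - b))); median between-deme LD as a function of time
with the three-parameter form y = z / (1 + exp(-a (x - b))), z the
asymptote.  ``b`` locates the inflection (where change is most rapid) and
``a`` sets the steepness there.  Comparing selected-site and neutral-site
fits yields the lag (horizontal offset of inflections) and the gap
(vertical divergence difference) between the two classes of sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares


@dataclass
class LogisticFit:
    a: float
    b: float
    z: float  # 1.0 for the two-parameter form
    rss: float
    converged: bool
    n_points: int
    form: str  # "2p" | "3p"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.z / (1.0 + np.exp(-self.a * (np.asarray(x) - self.b)))


def _multistart_b(x: np.ndarray) -> np.ndarray:
    return np.quantile(x, [0.1, 0.25, 0.5, 0.75, 0.9])


_A_STARTS = (1.0, -1.0, 10.0, -10.0)


def _a_starts(x: np.ndarray) -> tuple:
    # include slope starts scaled to the data range so axes in raw
    # generations (x ~ 1e5) get a workable starting magnitude
    span = float(np.ptp(x))
    scaled = () if span <= 0 else (4.0 / span, -4.0 / span,
                                   40.0 / span, -40.0 / span)
    return _A_STARTS + scaled


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(u, -700.0, 700.0)))


def fit_logistic2(x: np.ndarray, y: np.ndarray,
                  max_iter: int = 10_000) -> LogisticFit:
    """Least-squares fit of y = 1/(1 + exp(-a(x-b))).

    Multi-start Levenberg-Marquardt-style minimization with an analytic
    Jacobian; start points span the data quantiles in b and both signs and
    magnitudes in a.  Degenerate (constant) y is flagged non-converged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4 or np.ptp(y) < 1e-12:
        return LogisticFit(math.nan, math.nan, 1.0, math.nan, False, n, "2p")

    def resid(p):
        a, b = p
        return _sigmoid(-a * (x - b)) - y

    def jac(p):
        a, b = p
        f = _sigmoid(-a * (x - b))
        g = f * (1.0 - f)
        return np.column_stack([g * (x - b), g * (-a)])

    best = None
    for b0 in _multistart_b(x):
        for a0 in _a_starts(x):
            try:
                sol = least_squares(resid, x0=[a0, b0], jac=jac,
                                    method="lm", xtol=1e-15, ftol=1e-15,
                                    gtol=1e-15, max_nfev=max_iter)
            except Exception:
                continue
            rss = float(2 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return LogisticFit(math.nan, math.nan, 1.0, math.nan, False, n, "2p")
    rss, sol = best
    a, b = sol.x
    return LogisticFit(float(a), float(b), 1.0, rss,
                       bool(sol.success and np.isfinite(rss)), n, "2p")


def fit_logistic3(x: np.ndarray, y: np.ndarray,
                  max_iter: int = 10_000) -> LogisticFit:
    """Least-squares fit of y = z/(1 + exp(-a(x-b))) with 0 < z <= 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4 or np.ptp(y) < 1e-12:
        return LogisticFit(math.nan, math.nan, math.nan, math.nan, False, n,
                           "3p")

    def resid(p):
        z, a, b = p
        return z * _sigmoid(-a * (x - b)) - y

    def jac(p):
        z, a, b = p
        f = _sigmoid(-a * (x - b))
        g = z * f * (1.0 - f)
        return np.column_stack([f, g * (x - b), g * (-a)])

    z0 = min(max(float(y.max()), 1e-3), 1.0)
    best = None
    for b0 in _multistart_b(x):
        for a0 in _a_starts(x):
            try:
                sol = least_squares(
                    resid, x0=[z0, a0, b0], jac=jac, method="trf",
                    bounds=([1e-9, -np.inf, -np.inf], [1.0, np.inf, np.inf]),
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_iter)
            except Exception:
                continue
            rss = float(2 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return LogisticFit(math.nan, math.nan, math.nan, math.nan, False, n,
                           "3p")
    rss, sol = best
    z, a, b = sol.x
    return LogisticFit(float(a), float(b), float(z), rss,
                       bool(sol.success and np.isfinite(rss)), n, "3p")


@dataclass
class TransitionReport:
    lag: float           # b_neutral - b_selected, shared-axis units
    gap: float           # y_selected(b_selected) - y_neutral(b_selected)
    a_selected: float
    a_neutral: float
    b_selected: float
    b_neutral: float


def transition_report(fit_selected: LogisticFit,
                      fit_neutral: LogisticFit) -> TransitionReport:
    """Lag and gap between selected- and neutral-site transitions.

    The lag is the horizontal distance between inflection points (how much
    later the neutral transition begins); the gap is the vertical divergence
    difference evaluated at the selected inflection.
    """
    if not (fit_selected.converged and fit_neutral.converged):
        raise ValueError("both fits must be converged")
    lag = fit_neutral.b - fit_selected.b
    gap = float(fit_selected.predict(fit_selected.b)
                - fit_neutral.predict(fit_selected.b))
    return TransitionReport(lag=lag, gap=gap,
                            a_selected=fit_selected.a,
                            a_neutral=fit_neutral.a,
                            b_selected=fit_selected.b,
                            b_neutral=fit_neutral.b)
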