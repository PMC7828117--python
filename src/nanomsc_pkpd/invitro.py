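"""Small-data calibration fits performed outside the ODE estimation stack:
first-order drug release (association), nanoparticle exocytosis (decay), and
the bioluminescence-to-volume power calibration.

All three are exposed as scikit-learn style estimators (``fit`` +
trailing-underscore attributes) plus thin functional wrappers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .params import BioluminescenceCalibration

__all__ = [
    "FirstOrderAssociation",
    "FirstOrderDecay",
    "PowerCalibration",
    "fit_first_order_association",
    "fit_first_order_decay",
    "fit_power_calibration",
    "mass_scale_kexo",
]


def _validate_series(times, values, min_points=3, name="values"):
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {t.size}")
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(y)):
        raise ValueError("non-finite inputs")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t, y


def _r_squared(y, yhat):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


class FirstOrderAssociation(BaseEstimator):
    """One-phase association fit y(t) = plateau * (1 - exp(-k*t)) by
    nonlinear least squares (log-parameterized rate, starting values from a
    log-linear regression).

    Fitted attributes: ``plateau_``, ``rate_`` (1/h), ``r2_``.
    """

    def __init__(self, max_iterations: int = 10000):
        self.max_iterations = max_iterations

    def _start(self, t, y):
        plateau0 = max(float(np.max(y)) * 1.05, 1e-6)
        mask = (y > 0) & (y < plateau0) & (t > 0)
        if mask.sum() >= 2:
            z = np.log(1.0 - y[mask] / plateau0)
            k0 = max(-float(np.polyfit(t[mask], z, 1)[0]), 1e-8)
        else:
            k0 = 1.0 / max(float(np.mean(t[t > 0])) if np.any(t > 0) else 1.0, 1e-8)
        return plateau0, k0

    def fit(self, times, values):
        t, y = _validate_series(times, values)
        plateau0, k0 = self._start(t, y)

        def f(tt, log_plateau, log_k):
            return np.exp(log_plateau) * (1.0 - np.exp(-np.exp(log_k) * tt))

        try:
            popt, _ = curve_fit(f, t, y, p0=[np.log(plateau0), np.log(k0)],
                                maxfev=self.max_iterations)
        except RuntimeError as err:
            raise RuntimeError(
                f"association fit failed to converge (start plateau={plateau0:g}, "
                f"k={k0:g}): {err}") from err
        self.plateau_ = float(np.exp(popt[0]))
        self.rate_ = float(np.exp(popt[1]))
        self.r2_ = _r_squared(y, f(t, *popt))
        return self

    def predict(self, times):
        t = np.asarray(times, dtype=float)
        return self.plateau_ * (1.0 - np.exp(-self.rate_ * t))


class FirstOrderDecay(BaseEstimator):
    """One-phase decay fit y(t) = y0 * exp(-k*t) (no plateau term), by
    nonlinear least squares with log-linear starting values.

    Fitted attributes: ``y0_``, ``rate_`` (1/h), ``r2_``.
    """

    def __init__(self, max_iterations: int = 10000):
        self.max_iterations = max_iterations

    def fit(self, times, values):
        t, y = _validate_series(times, values)
        mask = y > 0
        if mask.sum() >= 2:
            slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
            y00, k0 = float(np.exp(intercept)), max(-float(slope), 1e-8)
        else:
            y00, k0 = max(float(np.max(y)), 1e-6), 1.0

        def f(tt, log_y0, log_k):
            return np.exp(log_y0) * np.exp(-np.exp(log_k) * tt)

        try:
            popt, _ = curve_fit(f, t, y, p0=[np.log(y00), np.log(k0)],
                                maxfev=self.max_iterations)
        except RuntimeError as err:
            raise RuntimeError(
                f"decay fit failed to converge (start y0={y00:g}, k={k0:g}): {err}"
            ) from err
        self.y0_ = float(np.exp(popt[0]))
        self.rate_ = float(np.exp(popt[1]))
        self.r2_ = _r_squared(y, f(t, *popt))
        return self

    def predict(self, times):
        t = np.asarray(times, dtype=float)
        return self.y0_ * np.exp(-self.rate_ * t)


class PowerCalibration(BaseEstimator):
    """Power-law calibration VT = a * TV**b fitted by ordinary least squares
    on log(VT) vs log(TV) — the spreadsheet power-trendline procedure.

    ``fit(tv, weight_g)`` converts tumor weight to volume at 1 g/mL.
    Fitted attributes: ``a_``, ``b_``, ``r2_`` (log-log scale),
    ``calibration_`` (a BioluminescenceCalibration).
    """

    #: tumor tissue density used to convert weight (g) to volume (mL)
    density_g_per_ml = 1.0

    def fit(self, tv, weight_g):
        x, w = _validate_series(tv, weight_g, min_points=3, name="pairs")
        if np.any(x <= 0) or np.any(w <= 0):
            raise ValueError("bioluminescence and weight must be > 0")
        vt = w / self.density_g_per_ml
        lx, ly = np.log(x), np.log(vt)
        b, log_a = np.polyfit(lx, ly, 1)
        self.a_ = float(np.exp(log_a))
        self.b_ = float(b)
        self.r2_ = _r_squared(ly, b * lx + log_a)
        self.calibration_ = BioluminescenceCalibration(a=self.a_, b=self.b_)
        return self

    def predict(self, tv):
        x = np.asarray(tv, dtype=float)
        return self.a_ * x**self.b_


def fit_first_order_association(times, release):
    """Fit release(t) = plateau*(1-exp(-Krel*t)); returns (plateau, Krel, R2)."""
    m = FirstOrderAssociation().fit(times, release)
    return m.plateau_, m.rate_, m.r2_


def fit_first_order_decay(times, retained):
    """Fit retained(t) = y0*exp(-Kexo*t); returns (y0, Kexo, R2) with Kexo on
    an NP-mass basis (see :func:`mass_scale_kexo`)."""
    m = FirstOrderDecay().fit(times, retained)
    return m.y0_, m.rate_, m.r2_


def fit_power_calibration(tv, weight_g):
    """Fit the bioluminescence-volume power law; returns
    (BioluminescenceCalibration, R2)."""
    m = PowerCalibration().fit(tv, weight_g)
    return m.calibration_, m.r2_


def mass_scale_kexo(kexo_np_mass: float, loading: float) -> float:
    """Rescale an exocytosis rate constant from an NP-mass to a PTX-mass
    basis by the drug loading (mg PTX per mg NP)."""
    if not (kexo_np_mass > 0 and loading > 0):
        raise ValueError("Kexo and loading must be > 0")
    return kexo_np_mass * loading
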