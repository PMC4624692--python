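"""Single-component 24-h cosinor rhythmometry.

The model is

    y(t) = M + A * cos(omega * t - phi),    omega = pi/12 rad/h,

fit by ordinary least squares through the exact linearization

    y(t) = M + beta * cos(omega t) + gamma * sin(omega t),
    beta = A cos(phi),  gamma = A sin(phi),

which minimizes the same residual sum of squares as direct nonlinear
regression on (M, A, phi).  The acrophase is reported in hours on the ZT
scale (phi_h = phi * 12/pi, mod 24), i.e. the clock time of the fitted
peak.  Standard errors of amplitude and acrophase follow from the linear
model's covariance by the delta method; rhythm significance is the
zero-amplitude F-test of the cosinor fit against an intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import OMEGA

#: Relative tolerance below which a residual sum of squares is treated as an
#: exact (perfect) fit.
_PERFECT_FIT_RTOL = 1e-12


class CosinorError(ValueError):
    """Data unsuitable for a cosinor fit."""


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares estimates for a single-component 24-h cosinor.

    Units: ``mesor``, ``amplitude`` and their SEs are in the expression
    units of ``y``; ``acrophase_h`` and its SE are hours; ``rss`` is in
    squared expression units.  ``amplitude_ci`` is the two-sided
    ``ci_level`` Student-t interval on the amplitude, floored at 0.
    ``p_zero_amplitude`` is the zero-amplitude F-test p-value; a perfect
    fit of a non-flat rhythm reports ``f_zero_amplitude = inf``, ``p = 0``
    and ``perfect_fit = True``.  ``acrophase_h`` is NaN when the fitted
    amplitude is exactly 0 (the acrophase is then undefined).
    """

    mesor: float
    amplitude: float
    acrophase_h: float
    beta: float
    gamma: float
    se_mesor: float
    se_amplitude: float
    se_acrophase_h: float
    rss: float
    n: int
    dof: int
    f_zero_amplitude: float
    p_zero_amplitude: float
    amplitude_ci: tuple[float, float]
    ci_level: float
    perfect_fit: bool

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        """Fitted mean at ZT hours ``t`` (peak value M + A at the acrophase)."""
        phi = 0.0 if np.isnan(self.acrophase_h) else OMEGA * self.acrophase_h
        return self.mesor + self.amplitude * np.cos(OMEGA * np.asarray(t, dtype=float) - phi)


def fit_cosinor(
    t: np.ndarray, y: np.ndarray, ci_level: float = 0.99
) -> CosinorFit:
    """Fit the 24-h cosinor to per-fish observations ``(t, y)``.

    ``t`` is in ZT hours; observations at ZT-0 and ZT-24 enter with
    identical regressors (24-h periodicity), which is correct behaviour.
    Requires ``n >= 4`` and at least three distinct regressor rows so that
    mesor, amplitude and acrophase are all identifiable.
    """
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if t.shape != y.shape:
        raise CosinorError("t and y must have equal length")
    n = t.size
    if n <= 3:
        raise CosinorError(f"need n >= 4 observations, got {n}")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise CosinorError("t and y must be finite")

    X = np.column_stack([np.ones(n), np.cos(OMEGA * t), np.sin(OMEGA * t)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise CosinorError(
            "cosinor regressors are collinear (need >= 3 distinct time points mod 24)"
        )
    mesor, beta, gamma = (float(c) for c in coef)
    resid = y - X @ coef
    rss = float(resid @ resid)
    rss = max(rss, 0.0)
    dof = n - 3

    amplitude = float(np.hypot(beta, gamma))
    if amplitude <= 1e-12 * max(1.0, float(np.abs(y).max())):
        # numerically zero harmonic component: report an exactly flat fit
        amplitude, beta, gamma = 0.0, 0.0, 0.0
    if amplitude > 0.0:
        acrophase_h = float((np.arctan2(gamma, beta) * 12.0 / np.pi) % 24.0)
        if acrophase_h >= 24.0:  # float wrap of a tiny negative phase
            acrophase_h = 0.0
    else:
        acrophase_h = float("nan")

    ybar_rss = float(np.sum((y - y.mean()) ** 2))
    scale = max(1.0, float(y @ y))
    perfect = rss <= _PERFECT_FIT_RTOL * scale

    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / dof
    cov = sigma2 * xtx_inv
    se_mesor = float(np.sqrt(cov[0, 0]))
    var_b, var_g, cov_bg = cov[1, 1], cov[2, 2], cov[1, 2]
    if amplitude > 0.0:
        se_amplitude = float(
            np.sqrt(beta**2 * var_b + gamma**2 * var_g + 2 * beta * gamma * cov_bg)
            / amplitude
        )
        se_acro_rad = float(
            np.sqrt(gamma**2 * var_b + beta**2 * var_g - 2 * beta * gamma * cov_bg)
            / amplitude**2
        )
        se_acrophase_h = se_acro_rad * 12.0 / np.pi
    else:
        se_amplitude = float(np.sqrt((var_b + var_g) / 2.0))  # isotropic limit
        se_acrophase_h = float("nan")

    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, dof))
    ci = (max(0.0, amplitude - tcrit * se_amplitude), amplitude + tcrit * se_amplitude)

    # Zero-amplitude F-test against the intercept-only model.
    if perfect:
        if ybar_rss <= _PERFECT_FIT_RTOL * scale:
            f_stat, p = 0.0, 1.0  # constant data: flat model is also perfect
            perfect = False
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((ybar_rss - rss) / 2.0) / (rss / dof)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, 2, dof))

    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase_h=acrophase_h,
        beta=beta,
        gamma=gamma,
        se_mesor=se_mesor,
        se_amplitude=se_amplitude,
        se_acrophase_h=se_acrophase_h,
        rss=rss,
        n=n,
        dof=dof,
        f_zero_amplitude=f_stat,
        p_zero_amplitude=p,
        amplitude_ci=ci,
        ci_level=ci_level,
        perfect_fit=perfect,
    )


def zero_amplitude_test(fit: CosinorFit, y: np.ndarray) -> tuple[float, float]:
    """Zero-amplitude F-test of ``fit`` against the intercept-only model.

    ``F = ((rss0 - rss)/2) / (rss/(n-3))`` with ``rss0`` the intercept-only
    residual sum of squares of ``y``; the p-value is from F(2, n-3).
    Returns ``(F, p)``; a perfect rhythmic fit yields ``(inf, 0.0)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != fit.n:
        raise CosinorError("y must be the data the fit was computed on")
    rss0 = float(np.sum((y - y.mean()) ** 2))
    scale = max(1.0, float(y @ y))
    if fit.rss <= _PERFECT_FIT_RTOL * scale:
        if rss0 <= _PERFECT_FIT_RTOL * scale:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = max(((rss0 - fit.rss) / 2.0) / (fit.rss / fit.dof), 0.0)
    return f_stat, float(stats.f.sf(f_stat, 2, fit.dof))


def predict(fit: CosinorFit, t: np.ndarray | float) -> np.ndarray | float:
    """Fitted cosinor mean at ZT hours ``t``; equals M + A at the acrophase."""
    return fit.predict(t)


def acrophase_difference(fit_a: CosinorFit | float, fit_b: CosinorFit | float) -> float:
    """Circular acrophase difference a - b in signed hours, wrapped to (-12, 12].

    Negative values mean ``a`` peaks earlier (phase advance of ``a``
    relative to ``b``).  Accepts fits or acrophases in hours.
    """
    pa = fit_a.acrophase_h if isinstance(fit_a, CosinorFit) else float(fit_a)
    pb = fit_b.acrophase_h if isinstance(fit_b, CosinorFit) else float(fit_b)
    d = (pa - pb) % 24.0
    if d > 12.0:
        d -= 24.0
    return d
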