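"""Re-epithelialization kinetics: modified-Gompertz fitting and screening QC.

Counts of cells infiltrating a scratch over time follow a sigmoid with a lag
phase, an exponential phase and a plateau, so the modified (Zwietering)
Gompertz growth model is fitted to each well's inside-count series:

    N(t) = A * exp(-exp( (mu_m * e / A) * (lam - t) + 1 ))

with plateau ``A`` (cells), maximum infiltration rate ``mu_m``
(cells / minute, the slope at the inflection point) and lag time ``lam``
(minutes, where the inflection tangent crosses zero; may be negative when
migration started before imaging).  Fitting is nonlinear least squares by a
Levenberg-Marquardt iteration; fits with R^2 below 0.9 (or that failed to
converge) are flagged for inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "GompertzParams",
    "KineticFit",
    "gompertz",
    "initial_guess",
    "fit_gompertz",
    "goodness_of_fit",
    "flag_fit",
    "z_prime",
]

#: R^2 below which a fit is flagged for visual inspection.
R2_FLAG_THRESHOLD = 0.9

_E = math.e
# exp() argument cap; exp(-exp(40)) underflows to 0 long before this matters
_EXP_CAP = 700.0


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the modified Gompertz growth curve."""

    A: float  # plateau cell count, > 0
    mu_m: float  # maximum rate, cells/minute, > 0
    lam: float  # lag time, minutes; negative allowed

    def __post_init__(self) -> None:
        if not (self.A > 0):
            raise ValidationError(f"A must be positive, got {self.A}")
        if not (self.mu_m > 0):
            raise ValidationError(f"mu_m must be positive, got {self.mu_m}")
        if not math.isfinite(self.lam):
            raise ValidationError(f"lam must be finite, got {self.lam}")


@dataclass
class KineticFit:
    """Result of fitting the Gompertz model to one infiltration series."""

    params: GompertzParams | None
    r_squared: float
    rmse: float
    converged: bool
    n_points: int
    flagged: bool
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))


def gompertz(t, params: GompertzParams):
    """Evaluate the modified Gompertz curve at times ``t`` (minutes).

    Vectorized over ``t``; returns values in (0, A) for finite times,
    strictly increasing in ``t``.
    """
    t = np.asarray(t, dtype=float)
    inner = (params.mu_m * _E / params.A) * (params.lam - t) + 1.0
    return params.A * np.exp(-np.exp(np.minimum(inner, _EXP_CAP)))


def _gompertz_theta(t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Model in the optimizer's coordinates theta = (log A, log mu_m, lam)."""
    # clamp log-params so a wild trial step yields a finite (rejectable)
    # candidate instead of an overflow
    a = math.exp(min(max(theta[0], -300.0), 300.0))
    mu = math.exp(min(max(theta[1], -300.0), 300.0))
    inner = (mu * _E / a) * (theta[2] - t) + 1.0
    return a * np.exp(-np.exp(np.minimum(inner, _EXP_CAP)))


def initial_guess(series) -> GompertzParams:
    """Tangent-based starting values for the fit.

    A0 is the largest observed count; mu_m0 the steepest secant slope
    (floored at 1e-6 so flat series stay finite); lam0 the time-axis
    intercept of the tangent through the steepest point.
    """
    counts = np.asarray(series.inside, dtype=float)
    times = np.asarray(series.times, dtype=float)
    if counts.size < 4:
        raise ValidationError("initial_guess requires at least 4 timepoints")
    if not np.any(counts > 0):
        raise DegenerateInputError("all-zero count series")
    a0 = float(counts.max())
    slopes = np.diff(counts) / np.diff(times)
    k = int(np.argmax(slopes))
    mu0 = max(float(slopes.max()), 1e-6)
    lam0 = float(times[k] - counts[k] / mu0)
    return GompertzParams(A=a0, mu_m=mu0, lam=lam0)


def _levenberg_marquardt(
    t: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    rel_tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, float, bool]:
    """Damped Gauss-Newton (Marquardt diagonal scaling) on theta.

    Damping starts at 1e-3, is divided by 10 on an accepted step and
    multiplied by 10 on a rejected one.  Returns (theta, rss, converged)
    where convergence means the relative RSS decrease of an accepted step
    fell below ``rel_tol``.
    """
    theta = theta0.astype(float).copy()
    resid = _gompertz_theta(t, theta) - y
    rss = float(resid @ resid)
    damping = 1e-3
    h = 1e-6

    for _ in range(max_iter):
        # forward-difference Jacobian in theta; model is cheap and smooth
        jac = np.empty((t.size, 3))
        for j in range(3):
            step = h * max(abs(theta[j]), 1.0)
            tp = theta.copy()
            tp[j] += step
            jac[:, j] = (_gompertz_theta(t, tp) - _gompertz_theta(t, theta)) / step
        jtj = jac.T @ jac
        g = jac.T @ resid
        accepted = False
        while damping < 1e14:
            lhs = jtj + damping * np.diag(np.maximum(np.diag(jtj), 1e-12))
            try:
                delta = np.linalg.solve(lhs, -g)
            except np.linalg.LinAlgError:
                damping *= 10.0
                continue
            cand = theta + delta
            cand_resid = _gompertz_theta(t, cand) - y
            cand_rss = float(cand_resid @ cand_resid)
            if np.isfinite(cand_rss) and cand_rss < rss:
                rel_drop = (rss - cand_rss) / max(rss, 1e-300)
                theta, resid, rss = cand, cand_resid, cand_rss
                damping = max(damping / 10.0, 1e-12)
                accepted = True
                if rel_drop < rel_tol or rss == 0.0:
                    return theta, rss, True
                break
            damping *= 10.0
        if not accepted:
            # no direction improves: stationary to working precision
            return theta, rss, True
    return theta, rss, False


def fit_gompertz(series) -> KineticFit:
    """Fit the modified Gompertz model to a well's inside-count series.

    Ordinary (unweighted) least squares, Levenberg-Marquardt, with A and
    mu_m kept positive by log-reparameterization and lam unbounded.
    Several plateau starting values are tried (max count x 1, 3, 10, 30)
    because a series sampled only during the lag phase bounds A poorly;
    the tangent guess is always among them, so the returned solution never
    has a higher residual sum of squares than the initial guess.
    Optimizer failure yields ``converged=False, flagged=True``, never an
    exception.
    """
    counts = np.asarray(series.inside, dtype=float)
    times = np.asarray(series.times, dtype=float)
    if counts.size < 4:
        raise ValidationError(
            f"fit requires at least 4 timepoints, got {counts.size}"
        )
    try:
        guess = initial_guess(series)
    except DegenerateInputError:
        return KineticFit(
            params=None,
            r_squared=float("nan"),
            rmse=float("nan"),
            converged=False,
            n_points=counts.size,
            flagged=True,
            fitted=np.zeros_like(counts),
        )

    best_theta, best_rss, best_conv = None, np.inf, False
    for scale in (1.0, 3.0, 10.0, 30.0):
        a0 = guess.A * scale
        theta0 = np.array([math.log(a0), math.log(guess.mu_m), guess.lam])
        theta, rss, conv = _levenberg_marquardt(times, counts, theta0)
        if rss < best_rss:
            best_theta, best_rss, best_conv = theta, rss, conv
        if best_rss <= 1e-16 * max(1.0, float(counts @ counts)):
            break

    params = GompertzParams(
        A=math.exp(min(max(best_theta[0], -300.0), 300.0)),
        mu_m=math.exp(min(max(best_theta[1], -300.0), 300.0)),
        lam=float(best_theta[2]),
    )
    fitted = gompertz(times, params)
    try:
        r2, rmse = goodness_of_fit(counts, fitted)
    except DegenerateInputError:
        r2, rmse = float("nan"), float(np.sqrt(best_rss / counts.size))
        best_conv = False
    fit = KineticFit(
        params=params,
        r_squared=r2,
        rmse=rmse,
        converged=best_conv,
        n_points=counts.size,
        flagged=False,
        fitted=fitted,
    )
    fit.flagged = flag_fit(fit)
    return fit


def goodness_of_fit(observed, fitted) -> tuple[float, float]:
    """Return (R^2, RMSE) of fitted against observed counts.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the observed mean;
    RMSE = sqrt(SS_res / n).
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValidationError("observed and fitted must have equal length >= 2")
    ss_res = float(np.sum((obs - fit) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("observed counts have zero variance")
    return 1.0 - ss_res / ss_tot, math.sqrt(ss_res / obs.size)


def flag_fit(fit: KineticFit, r2_threshold: float = R2_FLAG_THRESHOLD) -> bool:
    """True iff the fit needs inspection: R^2 strictly below the threshold
    (default 0.9) or the optimizer did not converge.  NaN R^2 flags."""
    if not fit.converged:
        return True
    return not (fit.r_squared >= r2_threshold)


def z_prime(positive, negative) -> float:
    """Z' screening-window factor between positive and negative controls.

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg| using sample
    standard deviations (ddof=1); at most 1, negative when the control
    distributions overlap.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("each control group needs at least 2 values")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0.0:
        raise DegenerateInputError("control group means are equal")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep
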