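"""Fitting the model's response laws to data, and synthesizing such data.

Two fits mirror the experimental procedure on wheat coleoptiles:

* the steady "modified sine-law" ``delta_steady(theta; R, A)`` is fit by
  ordinary least squares to (angle, response) measurements.  ``A``
  scales the curve linearly; ``R`` shapes it, but the shape converges as
  ``R`` grows, so for strongly coupled data ``R`` has a one-sided
  profile-likelihood plateau: the fit reports the plateau rather than a
  misleading point estimate.
* the dose-response memory time ``tau_PIN`` is fit (1D least squares)
  to (duration, maximal transient response) data with ``R`` and ``A``
  fixed by the steady fit, holding ``tau_aux / tau_PIN << 1``.  In that
  limit the transient model is a function of ``delta_T / tau_PIN``
  alone, which the fitter exploits through a precomputed master curve
  before polishing against the full simulation.

The synthetic-data generators produce both kinds of measurement from
the model's own response functions plus additive homoscedastic Gaussian
noise (the measurement-error model; sigma = 0.05 is typical of the
scatter of coleoptile response data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares, minimize_scalar

from gravipin.geometry import StatocyteGeometry, pile_cross_section
from gravipin.pin import PinParameters
from gravipin.response import dose_response
from gravipin.transport import TransportParameters

__all__ = [
    "ResponseCurve",
    "FitResult",
    "fit_sine_law",
    "fit_memory_time",
    "synth_steady_data",
    "synth_dose_data",
    "bin_curve",
]

_TAU_AUX_RATIO = 1.0 / 2000.0  # tau_aux / tau_PIN used for transient fits


@dataclass
class ResponseCurve:
    """A response dataset: stimulus values x (deg or min) and responses y."""

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.x.shape:
                raise ValueError("sigma must match x")
        if np.any(np.diff(self.x) < 0):
            order = np.argsort(self.x, kind="stable")
            self.x = self.x[order]
            self.y = self.y[order]
            if self.sigma is not None:
                self.sigma = self.sigma[order]

    def __len__(self) -> int:
        return self.x.size


@dataclass
class FitResult:
    """Least-squares estimates with convergence/identifiability diagnostics."""

    R_hat: float | None = None
    A_hat: float | None = None
    tau_pin_hat: float | None = None
    rss: float = math.nan
    converged: bool = False
    plateau: bool = False
    plateau_R_lower: float | None = None
    unidentifiable: bool = False
    message: str = ""
    extras: dict = field(default_factory=dict)


def _steady_design(thetas: np.ndarray, geom: StatocyteGeometry) -> tuple[np.ndarray, ...]:
    """Per-angle geometric factors (asym, S0, S1); independent of R and A."""
    asym = np.empty_like(thetas)
    S0 = np.empty_like(thetas)
    S1 = np.empty_like(thetas)
    for i, th in enumerate(thetas):
        part = pile_cross_section(geom, float(th))
        asym[i] = part.S1_r - part.S1_l
        S0[i] = part.S0
        S1[i] = part.S1
    return asym, S0, S1


def fit_sine_law(
    data: ResponseCurve,
    geom: StatocyteGeometry | None = None,
    r_bounds: tuple[float, float] = (1.0 + 1e-9, 1e4),
    a_bounds: tuple[float, float] = (1e-12, 1e2),
    n_starts: int = 6,
    plateau_rtol: float = 1e-3,
    weighted: bool = False,
) -> FitResult:
    """Fit (R, A) of the steady modified sine-law to (angle, response) data.

    Ordinary least squares with a profile over R (A enters linearly, so
    its conditional optimum is closed-form) plus multi-start polishing.
    When the residual at the upper R bound is within ``plateau_rtol`` of
    the optimum, ``plateau`` is set and ``plateau_R_lower`` reports the
    smallest R on the converged plateau — the data then constrain the
    curve (and A), not R itself.
    """
    if geom is None:
        geom = StatocyteGeometry()
    if len(data) < 2 or np.unique(data.x).size < 2:
        raise ValueError("need at least two distinct angles")
    # ordinary least squares by default; optional 1/sigma^2 weights
    w = (1.0 / data.sigma**2 if weighted and data.sigma is not None
         else np.ones_like(data.y))
    asym, S0, S1 = _steady_design(data.x, geom)

    def shape(R: float) -> np.ndarray:
        return 0.5 * (R - 1.0) * asym / (S0 + R * S1)

    def profile(R: float) -> tuple[float, float]:
        g = shape(R)
        denom = float(w @ g**2)
        if denom == 0.0:
            return 0.0, float(w @ data.y**2)
        A = float(np.clip((w @ (data.y * g)) / denom, *a_bounds))
        r = data.y - A * g
        return A, float(w @ r**2)

    R_grid = np.geomspace(max(r_bounds[0], 1.0 + 1e-6), r_bounds[1], 200)
    prof = np.array([profile(R)[1] for R in R_grid])
    best = int(np.argmin(prof))

    def residuals(x: np.ndarray) -> np.ndarray:
        R, A = 10.0 ** x[0], x[1]
        return np.sqrt(w) * (data.y - A * shape(R))

    starts = list(np.geomspace(max(r_bounds[0], 1.001), r_bounds[1] * 0.999,
                               n_starts - 1)) + [R_grid[best]]
    best_fit, best_rss = None, math.inf
    for R0 in starts:
        A0, _ = profile(R0)
        sol = least_squares(
            residuals, x0=[math.log10(R0), max(A0, a_bounds[0])],
            bounds=([math.log10(r_bounds[0]), a_bounds[0]],
                    [math.log10(r_bounds[1]), a_bounds[1]]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        rss = 2.0 * sol.cost
        if rss < best_rss:
            best_rss, best_fit = rss, sol

    R_hat, A_hat = 10.0 ** best_fit.x[0], float(best_fit.x[1])
    rss_top = profile(r_bounds[1])[1]
    scale = float(w @ (data.y - data.y.mean()) ** 2) + 1e-300
    plateau = bool(rss_top - best_rss <= plateau_rtol * max(best_rss, 1e-12 * scale))
    plateau_lower = None
    if plateau:
        thresh = best_rss + plateau_rtol * max(best_rss, 1e-12 * scale)
        on = prof <= thresh
        plateau_lower = float(R_grid[int(np.argmax(on))]) if on.any() else R_hat
    return FitResult(
        R_hat=float(R_hat), A_hat=A_hat, rss=float(best_rss),
        converged=bool(best_fit.success), plateau=plateau,
        plateau_R_lower=plateau_lower,
        message=best_fit.message,
        extras={"profile_R": R_grid, "profile_rss": prof},
    )


_MASTER_CACHE: dict = {}


def _master_curve(theta: float, R: float, A: float,
                  geom: StatocyteGeometry | None, s_grid: np.ndarray,
                  ) -> CubicSpline:
    """Transient response as a function of s = delta_T / tau_PIN.

    With tau_aux/tau_PIN fixed (and small) the coupled dynamics depend
    on time only through t/tau_PIN, so one simulated curve serves all
    candidate tau_PIN values (and is cached across fits).
    """
    key = (theta, R, A, geom, round(math.log(s_grid[0]), 9),
           round(math.log(s_grid[-1]), 9), s_grid.size)
    if key not in _MASTER_CACHE:
        p = PinParameters.from_reduced(R=R, P=1e-4, tau_pin=1.0)
        tp = TransportParameters.from_tau_aux(_TAU_AUX_RATIO)
        _, resp = dose_response(s_grid, theta, p, A=A, geom=geom, transport=tp)
        _MASTER_CACHE[key] = CubicSpline(np.log(s_grid), resp)
    return _MASTER_CACHE[key]


def fit_memory_time(
    data: ResponseCurve,
    theta: float = 45.0,
    R: float = 25.0,
    A: float = 1.3,
    geom: StatocyteGeometry | None = None,
    tau_bounds: tuple[float, float] | None = None,
    polish: bool = True,
    weighted: bool = False,
) -> FitResult:
    """Fit tau_PIN to (duration, maximal transient response) data.

    R and A are held fixed (the steady response fixes them first); the
    only free parameter is the PIN turnover time.  Data lying entirely
    on the saturation plateau carry no timescale information and are
    flagged ``unidentifiable``.
    """
    x = data.x
    if np.any(x <= 0):
        raise ValueError("durations must be positive")
    w = (1.0 / data.sigma**2 if weighted and data.sigma is not None
         else np.ones_like(data.y))
    if tau_bounds is None:
        tau_bounds = (x.min() / 10.0, x.max() * 10.0)
    s_lo, s_hi = x.min() / tau_bounds[1], x.max() / tau_bounds[0]
    s_grid = np.geomspace(s_lo * 0.9, s_hi * 1.1, 80)
    spline = _master_curve(theta, R, A, geom, s_grid)

    def rss_of(tau: float) -> float:
        model = spline(np.log(x / tau))
        return float(w @ (data.y - model) ** 2)

    res = minimize_scalar(lambda lt: rss_of(math.exp(lt)),
                          bounds=(math.log(tau_bounds[0]), math.log(tau_bounds[1])),
                          method="bounded",
                          options={"xatol": 1e-10})
    tau_hat = math.exp(res.x)
    rss = rss_of(tau_hat)

    if polish:
        p_tp = TransportParameters.from_tau_aux(_TAU_AUX_RATIO)

        def rss_direct(tau: float) -> float:
            p = PinParameters.from_reduced(R=R, P=1e-4, tau_pin=1.0)
            _, model = dose_response(x / tau, theta, p, A=A, geom=geom,
                                     transport=p_tp)
            return float(w @ (data.y - model) ** 2)

        res2 = minimize_scalar(
            lambda lt: rss_direct(math.exp(lt)),
            bounds=(math.log(tau_hat) - 0.1, math.log(tau_hat) + 0.1),
            method="bounded", options={"xatol": 1e-8},
        )
        if res2.fun <= rss:
            tau_hat, rss = math.exp(res2.x), float(res2.fun)

    # plateau-only data: no duration below ~3 tau probes the rise
    unident = bool(x.min() > 3.0 * tau_hat)
    at_bound = (tau_hat <= tau_bounds[0] * 1.01) or (tau_hat >= tau_bounds[1] * 0.99)
    return FitResult(
        R_hat=R, A_hat=A, tau_pin_hat=float(tau_hat), rss=rss,
        converged=bool(res.success) and not at_bound,
        unidentifiable=unident or at_bound,
        message="plateau-only data: tau_PIN not identifiable" if unident else "",
    )


def synth_steady_data(
    R: float = 25.0,
    A: float = 1.3,
    geom: StatocyteGeometry | None = None,
    n_angles: int = 100,
    sigma: float = 0.05,
    seed: int | None = None,
    angles: np.ndarray | None = None,
) -> ResponseCurve:
    """Synthetic steady sine-law measurements: model curve + Gaussian noise."""
    from gravipin.response import steady_response

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if angles is None:
        angles = np.linspace(0.0, 180.0, n_angles)
    angles = np.asarray(angles, dtype=float)
    y = np.asarray(steady_response(angles, R, A, geom), dtype=float)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=angles.size)
    return ResponseCurve(x=angles, y=y,
                         sigma=np.full(angles.size, sigma) if sigma > 0 else None)


def synth_dose_data(
    tau_pin: float = 13.0,
    theta: float = 45.0,
    R: float = 25.0,
    A: float = 1.3,
    durations: np.ndarray | None = None,
    sigma: float = 0.05,
    seed: int | None = None,
    geom: StatocyteGeometry | None = None,
) -> ResponseCurve:
    """Synthetic dose-response measurements: transient model + Gaussian noise."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if durations is None:
        durations = np.geomspace(1.0, 120.0, 12)
    durations = np.asarray(durations, dtype=float)
    p = PinParameters.from_reduced(R=R, P=1e-4, tau_pin=tau_pin)
    tp = TransportParameters.from_tau_aux(tau_pin * _TAU_AUX_RATIO)
    _, y = dose_response(durations, theta, p, A=A, geom=geom, transport=tp)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=durations.size)
    return ResponseCurve(x=durations, y=y,
                         sigma=np.full(durations.size, sigma) if sigma > 0 else None)


def bin_curve(data: ResponseCurve, n_bins: int,
              x_range: tuple[float, float] | None = None) -> ResponseCurve:
    """Bin a response curve into equal-width boxes; empty bins are dropped.

    Default range is [0, 180] degrees (the binning used to summarize
    sine-law measurements); pass ``x_range`` for other data.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = x_range if x_range is not None else (0.0, 180.0)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(data.x, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            xs.append(data.x[m].mean())
            ys.append(data.y[m].mean())
    return ResponseCurve(x=np.array(xs), y=np.array(ys))
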