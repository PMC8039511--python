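"""Auxin transport across a 1D array of cells.

The tissue of width ``2R`` is a row of ``N`` identical cells.  Efflux
permeabilities ``P^l, P^r`` (set by the PIN distribution) and a
quasi-steady cell wall give the discrete hopping model

    2 W dc_n/dt = P^l (c_{n+1} - c_n) + P^r (c_{n-1} - c_n),

whose continuum limit is the advection–diffusion equation
``dc/dt = D c'' - v c'`` with ``D = W (P^l + P^r)/4 ... = W P/2`` and
``v = (P^r - P^l)/2``.  The discrete model *is* the spatial
discretization used for transients (method of lines); the closed-form
continuum results are used as oracles.

Nondimensionalization: lengths in units of the organ width ``2R`` (cell
width ``h = 1/N``), time in minutes, diffusivity ``D_star`` in units of
``(2R)^2 / min``.  The advection strength is the Peclet number
``Pe = 2R v / D``; the corresponding permeability asymmetry is
``dP = 2 Pe D_star``, physical only while ``|dP| <= 2 P_bar`` i.e.
``|Pe| <= 2N`` (one-sided permeabilities cannot go negative).

Boundaries are impermeable: total auxin is conserved and a steady
profile with ``Pe != 0`` is exponential,
``c(x)/c_mean = Pe e^{Pe x}/(e^{Pe} - 1)``, giving the steady
gravitropic response (relative half-gradient) ``Pe/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransportParameters",
    "AuxinField",
    "transport_rhs",
    "wall_resolved_rhs",
    "steady_profile",
    "relative_gradient",
    "relaxation_time",
    "transport_matrices",
]


@dataclass(frozen=True)
class TransportParameters:
    """Discretization and transport scales.

    Parameters
    ----------
    N : number of cells across the organ (>= 3).
    D_star : auxin diffusivity in units of (2R)^2/min.  The purely
        diffusive relaxation time of the slowest mode is
        ``tau_aux = 1/(pi^2 D_star)``.
    w_ratio : wall-to-cell width ratio ``w/W`` (wall-resolved model only).
    P_in : influx permeability in units of 2R/min (wall-resolved model only).
    """

    N: int = 100
    D_star: float = 1.0
    w_ratio: float = 1e-4
    P_in: float | None = None

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("need at least N = 3 cells")
        if self.D_star <= 0:
            raise ValueError("D_star must be positive")

    @classmethod
    def from_tau_aux(cls, tau_aux: float, N: int = 100, **kw) -> "TransportParameters":
        """Set D_star from the diffusive relaxation time tau_aux (min)."""
        if tau_aux <= 0:
            raise ValueError("tau_aux must be positive")
        return cls(N=N, D_star=1.0 / (math.pi**2 * tau_aux), **kw)

    @property
    def h(self) -> float:
        """Cell width in organ units, 1/N."""
        return 1.0 / self.N

    @property
    def P_bar(self) -> float:
        """Mean efflux permeability 2 D_star / h (organ units/min)."""
        return 2.0 * self.D_star * self.N

    def permeabilities(self, Pe: float) -> tuple[float, float]:
        """(P^l, P^r) realizing the requested Peclet number at fixed D."""
        dP = 2.0 * Pe * self.D_star
        if abs(dP) > 2.0 * self.P_bar:
            raise ValueError(
                f"|Pe| = {abs(Pe):g} exceeds 2N = {2 * self.N}: a one-sided "
                "permeability would be negative at this diffusivity"
            )
        return self.P_bar - dP / 2.0, self.P_bar + dP / 2.0


@dataclass
class AuxinField:
    """Cell concentrations across the organ (cell 1 = top, cell N = bottom)."""

    c: np.ndarray
    C_walls: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)

    @property
    def c_mean(self) -> float:
        return float(self.c.mean())

    @classmethod
    def uniform(cls, N: int, c_mean: float = 1.0) -> "AuxinField":
        return cls(c=np.full(N, c_mean))


def transport_rhs(field: AuxinField, Pe_t: float, tp: TransportParameters
                  ) -> np.ndarray:
    """dc/dt of the quasi-steady-wall discrete model at Peclet ``Pe_t``.

    No-flux boundaries; written in flux form so total auxin is conserved
    to round-off.
    """
    if not math.isfinite(Pe_t):
        raise ValueError("Pe must be finite")
    c = field.c
    Pl, Pr = tp.permeabilities(Pe_t)
    # J[k] = flux from cell k+1 to cell k+2 (k = 0..N-2), organ units/min
    J = 0.5 * (Pr * c[:-1] - Pl * c[1:])
    dc = np.empty_like(c)
    dc[0] = -J[0]
    dc[1:-1] = J[:-1] - J[1:]
    dc[-1] = J[-1]
    return dc / tp.h


def transport_matrices(tp: TransportParameters) -> tuple[np.ndarray, np.ndarray]:
    """(T0, T1) such that dc/dt = (T0 + Pe(t) T1) c.

    T0 is the diffusive part, T1 the advective part per unit Peclet;
    both have zero column sums (conservation).
    """
    N = tp.N
    e = np.ones(N - 1)
    lap = np.diag(e, 1) + np.diag(e, -1) - 2.0 * np.eye(N)
    lap[0, 0] += 1.0
    lap[-1, -1] += 1.0
    T0 = tp.D_star * N * N * lap

    adv = np.zeros((N, N))
    half = 0.5 * tp.D_star * N
    for n in range(N - 1):  # flux Pe*D*(c_n + c_{n+1})/2 from n to n+1
        adv[n, n] -= half
        adv[n, n + 1] -= half
        adv[n + 1, n] += half
        adv[n + 1, n + 1] += half
    return T0, adv


def wall_resolved_rhs(field: AuxinField, Pe_t: float, tp: TransportParameters
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(dc/dt, dC/dt) of the full two-compartment (cell + wall) model.

    The N-1 interior walls carry their own concentration ``C_n``; the
    organ's outer membranes are impermeable.  As ``w/W -> 0`` the wall
    concentrations become slaved to ``(P^r c_n + P^l c_{n+1})/(2 P_in)``
    and the trajectories converge to :func:`transport_rhs`.
    """
    c, C = field.c, field.C_walls
    if C is None:
        raise ValueError("wall-resolved model needs field.C_walls (N-1 walls)")
    Pl, Pr = tp.permeabilities(Pe_t)
    P_in = tp.P_in if tp.P_in is not None else tp.P_bar
    h, w = tp.h, tp.w_ratio * tp.h
    dC = (-2.0 * P_in * C + Pr * c[:-1] + Pl * c[1:]) / w
    dc = np.zeros_like(c)
    dc[0] = -Pr * c[0] + P_in * C[0]
    dc[1:-1] = -(Pl + Pr) * c[1:-1] + P_in * (C[:-1] + C[1:])
    dc[-1] = -Pl * c[-1] + P_in * C[-1]
    return dc / h, dC


def steady_profile(Pe: float, xi) -> np.ndarray:
    """Steady no-flux concentration profile c(xi)/c_mean, xi in [0, 1].

    ``Pe e^{Pe xi} / (e^{Pe} - 1)``; the Pe -> 0 limit is the linear
    profile ``1 + Pe (xi - 1/2)``.  Integrates to 1 over [0, 1].
    """
    xi = np.asarray(xi, dtype=float)
    if abs(Pe) < 1e-8:
        return 1.0 + Pe * (xi - 0.5)
    return Pe * np.exp(Pe * xi) / np.expm1(Pe)


def relative_gradient(field: AuxinField, mode: str = "face") -> float:
    """Dimensionless gravitropic response (c_bottom - c_top) / (2 c_mean).

    ``mode="face"`` (default) linearly extrapolates the two outermost
    cell-center values to the organ faces (O(1/N^2) discretization
    error); ``mode="cell"`` uses the raw boundary-cell values (O(1/N)).
    """
    c = field.c
    if c.size < 2:
        raise ValueError("need at least two cells")
    cm = field.c_mean
    if cm == 0:
        raise ValueError("zero mean concentration")
    if mode == "face" and c.size >= 3:
        c_top = 1.5 * c[0] - 0.5 * c[1]
        c_bottom = 1.5 * c[-1] - 0.5 * c[-2]
    elif mode in ("face", "cell"):
        c_top, c_bottom = c[0], c[-1]
    else:
        raise ValueError("mode must be 'face' or 'cell'")
    return float((c_bottom - c_top) / (2.0 * cm))


def relaxation_time(Pe: float, two_R: float, v: float) -> float:
    """Auxin relaxation time across the organ, in seconds.

    ``tau_aux = (2R)^2/D / (pi^2 + Pe^2/4)`` expressed through the
    advection speed: ``tau_aux = (2R) / (Pe v) / (pi^2 + Pe^2/4)`` with
    ``two_R`` in micrometres and ``v`` in micrometres/second.  With
    Pe = 1, 2R = 1 mm and v = 3 um/s this gives ~33 s: auxin
    equilibrates across the organ far faster than PIN turnover.
    """
    if Pe <= 0 or v <= 0 or two_R <= 0:
        raise ValueError("Pe, v and two_R must be positive")
    return two_R / (Pe * v) / (math.pi**2 + Pe**2 / 4.0)
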