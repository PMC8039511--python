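"""Full gravitropic response: geometry + PIN trafficking + auxin transport.

A tilt protocol moves the statolith pile, which re-biases PIN
trafficking, which builds a lateral auxin-transport asymmetry
(instantaneous Peclet number), which establishes a transverse auxin
gradient, which drives differential growth and curvature:

    Pe(t)  = A * (int_right [PIN] - int_left [PIN]) / (N_tot / (2R/N))
           = A * (u1 - u0) (S1_r - S1_l) / S       (two-class form)
    dC/dt  = delta_tilde(t) / (R_organ * tau_g),

with ``delta_tilde`` the relative auxin gradient across the organ and
``A`` the lumped PIN-to-total-conductance ratio.  In the steady
limiting-pool, lateral-binding regime the response reduces to the
closed "modified sine-law"

    delta_steady(theta) = (A/2) (R-1) (S1_r - S1_l) / (S0 + R S1),

a piecewise-smooth concave curve in theta whose branch boundaries are
where statoliths completely leave the upper wall (W tan(theta) =
2 H_stato) and completely cover the lower wall (W tan(theta) =
H^2 / (2 H_stato)).

Timescale hierarchy: auxin equilibrates across the organ in
``tau_aux`` (~seconds–minutes) while PIN turnover takes ``tau_PIN``
(~10 min); the latter is the memory time seen in dose-response
experiments, and nothing in the model depends on the intensity of
gravity — only on the inclination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from gravipin.geometry import (
    BindingMode,
    ContactPartition,
    StatocyteGeometry,
    pile_cross_section,
)
from gravipin.pin import (
    MembraneModel,
    PinParameters,
    PinState,
    pin_steady_state,
    pin_timescales,
)
from gravipin.transport import (
    AuxinField,
    TransportParameters,
    relative_gradient,
    transport_matrices,
)

__all__ = [
    "OrganParameters",
    "Protocol",
    "Trajectory",
    "instantaneous_peclet",
    "steady_response",
    "steady_response_general",
    "simulate",
    "dose_response",
]


@dataclass(frozen=True)
class OrganParameters:
    """Organ-scale constants for curvature kinematics.

    R_organ : organ radius (mm); tau_g : growth timescale 1/mean growth
    rate (min); L_gz : growth-zone length (mm) converting curvature to a
    tip angle (the tip angle is only defined up to this factor).
    """

    R_organ: float = 0.5
    tau_g: float = 1200.0
    L_gz: float = 10.0

    def __post_init__(self) -> None:
        if self.R_organ <= 0 or self.tau_g <= 0 or self.L_gz <= 0:
            raise ValueError("organ parameters must be positive")


@dataclass(frozen=True)
class Protocol:
    """Tilt protocol: inclination theta_0 applied for delta_T, then upright.

    ``delta_T = inf`` is a permanent stimulus.  ``gravity_multiple``
    documents the nominal gravity intensity of the protocol (1 = Earth);
    with instantaneous statolith repositioning the model's response is
    independent of it — the statocyte is an inclination sensor, not a
    force sensor — so the field deliberately has no effect on the
    dynamics.
    """

    theta_0: float = 45.0
    delta_T: float = math.inf
    t_end: float = 120.0
    gravity_multiple: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_T < 0:
            raise ValueError("delta_T must be >= 0")
        if math.isfinite(self.delta_T) and self.t_end < self.delta_T:
            raise ValueError("t_end must cover the stimulus")


@dataclass
class Trajectory:
    """Time series of the coupled simulation (times in minutes)."""

    t: np.ndarray
    u0: np.ndarray
    u1: np.ndarray
    Pe: np.ndarray
    delta_tilde: np.ndarray
    curvature: np.ndarray      # 1/mm
    tip_angle: np.ndarray      # degrees, proportional to L_gz
    tau_1: float
    tau_2: float

    @property
    def tau_pin(self) -> float:
        return self.tau_2


def instantaneous_peclet(state: PinState, part: ContactPartition, A: float
                         ) -> float:
    """Peclet number from a two-class PIN state and contact partition.

    Pe = A (u1 - u0)(S1_r - S1_l) / S: the membrane asymmetry weighted
    by the lumped conductance ratio A.  Zero whenever the contact is
    symmetric or the statoliths do not bias trafficking (u1 = u0).
    """
    return A * (state.u1 - state.u0) * (part.S1_r - part.S1_l) / part.S


def steady_response(theta, R: float, A: float,
                    geom: StatocyteGeometry | None = None) -> np.ndarray | float:
    """Steady gravitropic response (modified sine-law), limiting pool +
    lateral binding.

    delta_steady = (A/2)(R-1)(S1_r - S1_l)/(S0 + R S1) with the surfaces
    from the liquid-pile geometry; accepts a scalar angle or an array of
    angles in degrees.
    """
    if R <= 0 or A <= 0:
        raise ValueError("R and A must be positive")
    if geom is None:
        geom = StatocyteGeometry()
    if geom.binding_mode is not BindingMode.LATERAL:
        geom = replace(geom, binding_mode=BindingMode.LATERAL)
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    out = np.empty_like(thetas)
    for i, th in enumerate(thetas):
        part = pile_cross_section(geom, float(th))
        out[i] = 0.5 * A * (R - 1.0) * (part.S1_r - part.S1_l) / (
            part.S0 + R * part.S1)
    return out if np.ndim(theta) else float(out[0])


def steady_response_general(p: PinParameters, geom: StatocyteGeometry,
                            A: float, theta) -> np.ndarray | float:
    """Steady response for any pool number and binding mode.

    delta_steady = (A/2)(R-1)(S1_r - S1_l) u0_steady / S; reduces to
    :func:`steady_response` in the limiting-pool lateral case and to the
    peaked (convex) curve in the infinite-pool regime.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    geom = replace(geom, binding_mode=p.binding_mode)
    R = p.kappa_1 * p.k_off_0 / (p.kappa_0 * p.k_off_1)
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    out = np.empty_like(thetas)
    for i, th in enumerate(thetas):
        part = pile_cross_section(geom, float(th))
        u0 = pin_steady_state(p, part).u0
        out[i] = 0.5 * A * (R - 1.0) * (part.S1_r - part.S1_l) * u0 / part.S
    return out if np.ndim(theta) else float(out[0])


def _phase_grid(t0: float, t1: float, tau_aux: float, n: int) -> np.ndarray:
    """Output grid for one phase: log-spaced head resolving the auxin
    boundary layer, then linear."""
    span = t1 - t0
    head = np.geomspace(max(span * 1e-8, tau_aux * 1e-3), min(span, 5 * tau_aux),
                        n // 2, endpoint=False)
    tail = np.linspace(0.0, span, n - n // 2)
    loc = np.unique(np.concatenate([[0.0], head, tail]))
    return t0 + loc


def simulate(
    protocol: Protocol,
    pin_params: PinParameters,
    A: float = 1.3,
    geom: StatocyteGeometry | None = None,
    transport: TransportParameters | None = None,
    organ: OrganParameters = OrganParameters(),
    pin_scheme: str = "patch",
    t_eval: np.ndarray | None = None,
    n_out: int = 240,
    method: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-13,
    curvature_feedback: bool = False,
    feedback_dt: float = 2.0,
) -> Trajectory:
    """Integrate the coupled PIN + auxin system through a tilt protocol.

    PIN starts at the upright (theta = 0) steady state and auxin uniform.
    The membrane subsystem is linear within each phase and is propagated
    exactly; the auxin deviation ``delta = c/c_mean - 1`` is integrated
    with an implicit (BDF) method with analytic Jacobian
    ``T0 + Pe(t) T1``.  Statolith repositioning at a switch is treated
    as instantaneous.

    ``curvature_feedback=True`` closes the loop exploratorily: the
    effective inclination is reduced by the accumulated tip angle,
    theta(t) = theta_protocol - tip_angle(t), re-evaluated every
    ``feedback_dt`` minutes.  The open-loop default is the configuration
    every reported quantity uses; the closed loop approximates the
    organ's reorientation during the response.
    """
    if geom is None:
        geom = StatocyteGeometry(binding_mode=pin_params.binding_mode)
    if transport is None:
        transport = TransportParameters.from_tau_aux(13.0 / 2000.0)
    tau_aux = 1.0 / (math.pi**2 * transport.D_star)

    part0 = pile_cross_section(geom, 0.0)
    membrane = MembraneModel(pin_params, part0, scheme=pin_scheme)
    T0, T1 = transport_matrices(transport)
    b1 = T1 @ np.ones(transport.N)  # advection acting on the uniform state

    dT = min(protocol.delta_T, protocol.t_end)
    phases = [(0.0, dT, protocol.theta_0)]
    if protocol.t_end > dT:
        phases.append((dT, protocol.t_end, 0.0))
    if curvature_feedback:
        split = []
        for ta, tb, th in phases:
            edges = np.append(np.arange(ta, tb, feedback_dt), tb)
            split += [(a, b, th) for a, b in zip(edges[:-1], edges[1:]) if b > a]
        phases = split

    if t_eval is None:
        t_eval = np.unique(np.concatenate(
            [_phase_grid(ta, tb, tau_aux, n_out // len(phases))
             for ta, tb, _ in phases]))
    t_eval = np.asarray(t_eval, dtype=float)

    ts, pes, dts_, u0s, u1s = [], [], [], [], []
    delta = np.zeros(transport.N)
    S = part0.S
    tip_scale = organ.L_gz / (organ.R_organ * organ.tau_g)
    for (ta, tb, th) in phases:
        if curvature_feedback and ts:
            # effective inclination reduced by the accumulated tip angle
            tip_now = math.degrees(
                tip_scale * np.trapezoid(dts_, ts)) if len(ts) > 1 else 0.0
            th = float(np.clip(th - math.copysign(tip_now, th), -180.0, 180.0))
        part = pile_cross_section(geom, th)
        membrane.reassign(part)

        def peclet(tloc: float) -> float:
            return A * membrane.asymmetry_at(tloc) / S

        def rhs(tloc, d):
            pe = peclet(tloc)
            return T0 @ d + pe * (b1 + T1 @ d)

        def jac(tloc, d):
            return T0 + peclet(tloc) * T1

        sel = (t_eval >= ta) & (t_eval <= tb)
        t_loc = np.clip(t_eval[sel] - ta, 0.0, tb - ta)
        # drop a duplicated phase-start point except in the first phase
        if ts and t_loc.size and t_loc[0] == 0.0:
            t_loc = t_loc[1:]
            sel_times = t_eval[sel][1:]
        else:
            sel_times = t_eval[sel]
        if t_loc.size:
            # BDF is robust on phases resolving the auxin boundary layer;
            # LSODA steps far more efficiently across long quasi-steady
            # stretches
            phase_method = method
            if method == "auto":
                phase_method = "BDF" if (tb - ta) <= 50.0 * tau_aux else "LSODA"
            sol = solve_ivp(
                rhs, (0.0, tb - ta), delta, method=phase_method, jac=jac,
                t_eval=np.unique(np.concatenate([t_loc, [tb - ta]])),
                rtol=rtol, atol=atol,
                # start inside the auxin boundary layer: LSODA's default
                # initial step can overshoot it on very long phases
                first_step=min(tau_aux / 50.0, (tb - ta) / 100.0),
            )
            if not sol.success:  # pragma: no cover
                raise RuntimeError(f"transport integration failed: {sol.message}")
            for k, tl in enumerate(t_loc):
                j = int(np.searchsorted(sol.t, tl))
                d = sol.y[:, j]
                ts.append(ta + tl)
                pes.append(peclet(tl))
                dts_.append(relative_gradient(AuxinField(1.0 + d)))
                u = membrane.u_at(tl)
                L = membrane._lengths
                cls = membrane._classes
                w0 = L[cls == 0].sum()
                w1 = L[cls == 1].sum()
                u0s.append(float((L[cls == 0] @ u[cls == 0]) / w0) if w0 else 0.0)
                u1s.append(float((L[cls == 1] @ u[cls == 1]) / w1) if w1 else 0.0)
            delta = sol.y[:, -1]
        membrane.advance(tb - ta)

    t = np.asarray(ts)
    delta_tilde = np.asarray(dts_)
    # curvature kinematics: dC/dt = delta_tilde / (R_organ tau_g)
    integral = cumulative_trapezoid(delta_tilde, t, initial=0.0)
    curvature = integral / (organ.R_organ * organ.tau_g)
    tip_angle = np.degrees(organ.L_gz * curvature)
    tau1, tau2 = pin_timescales(pin_params, pile_cross_section(geom, protocol.theta_0))
    return Trajectory(
        t=t, u0=np.asarray(u0s), u1=np.asarray(u1s), Pe=np.asarray(pes),
        delta_tilde=delta_tilde, curvature=curvature, tip_angle=tip_angle,
        tau_1=float(tau1), tau_2=float(tau2),
    )


def dose_response(
    delta_T_grid,
    theta: float,
    pin_params: PinParameters,
    A: float = 1.3,
    geom: StatocyteGeometry | None = None,
    transport: TransportParameters | None = None,
    pin_scheme: str = "patch",
    **sim_kw,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximal transient response vs stimulus duration (dose-response law).

    For each duration ``delta_T`` the organ is tilted to ``theta`` for
    ``delta_T`` minutes, returned upright, and the response is the
    maximum of the relative auxin gradient over the whole dynamics:
    proportional to ``delta_T`` for short stimuli and saturating at the
    steady response once ``delta_T >> tau_PIN``.

    Returns (delta_T array, response array).
    """
    if transport is None:
        transport = TransportParameters.from_tau_aux(13.0 / 2000.0)
    tau_aux = 1.0 / (math.pi**2 * transport.D_star)
    dTs = np.atleast_1d(np.asarray(delta_T_grid, dtype=float))
    out = np.empty_like(dTs)
    for i, dT in enumerate(dTs):
        if dT == 0.0:
            out[i] = 0.0
            continue
        t_end = dT + max(60.0 * tau_aux, 1e-3 * dT)
        proto = Protocol(theta_0=theta, delta_T=dT, t_end=t_end)
        traj = simulate(proto, pin_params, A=A, geom=geom, transport=transport,
                        pin_scheme=pin_scheme, **sim_kw)
        out[i] = float(traj.delta_tilde.max())
    return dTs, out
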