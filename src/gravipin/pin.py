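"""PIN carrier trafficking at the statocyte membrane.

PIN auxin-efflux carriers cycle between the cell membrane and an
intracellular pool through endocytosis (rate ``k_off``) and exocytosis
(volumetric rate ``kappa = k_on / W``).  Statolith contact biases both:
membrane regions touched by the statolith pile (class 1) and free
regions (class 0) have their own rate pair.  With a conserved total PIN
count ``N_tot``, the dimensionless membrane concentrations

    u_i = [PIN]_i * S / N_tot          (S = H, one lateral face)

obey

    du_i/dt = -k_off_i * u_i + kappa_i * (1 - sum_b L_b u_b / S),

where the sum runs over all membrane segments that can bind PIN and the
parenthesis is the free-pool fraction.  Two dimensionless groups govern
the behaviour:

* coupling ratio  R = kappa_1 k_off_0 / (kappa_0 k_off_1)
      = steady [PIN]_1 / [PIN]_0 (contacted vs free membrane);
* pool number     P = k_off_1 / kappa_1
      (P >> 1: infinite pool, P << 1: limiting pool — nearly all PIN
      membrane-bound).

Two transient bookkeeping schemes are provided for protocols in which
the inclination (hence the contact partition) switches:

* ``"patch"`` (default): each membrane patch keeps its local PIN
  concentration when its contact class changes, and then relaxes with
  the new class's rates.  Patches are tracked exactly as history
  intervals, so no membrane discretization is needed.  In the
  limiting-pool, equal-``k_off`` case this scheme yields the
  single-exponential memory law ``Pe(t) ∝ 1 - exp(-t/tau_PIN)``.
* ``"pooled"``: the two class concentrations u0, u1 are carried over
  continuously across the switch and the pool absorbs the jump in the
  membrane totals.  Membrane patches that change class instantly adopt
  the concentration of their new class, so the left/right asymmetry
  responds essentially instantaneously; kept for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh as _eigh
from scipy.linalg import expm as _expm

from gravipin.geometry import BindingMode, ContactPartition

__all__ = [
    "PinParameters",
    "PinState",
    "DerivedRegime",
    "pin_rhs",
    "pin_steady_state",
    "pin_timescales",
    "limiting_pool_timescales",
    "derive_regime",
    "MembraneModel",
]


@dataclass(frozen=True)
class PinParameters:
    """Endo/exocytosis rates (1/min) and total PIN count.

    ``kappa_i = k_on_i / W`` is the volumetric exocytosis rate; the
    binding mode says which walls compete for the pool.
    """

    k_off_0: float
    k_off_1: float
    kappa_0: float
    kappa_1: float
    N_tot: float = 1.0
    binding_mode: BindingMode = BindingMode.LATERAL

    def __post_init__(self) -> None:
        for name in ("k_off_0", "k_off_1", "kappa_0", "kappa_1", "N_tot"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "binding_mode", BindingMode(self.binding_mode))

    @classmethod
    def from_reduced(
        cls,
        R: float,
        P: float,
        tau_pin: float,
        N_tot: float = 1.0,
        binding_mode: BindingMode = BindingMode.LATERAL,
    ) -> "PinParameters":
        """Build rates from the reduced triple (R, P, tau_PIN).

        Anchored with equal endocytosis rates k_off_0 = k_off_1 =
        1/tau_PIN (contact bias acts through exocytosis only), so that
        in the limiting pool the slow turnover time is exactly
        ``tau_PIN`` and the fast time satisfies tau_1/tau_PIN -> 0 as
        P -> 0.
        """
        if R <= 0 or P <= 0 or tau_pin <= 0:
            raise ValueError("R, P, tau_pin must be positive")
        k_off = 1.0 / tau_pin
        kappa_1 = k_off / P
        kappa_0 = kappa_1 / R
        return cls(k_off, k_off, kappa_0, kappa_1, N_tot, binding_mode)


@dataclass(frozen=True)
class PinState:
    """Dimensionless two-class membrane state (u0, u1) and free-pool fraction."""

    u0: float
    u1: float
    pool: float


@dataclass(frozen=True)
class DerivedRegime:
    """Dimensionless statolith–PIN coupling ratio R and pool number P."""

    R: float
    P: float


def derive_regime(p: PinParameters) -> DerivedRegime:
    """R = kappa_1 k_off_0 / (kappa_0 k_off_1); P = k_off_1 / kappa_1."""
    return DerivedRegime(
        R=p.kappa_1 * p.k_off_0 / (p.kappa_0 * p.k_off_1),
        P=p.k_off_1 / p.kappa_1,
    )


def _pool_fraction(u0: float, u1: float, part: ContactPartition) -> float:
    return 1.0 - (part.S0 * u0 + part.S1 * u1) / part.S


def pin_rhs(state: PinState, part: ContactPartition, p: PinParameters
            ) -> tuple[float, float]:
    """Time derivatives (du0/dt, du1/dt) of the two-class trafficking ODE."""
    pool = _pool_fraction(state.u0, state.u1, part)
    du0 = -p.k_off_0 * state.u0 + p.kappa_0 * pool
    du1 = -p.k_off_1 * state.u1 + p.kappa_1 * pool
    return du0, du1


def pin_steady_state(p: PinParameters, part: ContactPartition) -> PinState:
    """Closed-form steady state of the trafficking ODE.

    With a_i = kappa_i / k_off_i the fixed point is u_i = a_i * f,
    f = 1 / (1 + (S0 a0 + S1 a1)/S), so u1/u0 = a1/a0 = R always.
    """
    a0 = p.kappa_0 / p.k_off_0
    a1 = p.kappa_1 / p.k_off_1
    f = 1.0 / (1.0 + (part.S0 * a0 + part.S1 * a1) / part.S)
    return PinState(u0=a0 * f, u1=a1 * f, pool=f)


def _jacobian(p: PinParameters, part: ContactPartition) -> np.ndarray:
    S = part.S
    return np.array(
        [
            [-p.k_off_0 - p.kappa_0 * part.S0 / S, -p.kappa_0 * part.S1 / S],
            [-p.kappa_1 * part.S0 / S, -p.k_off_1 - p.kappa_1 * part.S1 / S],
        ]
    )


def pin_timescales(p: PinParameters, part: ContactPartition) -> tuple[float, float]:
    """Relaxation times (tau_1, tau_2), tau_1 <= tau_2, of the linearized system.

    These are the inverse eigen-rates of the 2x2 trafficking Jacobian;
    ``tau_2`` is the slow PIN turnover time tau_PIN that sets the
    gravitropic memory.  Both eigenvalues are real and negative (the
    Jacobian is a sum of a negative diagonal and a rank-one matrix with
    a non-positive spectrum), but a degenerate (zero-discriminant) pair
    is returned as an equal pair.
    """
    J = _jacobian(p, part)
    tr, det = J[0, 0] + J[1, 1], J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = tr * tr - 4.0 * det
    if disc < 0.0:  # numerically degenerate
        disc = 0.0
    root = math.sqrt(disc)
    lam_fast = (tr - root) / 2.0
    lam_slow = (tr + root) / 2.0
    return -1.0 / lam_fast, -1.0 / lam_slow


def limiting_pool_timescales(p: PinParameters, part: ContactPartition
                             ) -> tuple[float, float]:
    """Limiting-pool closed forms for (tau_1, tau_2).

    tau_1 = S / (kappa_0 S0 + kappa_1 S1) and
    tau_2 = (kappa_0 S0 + kappa_1 S1) /
            (k_off_0 kappa_1 S1 + k_off_1 kappa_0 S0);
    valid when S * k_off_i / (kappa_i S_i) << 1.  When the contact bias
    is purely exocytotic (k_off_0 = k_off_1 = k) this gives
    tau_2 = 1/k; when it is purely endocytotic (k_off_0 >> k_off_1,
    equal kappa) the slow time is controlled by the *fastest*
    detachment rate: tau_2 ~= (1 + S0/S1) / k_off_0.
    """
    m = p.kappa_0 * part.S0 + p.kappa_1 * part.S1
    tau1 = part.S / m
    tau2 = m / (p.k_off_0 * p.kappa_1 * part.S1 + p.k_off_1 * p.kappa_0 * part.S0)
    return tau1, tau2


# ---------------------------------------------------------------------------
# Membrane bookkeeping for time-varying contact partitions
# ---------------------------------------------------------------------------

_LATERAL_FACES = ("left", "right")
_ALL_FACES = ("left", "right", "basal", "apical")


class MembraneModel:
    """Piecewise-linear propagation of membrane PIN through a protocol.

    The membrane is a set of compartments, each with a length ``L_b``, a
    current contact class and a uniform concentration ``u_b``.  Between
    inclination switches the dynamics are the affine-linear system

        du/dt = M u + q,   M = -diag(k_off_c) - kappa_c L^T / S,
        q = kappa_c,

    which is propagated *exactly* through its eigendecomposition (the
    system is stiff for small pool numbers; exact propagation sidesteps
    that entirely).  At a switch the scheme decides what happens to
    patches whose class changed (see module docstring).
    """

    def __init__(self, p: PinParameters, part: ContactPartition,
                 scheme: str = "patch") -> None:
        if scheme not in ("patch", "pooled"):
            raise ValueError("scheme must be 'patch' or 'pooled'")
        self.p = p
        self.scheme = scheme
        self.S = part.S
        self._part = part
        self.faces = (
            _LATERAL_FACES if p.binding_mode is BindingMode.LATERAL else _ALL_FACES
        )
        self._face_len = {"left": part.H, "right": part.H,
                          "basal": part.W, "apical": part.W}
        ss = pin_steady_state(p, part)
        if scheme == "pooled":
            # two compartments: class 0 and class 1
            self._lengths = np.array([part.S0, part.S1])
            self._classes = np.array([0, 1])
            self._u = np.array([ss.u0, ss.u1])
        else:
            self._segments = {f: [(0.0, self._face_len[f])] for f in self.faces}
            self._seg_u = {f: [0.0] for f in self.faces}
            self._set_classes(part, initial=(ss.u0, ss.u1))
        self._decompose()

    # -- patch-scheme segment bookkeeping ----------------------------------
    def _set_classes(self, part: ContactPartition,
                     initial: tuple[float, float] | None = None) -> None:
        """Split segments at the new coverage boundaries and reclassify."""
        for f in self.faces:
            lo, hi = part.intervals[f]
            segs, us = [], []
            for (a, b), u in zip(self._segments[f], self._seg_u[f]):
                cuts = sorted({a, b, min(max(lo, a), b), min(max(hi, a), b)})
                for x0, x1 in zip(cuts[:-1], cuts[1:]):
                    if x1 - x0 > 1e-12:
                        segs.append((x0, x1))
                        us.append(u)
            self._segments[f] = segs
            self._seg_u[f] = us
        lengths, classes, u, faces_of = [], [], [], []
        for f in self.faces:
            lo, hi = part.intervals[f]
            for (a, b), uu in zip(self._segments[f], self._seg_u[f]):
                mid = 0.5 * (a + b)
                covered = lo - 1e-12 <= mid <= hi + 1e-12 and hi - lo > 1e-12
                lengths.append(b - a)
                classes.append(1 if covered else 0)
                faces_of.append(f)
                u.append(uu)
        self._lengths = np.array(lengths)
        self._classes = np.array(classes)
        self._faces_of = faces_of
        if initial is not None:
            u0, u1 = initial
            self._u = np.where(self._classes == 1, u1, u0).astype(float)
        else:
            self._u = np.array(u)

    def _writeback(self) -> None:
        if self.scheme == "pooled":
            return
        k = 0
        for f in self.faces:
            n = len(self._segments[f])
            self._seg_u[f] = list(self._u[k:k + n])
            k += n

    # -- linear algebra -----------------------------------------------------
    def _decompose(self) -> None:
        p = self.p
        koff = np.where(self._classes == 1, p.k_off_1, p.k_off_0)
        kap = np.where(self._classes == 1, p.kappa_1, p.kappa_0)
        M = -np.diag(koff) - np.outer(kap, self._lengths) / self.S
        self._M = M
        self._u_star = np.linalg.solve(M, -kap)
        # M is similar to a symmetric matrix via the diagonal scaling
        # a = sqrt(kappa/L):  diag(1/a) M diag(a) = -diag(koff) - q q^T/S
        # with q = sqrt(kappa L).  eigh on that form gives an orthogonal
        # (perfectly conditioned) eigenbasis even with repeated rates.
        self._spectral = bool(np.all(self._lengths > 0))
        if self._spectral:
            a = np.sqrt(kap / self._lengths)
            q = np.sqrt(kap * self._lengths)
            Ms = -np.diag(koff) - np.outer(q, q) / self.S
            lam, V = _eigh(Ms)
            self._w = lam
            self._V = V
            self._a = a
            self._c0 = V.T @ ((self._u - self._u_star) / a)
        self._memo_t = None
        self._memo_u = None

    def reassign(self, part: ContactPartition) -> None:
        """Apply a new contact partition (inclination switch) at the
        current state, then rebuild the propagator."""
        if self.scheme == "pooled":
            self._lengths = np.array([part.S0, part.S1])
        else:
            self._writeback()
            self._set_classes(part)
        self._part = part
        self._decompose()

    def advance(self, dt: float) -> None:
        """Move the stored state forward by ``dt`` minutes (exactly)."""
        self._u = self.u_at(dt)
        if self._spectral:
            self._c0 = self._V.T @ ((self._u - self._u_star) / self._a)
        self._memo_t = None

    def u_at(self, dt: float) -> np.ndarray:
        """Compartment concentrations ``dt`` minutes after the last switch."""
        if self._spectral:
            return self._u_star + self._a * (
                self._V @ (np.exp(self._w * dt) * self._c0))
        if self._memo_t == dt:
            return self._memo_u
        u = self._u_star + _expm(self._M * dt) @ (self._u - self._u_star)
        self._memo_t, self._memo_u = dt, u
        return u

    def _asym_vector(self) -> np.ndarray:
        if self.scheme == "pooled":
            # (u1 - u0) * (S1_r - S1_l): class concentrations weighted by
            # the lateral coverage asymmetry of the current partition
            d = self._part.S1_r - self._part.S1_l
            return np.array([-d, d])
        sign = np.array([{"right": 1.0, "left": -1.0}.get(f, 0.0)
                         for f in self._faces_of])
        return sign * self._lengths

    def asymmetry_coeffs(self) -> tuple[float, np.ndarray, np.ndarray] | None:
        """Lateral asymmetry as const + sum_j a_j exp(w_j t).

        Returns (steady asymmetry, amplitudes a, rates w) such that
        ``int_right [PIN] - int_left [PIN]`` in u-units equals
        ``const + a . exp(w t)``; ``None`` when the spectral fast path is
        unavailable (use :meth:`asymmetry_at` instead).
        """
        r = self._asym_vector()
        if not self._spectral:
            return None
        return float(r @ self._u_star), ((r * self._a) @ self._V) * self._c0, self._w

    def asymmetry_at(self, dt: float) -> float:
        """Signed lateral membrane asymmetry at time dt after last switch."""
        r = self._asym_vector()
        if self._spectral:
            return float(r @ self._u_star) + float(
                ((r * self._a) @ self._V) @ (np.exp(self._w * dt) * self._c0))
        return float(r @ self.u_at(dt))

    def totals(self) -> float:
        """Membrane-bound total sum_b L_b u_b (conserved + pool*S = S-normalized)."""
        return float(self._lengths @ self._u)

    def pool_fraction_at(self, dt: float) -> float:
        return 1.0 - float(self._lengths @ self.u_at(dt)) / self.S
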