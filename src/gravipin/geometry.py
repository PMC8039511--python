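"""Statolith-pile geometry inside a tilted statocyte.

Statoliths in gravisensing cells behave on long timescales like an
effective liquid: after the cell is inclined, the sedimented pile
re-forms with a *horizontal* free surface.  Which parts of the cell
membrane the pile touches is then a purely geometrical question,
controlled by the inclination angle ``theta``, the cell aspect ratio
``H/W`` and the pile aspect ratio ``H_stato/W``.

The cell cross-section is the rectangle ``[0, W] x [0, H]`` in cell
coordinates (``x`` across the cell, ``y`` along its long axis, basal
wall at ``y = 0``).  With the cell tilted by ``theta`` from the
vertical, the unit gravity vector expressed in the cell frame is
``g = (sin(theta), -cos(theta))``, so the "depth" potential of a point
``p`` is ``phi(p) = g . p``.  The liquid pile occupies the deepest
region ``{p : phi(p) >= lam}``, where the level ``lam`` is fixed by
conservation of the pile cross-section area ``W * H_stato``.

All lengths are measured in units of the statolith diameter ``d``;
"surface areas" are edge lengths (2D geometry, per unit depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Polygon

__all__ = [
    "BindingMode",
    "StatocyteGeometry",
    "ContactPartition",
    "pile_cross_section",
    "contact_asymmetry",
]


class BindingMode(str, Enum):
    """Where PIN carriers may attach: only lateral walls, or all four."""

    LATERAL = "lateral"
    ALL_SIDES = "all_sides"


@dataclass(frozen=True)
class StatocyteGeometry:
    """Cell and statolith-pile dimensions (units of statolith diameter d).

    Parameters
    ----------
    W : cell width.
    H : cell height (long axis).
    H_stato : height of the sedimented pile in the upright cell.
    binding_mode : which walls count toward the PIN-binding surfaces.

    Defaults are the wheat-coleoptile statocyte values used throughout:
    ``H_stato = 4 d``, ``W = 10 d``, ``H = 25 d``.
    """

    W: float = 10.0
    H: float = 25.0
    H_stato: float = 4.0
    binding_mode: BindingMode = BindingMode.LATERAL

    def __post_init__(self) -> None:
        if not (self.W > 0 and self.H > 0):
            raise ValueError("cell dimensions W, H must be positive")
        if not 0 < self.H_stato < self.H:
            raise ValueError("pile height H_stato must satisfy 0 < H_stato < H")
        object.__setattr__(self, "binding_mode", BindingMode(self.binding_mode))

    @property
    def pile_area(self) -> float:
        """Conserved pile cross-section area W * H_stato."""
        return self.W * self.H_stato


# face name -> (start corner, end corner) in cell coordinates; the face
# coordinate s runs from start to end.
def _face_endpoints(W: float, H: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        "left": (np.array([0.0, 0.0]), np.array([0.0, H])),
        "right": (np.array([W, 0.0]), np.array([W, H])),
        "basal": (np.array([0.0, 0.0]), np.array([W, 0.0])),
        "apical": (np.array([0.0, H]), np.array([W, H])),
    }


@dataclass(frozen=True)
class ContactPartition:
    """Per-face statolith-covered lengths and class surfaces at one inclination.

    ``l_left``/``l_right`` are the covered lengths of the lateral faces,
    ``l_basal``/``l_apical`` of the transverse faces.  ``S1`` (``S0``) is
    the total length in contact (not in contact) with statoliths under
    the partition's binding mode; ``S1_l``/``S1_r`` are the lateral
    covered lengths entering the left/right asymmetry.  ``intervals``
    holds the exact covered sub-interval of each face in its own
    coordinate (needed to propagate membrane patches through protocols
    where the coverage moves).
    """

    l_left: float
    l_right: float
    l_basal: float
    l_apical: float
    S1: float
    S0: float
    S1_l: float
    S1_r: float
    binding_mode: BindingMode
    W: float
    H: float
    theta_deg: float
    intervals: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def S(self) -> float:
        """Lateral face length (the cell's lateral 'surface area' S = H)."""
        return self.H


def _covered_interval(phi_a: float, phi_b: float, lam: float, length: float
                      ) -> tuple[float, float]:
    """Covered sub-interval of an edge with linear potential phi(s).

    phi varies linearly from ``phi_a`` at s=0 to ``phi_b`` at s=length;
    the covered set is ``{s : phi(s) >= lam}``, a single interval.
    """
    if phi_a == phi_b:
        return (0.0, length) if phi_a >= lam else (0.0, 0.0)
    s_star = (lam - phi_a) / (phi_b - phi_a) * length
    s_star = min(max(s_star, 0.0), length)
    if phi_b > phi_a:          # deep end at s = length
        return (s_star, length)
    return (0.0, s_star)       # deep end at s = 0


def _halfplane_area(rect: Polygon, g: np.ndarray, lam: float, corners: np.ndarray,
                    ) -> float:
    """Area of rect ∩ {g.p >= lam} via polygon clipping."""
    phis = corners @ g
    if lam <= phis.min():
        return rect.area
    if lam >= phis.max():
        return 0.0
    # Build a large half-plane polygon: line g.p = lam, extended far along
    # the tangent t = (-g_y, g_x) and offset toward +g.
    t = np.array([-g[1], g[0]])
    p0 = g * lam  # a point on the line
    L = 10.0 * (np.abs(corners).max() + 1.0)
    quad = Polygon([p0 - L * t, p0 + L * t, p0 + L * t + L * g, p0 - L * t + L * g])
    return rect.intersection(quad).area


def pile_cross_section(geom: StatocyteGeometry, theta: float) -> ContactPartition:
    """Contact partition of the statocyte membrane at inclination ``theta``.

    Parameters
    ----------
    geom : statocyte geometry.
    theta : inclination in degrees, in [-180, 180].  ``theta = 0`` is the
        upright cell, ``90`` horizontal, ``180`` inverted.  For
        ``0 < theta < 180`` the "right" face (``x = W``) is the lower
        lateral face.  Negative ``theta`` returns the mirror image
        (left and right swapped).

    Returns
    -------
    ContactPartition with covered lengths, class surfaces, and the exact
    covered intervals per face.  The covered-region area equals
    ``W * H_stato`` to root-finder tolerance, for every ``theta``.
    """
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    if not -180.0 - 1e-9 <= theta <= 180.0 + 1e-9:
        raise ValueError("theta must lie in [-180, 180] degrees")

    if theta < 0.0:
        part = pile_cross_section(geom, -theta)
        iv = part.intervals
        W = geom.W
        mirror = {
            "left": iv["right"],
            "right": iv["left"],
            "basal": (W - iv["basal"][1], W - iv["basal"][0]),
            "apical": (W - iv["apical"][1], W - iv["apical"][0]),
        }
        return ContactPartition(
            l_left=part.l_right, l_right=part.l_left,
            l_basal=part.l_basal, l_apical=part.l_apical,
            S1=part.S1, S0=part.S0,
            S1_l=part.S1_r, S1_r=part.S1_l,
            binding_mode=part.binding_mode, W=part.W, H=part.H,
            theta_deg=theta, intervals=mirror,
        )

    W, H = geom.W, geom.H
    th = math.radians(theta)
    g = np.array([math.sin(th), -math.cos(th)])
    corners = np.array([[0.0, 0.0], [W, 0.0], [W, H], [0.0, H]])
    rect = Polygon(corners)
    target = geom.pile_area

    phis = corners @ g
    lo, hi = phis.min(), phis.max()
    # area(lam) decreases monotonically from W*H at lam=lo to 0 at lam=hi
    lam = brentq(
        lambda lam_: _halfplane_area(rect, g, lam_, corners) - target,
        lo, hi, xtol=1e-12 * max(W, H), rtol=8.881784197001252e-16,
    )

    ends = _face_endpoints(W, H)
    intervals = {}
    lengths = {}
    for name, (a, b) in ends.items():
        length = float(np.linalg.norm(b - a))
        s0, s1 = _covered_interval(float(a @ g), float(b @ g), lam, length)
        intervals[name] = (s0, s1)
        lengths[name] = s1 - s0

    l_left, l_right = lengths["left"], lengths["right"]
    l_basal, l_apical = lengths["basal"], lengths["apical"]
    if geom.binding_mode is BindingMode.LATERAL:
        S1 = l_left + l_right
        S0 = 2.0 * H - S1
    else:
        S1 = l_left + l_right + l_basal + l_apical
        S0 = 2.0 * H + 2.0 * W - S1
    return ContactPartition(
        l_left=l_left, l_right=l_right, l_basal=l_basal, l_apical=l_apical,
        S1=S1, S0=S0, S1_l=l_left, S1_r=l_right,
        binding_mode=geom.binding_mode, W=W, H=H,
        theta_deg=theta, intervals=intervals,
    )


def contact_asymmetry(part: ContactPartition) -> float:
    """Left/right contact asymmetry ``S1_r - S1_l`` (units of d).

    This is the geometric factor that biases PIN recruitment toward the
    lower side of the cell; it is zero for the upright (0°) and fully
    inverted (180°) cell and antisymmetric in theta.
    """
    return part.S1_r - part.S1_l
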