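"""The steady gravitropic response: a 'modified sine-law'.

Computes the steady relative auxin gradient delta_steady(theta) for a
wheat-coleoptile-like statocyte (W=10d, H=25d, pile height 4d) with
statolith-PIN coupling R=25 and conductance ratio A=1.3 — the
limiting-pool, lateral-binding regime in which the curve is concave and
sine-like.  The law is piecewise: its two branch boundaries are the
angles at which statoliths completely leave the upper wall and
completely cover the lower wall.
"""

import math

import numpy as np

from gravipin import StatocyteGeometry, steady_response

geom = StatocyteGeometry()
R, A = 25.0, 1.3

th_1 = math.degrees(math.atan(2 * geom.H_stato / geom.W))
th_2 = math.degrees(math.atan(geom.H**2 / (2 * geom.H_stato * geom.W)))
print(f"branch boundaries: {th_1:.2f} deg (upper wall vacated), "
      f"{th_2:.2f} deg (lower wall covered)")

print(f"{'theta (deg)':>12s} {'delta_steady':>13s}")
for theta in np.arange(0.0, 181.0, 15.0):
    print(f"{theta:12.0f} {steady_response(theta, R, A, geom):13.4f}")

peak = steady_response(90.0, R, A, geom)
print(f"\npeak response at 90 deg: {peak:.3f} = (A/2)(R-1)/(R+1); "
      "the response vanishes for the upright (0 deg) and inverted "
      "(180 deg) plant, and equals half the steady Peclet number.")
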