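"""Reference wing geometry.

The package models odonate (dragonfly) wings as a closed outline plus a small
set of internal vein landmarks.  Every simulated specimen is a smooth
deformation of the single reference geometry defined here, which follows the
field's standard 38-point sampling scheme for libellulid wings:

* 6 outline *anchor* landmarks (points 1, 6, 13, 20, 25, 31 in 1-based
  numbering) subdividing the periphery into five sampling zones,
* 25 outline *semilandmarks* spaced at equal arc length within the zones
  (4, 6, 6, 4 and 5 per zone respectively),
* 7 *internal* landmarks at origins/intersections of major veins
  (points 32-38).

Coordinates are dimensionless, wing length 1 along +x, anterior margin at
+y.  The forewing is narrower (width 0.28) than the hindwing (width 0.405),
matching the 200x56 / 200x81 pixel frame aspect ratios used for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: anchor landmark positions in the 38-point scheme (0-based indices of the
#: 1-based points 1, 6, 13, 20, 25, 31)
ANCHOR_INDICES = (0, 5, 12, 19, 24, 30)

#: semilandmarks per outline zone (zones 1..5); totals 25
ZONE_SEMILANDMARK_COUNTS = (4, 6, 6, 4, 5)

N_BOUNDARY = 31      # 6 anchors + 25 semilandmarks
N_INTERNAL = 7       # internal vein landmarks, indices 31..37
N_POINTS = 38

# outline parameter (theta) of the six anchors; theta ~ 0 is the anterior
# wing attachment, theta = pi the apex, theta in (pi, 2*pi) the posterior
# margin back toward the attachment.  The parameter domain stops short of the
# singular root point on either side (theta in [ROOT_THETA, 2*pi - ROOT_THETA]);
# the outline is closed by a short straight attachment (root) edge.
ROOT_THETA = 0.25
_ANCHOR_THETA = (ROOT_THETA, 1.7, 2.9, 3.8, 4.8, 2 * np.pi - ROOT_THETA)

# vein graph: edges between point indices (0-based) used for rendering
VEIN_EDGES = (
    (0, 31), (31, 32), (32, 33), (33, 34), (34, 12),
    (5, 32), (33, 19), (31, 35), (35, 36), (36, 24),
    (36, 37), (37, 28), (35, 2),
)


def _outline_xy(theta: np.ndarray, half_width: float, anal_amp: float,
                anal_theta: float) -> np.ndarray:
    """Analytic reference outline: a stretched ellipse with a posterior
    proximal bulge (the anal 'corner')."""
    x = 0.5 - 0.5 * np.cos(theta)
    bulge = 1.0 + anal_amp * np.exp(-((theta - anal_theta) ** 2) / (2 * 0.08))
    y = half_width * np.sin(theta) * bulge
    return np.column_stack([x, y])


_WING_SHAPES = {
    "forewing": dict(half_width=0.14, anal_amp=0.25, anal_theta=2 * np.pi - 0.9),
    "hindwing": dict(half_width=0.2025, anal_amp=0.55, anal_theta=2 * np.pi - 1.1),
}

# internal vein landmarks (points 32-38): nodus vertex, R3 bifurcation,
# distal IR3, arculus, cubitus fork, anal vein vertex, CuP terminus
_INTERNAL_XY = {
    "forewing": np.array([
        [0.55, 0.045], [0.68, 0.030], [0.85, 0.018],
        [0.22, 0.020], [0.30, -0.045], [0.14, -0.055], [0.40, -0.020],
    ]),
    "hindwing": np.array([
        [0.55, 0.060], [0.68, 0.040], [0.85, 0.022],
        [0.22, 0.025], [0.30, -0.070], [0.14, -0.095], [0.40, -0.030],
    ]),
}

#: image frames, (width, height) in pixels
FRAME_FOREWING = (200, 56)
FRAME_HINDWING = (200, 81)


@dataclass(frozen=True)
class WingTemplate:
    """Reference geometry for one wing type."""

    wing_type: str
    base_config: np.ndarray          # (38, 2) reference point positions
    boundary_theta: np.ndarray       # (31,) outline parameter per boundary point
    dense_theta: np.ndarray          # (M,) dense outline parameter grid
    dense_boundary: np.ndarray       # (M, 2) dense reference outline
    roles: np.ndarray = field(repr=False, default=None)   # 'landmark'/'semilandmark'
    zones: np.ndarray = field(repr=False, default=None)   # 0 for landmarks, 1..5


def outline_points(wing_type: str, theta: np.ndarray) -> np.ndarray:
    """Evaluate the reference outline of ``wing_type`` at parameter values
    ``theta`` (radians, 0 = anterior attachment, pi = apex)."""
    return _outline_xy(np.asarray(theta, dtype=float), **_WING_SHAPES[wing_type])


def _arc_positions(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@lru_cache(maxsize=None)
def wing_template(wing_type: str = "forewing", n_dense: int = 1440) -> WingTemplate:
    """Build (and cache) the reference template for ``wing_type``.

    Semilandmark outline parameters are chosen so the reference points sit at
    equal arc-length spacing between consecutive anchors, mirroring how the
    digitizing protocol places them on real outlines.
    """
    if wing_type not in _WING_SHAPES:
        raise ValueError(f"unknown wing type {wing_type!r}")
    shape = _WING_SHAPES[wing_type]

    dense_theta = np.linspace(_ANCHOR_THETA[0], _ANCHOR_THETA[-1], n_dense)
    dense = _outline_xy(dense_theta, **shape)
    # close with the straight root (attachment) edge
    root = np.linspace(dense[-1], dense[0], 8)[1:-1]
    dense = np.vstack([dense, root])

    boundary_theta = np.empty(N_BOUNDARY)
    idx = 0
    for zone, m in enumerate(ZONE_SEMILANDMARK_COUNTS):
        t0, t1 = _ANCHOR_THETA[zone], _ANCHOR_THETA[zone + 1]
        boundary_theta[idx] = t0
        # equal arc length within the zone: resample the analytic curve
        tt = np.linspace(t0, t1, 512)
        pts = _outline_xy(tt, **shape)
        arc = _arc_positions(pts)
        targets = np.linspace(0, arc[-1], m + 2)[1:-1]
        boundary_theta[idx + 1: idx + 1 + m] = np.interp(targets, arc, tt)
        idx += m + 1
    boundary_theta[-1] = _ANCHOR_THETA[-1]

    boundary = _outline_xy(boundary_theta, **shape)
    config = np.vstack([boundary, _INTERNAL_XY[wing_type]])

    roles = np.array(
        ["landmark" if i in ANCHOR_INDICES or i >= N_BOUNDARY else "semilandmark"
         for i in range(N_POINTS)]
    )
    zones = np.zeros(N_POINTS, dtype=int)
    idx = 0
    for zone, m in enumerate(ZONE_SEMILANDMARK_COUNTS):
        zones[idx + 1: idx + 1 + m] = zone + 1
        idx += m + 1

    return WingTemplate(wing_type=wing_type, base_config=config,
                        boundary_theta=boundary_theta, dense_theta=dense_theta,
                        dense_boundary=dense, roles=roles, zones=zones)


def _template_displacement_field(wing_type: str) -> np.ndarray:
    """The fixed habitat deformation template (38 x 2), unit max magnitude.

    Encodes, for the open-landscape direction: outboard (anterior, +y)
    migration of costal points peaking between nodus and apex with a
    subordinate posterior turn near the apex; inboard-anterior migration of
    the posterior-margin points peaking near the R3 terminus; and a reduction
    of the anal-corner prominence (inboard shift of the anal-area points).
    Forested-landscape specimens receive the negated field, which widens the
    wing and sharpens the anal corner.
    """
    d = np.zeros((N_POINTS, 2))
    # costal points 0..12 (zones 1-2): outboard, peak mid zone 2
    for i in range(13):
        d[i, 1] = np.sin(np.pi * i / 12.0)
    # apex vicinity: subordinate posterior (distal, +x then -y) component
    for i in (11, 12, 13):
        d[i, 0] += 0.25
        d[i, 1] -= 0.15
    # posterior margin 13..23 (zones 3-4): inboard (+y, toward midline) and
    # anterior-ward (-x), peak near R3 terminus (index 19)
    for i in range(13, 24):
        s = np.sin(np.pi * (i - 13) / 10.0)
        d[i, 1] += 0.85 * s
        d[i, 0] -= 0.25 * s
    # anal area 24..30 (zone 5): corner reduction (inboard +y)
    for i in range(24, 31):
        d[i, 1] += 0.9 * np.sin(np.pi * (i - 24) / 6.0)
    # internal landmarks follow their outline neighbourhood, attenuated
    d[31] = (0.0, 0.35)    # nodus vertex tracks costal shift
    d[32] = (0.05, 0.3)    # R3 bifurcation
    d[33] = (0.2, 0.1)     # distal IR3, contrary subordinate anterior turn
    d[34] = (0.0, 0.1)
    d[35] = (-0.05, 0.25)
    d[36] = (-0.05, 0.3)
    d[37] = (0.0, 0.2)
    d /= np.linalg.norm(d, axis=1).max()
    return d


#: fixed 'narrowing + anal-corner' habitat deformation template
NARROWING_TEMPLATE = _template_displacement_field("forewing")
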