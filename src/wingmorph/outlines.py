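"""Extended eigenshape outline sampling.

The wing periphery is split into five zones by six anchor landmarks.  Each
zone is represented by equally spaced (arc length) semilandmarks, with the
*sample* deciding how many are needed: the per-zone count is the smallest m
for which every specimen's zone outline is reproduced to better than a 95%
accuracy threshold.  Accuracy is the canonical eigenshape perimeter ratio —
the length of the m+1-point equally spaced polyline divided by the length of
the fully digitized zone boundary — which is scale- and rotation-invariant
and converges to 1 as m grows.

Semilandmarks are interpolated linearly along the digitized boundary and are
not slid afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration
from .template import ANCHOR_INDICES, N_BOUNDARY, ZONE_SEMILANDMARK_COUNTS

N_ZONES = 5


class UndefinedAccuracyError(ValueError):
    """Raised for zero-length zone boundaries."""


@dataclass
class OutlineTrace:
    """A digitized closed outline with the positions of the six zone-bounding
    anchor landmarks.  ``boundary`` stores each vertex once (closure implied);
    anchors must be strictly ordered along the boundary."""

    boundary: np.ndarray            # (M, 2) ordered vertices
    anchor_indices: np.ndarray      # (6,) indices into boundary
    metadata: dict | None = None

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.anchor_indices = np.asarray(self.anchor_indices, dtype=int)
        if len(self.anchor_indices) != 6:
            raise ValueError("six zone-bounding anchors are required")
        if np.any(np.diff(self.anchor_indices) <= 0):
            raise ValueError("anchors must be strictly ordered along the boundary")
        if self.anchor_indices[-1] >= len(self.boundary):
            raise IndexError("anchor index outside boundary")
        for z in range(N_ZONES):
            if self.anchor_indices[z + 1] - self.anchor_indices[z] < 2:
                raise ValueError(f"zone {z + 1} has fewer than 3 boundary points")

    def zone_points(self, zone: int) -> np.ndarray:
        """Digitized vertices of one zone (1-based), anchors inclusive."""
        i0, i1 = self.anchor_indices[zone - 1], self.anchor_indices[zone]
        return self.boundary[i0:i1 + 1]


@dataclass
class ZoneSamplingPlan:
    """Per-zone semilandmark counts plus the accuracy bookkeeping that
    justified them."""

    counts: list[int]
    threshold: float
    achieved: np.ndarray            # (n_specimens, 5) accuracy at chosen counts
    binding_specimen: list[int]     # worst specimen per zone

    @property
    def total_semilandmarks(self) -> int:
        return int(sum(self.counts))


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _equal_arc_sample(points: np.ndarray, n: int) -> np.ndarray:
    """n points at equal arc-length spacing along a polyline, endpoints
    included."""
    arc = _arc_lengths(points)
    targets = np.linspace(0.0, arc[-1], n)
    x = np.interp(targets, arc, points[:, 0])
    y = np.interp(targets, arc, points[:, 1])
    return np.column_stack([x, y])


def zone_accuracy(zone_boundary: np.ndarray, m: int) -> float:
    """Perimeter-ratio accuracy of representing a zone by m semilandmark
    intervals (an m+1-point equally spaced polyline)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    zone_boundary = np.asarray(zone_boundary, dtype=float)
    if len(zone_boundary) < 2:
        raise ValueError("zone must have at least 2 points")
    full = _arc_lengths(zone_boundary)[-1]
    if full <= 0:
        raise UndefinedAccuracyError("zero-length zone boundary")
    sub = _equal_arc_sample(zone_boundary, m + 1)
    return float(_arc_lengths(sub)[-1] / full)


def select_semilandmark_counts(outlines: list[OutlineTrace],
                               threshold: float = 0.95,
                               max_m: int = 200) -> ZoneSamplingPlan:
    """Smallest per-zone semilandmark count achieving ``> threshold``
    accuracy for *every* specimen; records the binding (worst) specimen."""
    if not outlines:
        raise ValueError("empty sample")
    counts: list[int] = []
    binding: list[int] = []
    achieved = np.empty((len(outlines), N_ZONES))
    for zone in range(1, N_ZONES + 1):
        for m in range(1, max_m + 1):
            acc = np.array([zone_accuracy(o.zone_points(zone), m) for o in outlines])
            if acc.min() > threshold:
                counts.append(m)
                binding.append(int(acc.argmin()))
                achieved[:, zone - 1] = acc
                break
        else:
            raise RuntimeError(
                f"zone {zone}: threshold {threshold} not reached by m <= {max_m}")
    return ZoneSamplingPlan(counts=counts, threshold=threshold,
                            achieved=achieved, binding_specimen=binding)


def interpolate_semilandmarks(outline: OutlineTrace,
                              plan: ZoneSamplingPlan | list[int],
                              internal_points: np.ndarray | None = None,
                              wing_type: str = "forewing") -> LandmarkConfiguration:
    """Place the planned number of equally spaced semilandmarks in each zone.

    Anchors are preserved exactly.  With the default 5-zone plan totalling 25
    semilandmarks, 6 anchors and 7 internal vein landmarks, the configuration
    has the standard 38 points: boundary points first (anchors interleaved
    with their zone's semilandmarks, in boundary order), internal landmarks
    last.
    """
    counts = plan.counts if isinstance(plan, ZoneSamplingPlan) else list(plan)
    if any(c < 1 for c in counts):
        raise ValueError("plan counts must be positive")
    pts: list[np.ndarray] = []
    roles: list[str] = []
    zones: list[int] = []
    for zone in range(1, N_ZONES + 1):
        zp = outline.zone_points(zone)
        sampled = _equal_arc_sample(zp, counts[zone - 1] + 2)
        pts.append(sampled[:-1])          # anchor + semis; next zone adds its anchor
        roles += ["landmark"] + ["semilandmark"] * counts[zone - 1]
        zones += [0] + [zone] * counts[zone - 1]
    pts.append(outline.boundary[outline.anchor_indices[-1]][None, :])
    roles.append("landmark")
    zones.append(0)
    coords = np.vstack(pts)
    if internal_points is not None:
        internal_points = np.asarray(internal_points, dtype=float)
        coords = np.vstack([coords, internal_points])
        roles += ["landmark"] * len(internal_points)
        zones += [0] * len(internal_points)
    return LandmarkConfiguration(coords=coords, roles=np.array(roles),
                                 zones=np.array(zones), wing_type=wing_type,
                                 metadata=dict(outline.metadata or {}))


def write_trace_csv(path, trace: OutlineTrace) -> None:
    """CSV with one boundary vertex per row (x, y) and an ``anchor`` column
    giving the anchor's 1-based rank (0 for ordinary vertices)."""
    import pandas as pd
    anchor = np.zeros(len(trace.boundary), dtype=int)
    anchor[trace.anchor_indices] = np.arange(1, 7)
    pd.DataFrame({"x": trace.boundary[:, 0], "y": trace.boundary[:, 1],
                  "anchor": anchor}).to_csv(path, index=False)


def read_trace_csv(path) -> OutlineTrace:
    import pandas as pd
    df = pd.read_csv(path)
    anchors = np.flatnonzero(df["anchor"].to_numpy() > 0)
    order = np.argsort(df["anchor"].to_numpy()[anchors])
    return OutlineTrace(boundary=df[["x", "y"]].to_numpy(),
                        anchor_indices=anchors[order])


def default_plan() -> list[int]:
    """The package's reference per-zone counts (totals 25 semilandmarks)."""
    return list(ZONE_SEMILANDMARK_COUNTS)
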