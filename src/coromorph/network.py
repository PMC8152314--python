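"""Domain model for traced coronary resistance-artery networks.

A network is a rooted tree of vessel segments. Each segment carries an
ordered polyline of centerline points (proximal to distal) with outer and
inner (lumen) diameters measured at every point. The tree is rooted at the
orifice of the left anterior descending (LAD) coronary artery; after
loading, coordinates are translated so the orifice sits at the origin, the
X axis points from orifice toward the apex, and positive Y points toward
the left ventricle. All lengths are micrometres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import StructuralError, ValidationError

log = logging.getLogger(__name__)

#: default preparation cutoff: vessels were traced down to ~80 um outer diameter
DIAMETER_CUTOFF_UM = 80.0

#: a child's first point must lie within this distance of a parent vertex
ATTACHMENT_TOLERANCE_UM = 5.0


@dataclass(frozen=True)
class CenterlinePoint:
    """One traced centerline sample: planar position plus both diameters (um)."""

    x: float
    y: float
    outer_d: float
    inner_d: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinates ({self.x}, {self.y})")
        if not (self.outer_d > 0 and math.isfinite(self.outer_d)):
            raise ValidationError(f"outer diameter must be positive, got {self.outer_d}")
        if not (0 < self.inner_d < self.outer_d):
            raise ValidationError(
                f"inner diameter must satisfy 0 < inner < outer, got "
                f"inner={self.inner_d}, outer={self.outer_d}"
            )

    def translated(self, dx: float, dy: float) -> "CenterlinePoint":
        return CenterlinePoint(self.x + dx, self.y + dy, self.outer_d, self.inner_d)


@dataclass(frozen=True)
class AxisConvention:
    """Orthonormal frame of the collage: X orifice->apex, Y toward the LV."""

    x_axis: tuple[float, float] = (1.0, 0.0)
    y_positive: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        xa, ya = np.asarray(self.x_axis, float), np.asarray(self.y_positive, float)
        if not (
            math.isclose(float(xa @ xa), 1.0, abs_tol=1e-9)
            and math.isclose(float(ya @ ya), 1.0, abs_tol=1e-9)
            and math.isclose(float(xa @ ya), 0.0, abs_tol=1e-9)
        ):
            raise ValidationError("axis convention must be an orthonormal pair")


@dataclass
class VesselSegment:
    """A numbered vessel segment: a polyline of >= 2 distinct centerline points."""

    segment_id: str
    parent_id: Optional[str]
    points: list[CenterlinePoint]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValidationError(
                f"segment {self.segment_id!r} needs >= 2 centerline points"
            )
        xy = self.coords()
        step = np.hypot(*np.diff(xy, axis=0).T)
        if np.any(step == 0.0):
            raise ValidationError(
                f"segment {self.segment_id!r} has coincident consecutive points"
            )

    # -- geometry ---------------------------------------------------------

    def coords(self) -> np.ndarray:
        """(n, 2) array of centerline coordinates."""
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    def cumulative_arc(self) -> np.ndarray:
        """Arc position of each vertex from the proximal end, starting at 0."""
        xy = self.coords()
        seg = np.hypot(*np.diff(xy, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(seg)])


def arc_length(seg: VesselSegment) -> float:
    """Total centerline length of a segment (um)."""
    return float(seg.cumulative_arc()[-1])


def point_at(seg: VesselSegment, s: float | np.ndarray) -> np.ndarray:
    """Interpolated centerline position(s) at arc position ``s`` (um)."""
    cum = seg.cumulative_arc()
    xy = seg.coords()
    x = np.interp(s, cum, xy[:, 0])
    y = np.interp(s, cum, xy[:, 1])
    return np.stack([x, y], axis=-1)


def diameters_at(seg: VesselSegment, s: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolated (outer_d, inner_d) at arc position ``s``."""
    cum = seg.cumulative_arc()
    outer = np.interp(s, cum, [p.outer_d for p in seg.points])
    inner = np.interp(s, cum, [p.inner_d for p in seg.points])
    return outer, inner


def direction_at(seg: VesselSegment, s: float, window: float) -> np.ndarray:
    """Unit secant of the centerline over ``[s - window/2, s + window/2]``.

    The span is clipped to the segment; the vector points distally. Raises
    :class:`ValidationError` for a degenerate (zero-length) span.
    """
    if window <= 0:
        raise ValidationError(f"window must be positive, got {window}")
    total = arc_length(seg)
    s0 = max(0.0, s - window / 2.0)
    s1 = min(total, s + window / 2.0)
    if s1 - s0 <= 0:
        raise ValidationError(
            f"degenerate direction window at s={s} on segment {seg.segment_id!r}"
        )
    p0, p1 = point_at(seg, s0), point_at(seg, s1)
    v = p1 - p0
    n = float(np.hypot(*v))
    if n == 0.0:
        raise ValidationError(
            f"centerline doubles back exactly over [{s0}, {s1}] on segment "
            f"{seg.segment_id!r}; direction undefined"
        )
    return v / n


@dataclass(eq=False)   # equality is structural: segments only, not metadata
class CoronaryNetwork:
    """Rooted tree of vessel segments with the orifice at the origin."""

    segments: dict[str, VesselSegment]
    metadata: dict = field(default_factory=dict)
    axes: AxisConvention = field(default_factory=AxisConvention)

    # -- structure --------------------------------------------------------

    @property
    def root(self) -> VesselSegment:
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root segment, found {len(roots)}")
        return roots[0]

    @property
    def orifice(self) -> CenterlinePoint:
        return self.root.points[0]

    def children_of(self, segment_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.parent_id == segment_id]

    def traverse(self) -> Iterator[VesselSegment]:
        """Depth-first traversal from the root."""
        stack = [self.root]
        while stack:
            seg = stack.pop()
            yield seg
            stack.extend(reversed(self.children_of(seg.segment_id)))

    # -- attachment and flow distance -------------------------------------

    def attachment_arc(self, child: VesselSegment,
                       tolerance: float = ATTACHMENT_TOLERANCE_UM) -> float:
        """Arc position on the parent where ``child`` attaches.

        The nearest parent vertex to the child's first point defines the
        attachment; it must lie within ``tolerance`` um (manual tracing noise).
        """
        if child.parent_id is None:
            raise StructuralError(f"segment {child.segment_id!r} has no parent")
        parent = self.segments[child.parent_id]
        xy = parent.coords()
        p0 = np.array([child.points[0].x, child.points[0].y])
        d = np.hypot(*(xy - p0).T)
        k = int(np.argmin(d))
        if d[k] > tolerance:
            raise StructuralError(
                f"segment {child.segment_id!r} starts {d[k]:.1f} um from its "
                f"parent {parent.segment_id!r} (tolerance {tolerance} um)"
            )
        return float(parent.cumulative_arc()[k])

    def flow_offsets(self) -> dict[str, float]:
        """Flow distance from the orifice to each segment's proximal end (um)."""
        offsets: dict[str, float] = {self.root.segment_id: 0.0}
        stack = [self.root]
        while stack:
            seg = stack.pop()
            for child in self.children_of(seg.segment_id):
                offsets[child.segment_id] = (
                    offsets[seg.segment_id] + self.attachment_arc(child)
                )
                stack.append(child)
        return offsets

    # -- validation --------------------------------------------------------

    def validate(self, diameter_cutoff: Optional[float] = DIAMETER_CUTOFF_UM,
                 attach_tolerance: float = ATTACHMENT_TOLERANCE_UM,
                 origin_tolerance: float = 1e-6) -> "CoronaryNetwork":
        """Check every network invariant; return self on success."""
        if not self.segments:
            raise ValidationError("network has no segments")
        root = self.root  # raises if not exactly one
        ids = set(self.segments)
        for seg in self.segments.values():
            if seg.parent_id is not None and seg.parent_id not in ids:
                raise StructuralError(
                    f"segment {seg.segment_id!r} references missing parent "
                    f"{seg.parent_id!r}"
                )
        # cycle / reachability: walk parent chains
        for seg in self.segments.values():
            seen = set()
            cur: Optional[str] = seg.segment_id
            while cur is not None:
                if cur in seen:
                    raise StructuralError(
                        f"cycle in parent links involving segment {cur!r}"
                    )
                seen.add(cur)
                cur = self.segments[cur].parent_id
        if math.hypot(root.points[0].x, root.points[0].y) > origin_tolerance:
            raise ValidationError(
                "orifice is not at the coordinate origin; networks must be "
                "normalized on load"
            )
        for seg in self.segments.values():
            if seg.parent_id is not None:
                self.attachment_arc(seg, tolerance=attach_tolerance)
            if diameter_cutoff is not None:
                dmin = min(p.outer_d for p in seg.points)
                if dmin < diameter_cutoff:
                    raise ValidationError(
                        f"segment {seg.segment_id!r} falls below the "
                        f"{diameter_cutoff}-um preparation cutoff "
                        f"(min outer diameter {dmin:.1f} um)"
                    )
        return self

    # -- normalization ------------------------------------------------------

    def normalized(self) -> "CoronaryNetwork":
        """Translate all coordinates so the orifice is at (0, 0)."""
        o = self.root.points[0]
        if o.x == 0.0 and o.y == 0.0:
            return self
        dx, dy = -o.x, -o.y
        segs = {
            sid: VesselSegment(
                seg.segment_id, seg.parent_id,
                [p.translated(dx, dy) for p in seg.points],
            )
            for sid, seg in self.segments.items()
        }
        return CoronaryNetwork(segs, dict(self.metadata), self.axes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoronaryNetwork):
            return NotImplemented
        return (
            list(self.segments) == list(other.segments)
            and all(
                a.parent_id == b.parent_id and a.points == b.points
                for a, b in zip(self.segments.values(), other.segments.values())
            )
        )
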