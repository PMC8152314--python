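"""Ring-unit decomposition of a traced network.

The whole network is divided (theoretically) into 50-um-long cylindrical
*ring units*, the atomic elements of the morphometry. Ring ``k`` (1-based)
of a segment spans the arc interval ``[(k-1)*L, k*L]``; its centre is the
centerline point at arc position ``(k - 1/2)*L``. A trailing remainder
shorter than one ring length is discarded. For every ring the outer and
inner radii, wall thickness, planar centre coordinates, axis angle with the
orifice-apex X axis, direct (Euclidean) distance from the orifice and flow
distance along the tree from the orifice are computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import CoronaryNetwork, VesselSegment, arc_length, direction_at
from .errors import ValidationError

log = logging.getLogger(__name__)

RING_LENGTH_UM = 50.0

RING_TABLE_COLUMNS = [
    "segment_id", "ring_index", "outer_r_um", "inner_r_um", "wall_um",
    "x_um", "y_um", "axis_deg", "direct_um", "flow_um",
]


@dataclass(frozen=True)
class RingUnit:
    """One 50-um cylindrical element of the network (lengths in um)."""

    segment_id: str
    index: int                 # 1-based ordinal within the segment
    outer_r: float
    inner_r: float
    wall_thickness: float
    x: float
    y: float
    axis_angle: float          # degrees vs the X axis, folded to [0, 180)
    direct_distance: float     # Euclidean distance orifice -> ring centre
    flow_distance: float       # path length along the tree orifice -> centre

    @property
    def outer_d(self) -> float:
        return 2.0 * self.outer_r

    @property
    def inner_d(self) -> float:
        return 2.0 * self.inner_r


def decompose(net: CoronaryNetwork, ring_length: float = RING_LENGTH_UM) -> list[RingUnit]:
    """Cut every segment into ring units of length ``ring_length``.

    Each segment contributes ``floor(arc_length / ring_length)`` rings laid
    from its proximal end; segments shorter than one ring length contribute
    none (logged). Radii at the ring centre are linear interpolations of the
    traced point diameters.
    """
    if ring_length <= 0:
        raise ValidationError(f"ring_length must be positive, got {ring_length}")
    offsets = net.flow_offsets()
    rings: list[RingUnit] = []
    short = 0
    for seg in net.traverse():
        total = arc_length(seg)
        n = int(math.floor(total / ring_length))
        if n == 0:
            short += 1
            continue
        centres = (np.arange(1, n + 1) - 0.5) * ring_length
        cum = seg.cumulative_arc()
        xy = seg.coords()
        xs = np.interp(centres, cum, xy[:, 0])
        ys = np.interp(centres, cum, xy[:, 1])
        outer = np.interp(centres, cum, [p.outer_d for p in seg.points])
        inner = np.interp(centres, cum, [p.inner_d for p in seg.points])
        base_flow = offsets[seg.segment_id]
        for k in range(n):
            u = direction_at(seg, float(centres[k]), window=ring_length)
            angle = math.degrees(math.atan2(u[1], u[0])) % 180.0
            rings.append(RingUnit(
                segment_id=seg.segment_id,
                index=k + 1,
                outer_r=float(outer[k]) / 2.0,
                inner_r=float(inner[k]) / 2.0,
                wall_thickness=(float(outer[k]) - float(inner[k])) / 2.0,
                x=float(xs[k]),
                y=float(ys[k]),
                axis_angle=angle,
                direct_distance=float(np.hypot(xs[k], ys[k])),
                flow_distance=float(base_flow + centres[k]),
            ))
    if short:
        log.info("%d segments shorter than %.0f um contributed no rings",
                 short, ring_length)
    return rings


def ring_table(rings: Iterable[RingUnit]) -> pd.DataFrame:
    """One row per ring with all ring fields, in stable column order."""
    rows = [
        (r.segment_id, r.index, r.outer_r, r.inner_r, r.wall_thickness,
         r.x, r.y, r.axis_angle, r.direct_distance, r.flow_distance)
        for r in rings
    ]
    return pd.DataFrame(rows, columns=RING_TABLE_COLUMNS)


def rings_from_table(df: pd.DataFrame) -> list[RingUnit]:
    """Inverse of :func:`ring_table` (reads a ring CSV back into objects)."""
    missing = [c for c in RING_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"ring table lacks columns {missing}")
    return [
        RingUnit(str(r.segment_id), int(r.ring_index), float(r.outer_r_um),
                 float(r.inner_r_um), float(r.wall_um), float(r.x_um),
                 float(r.y_um), float(r.axis_deg), float(r.direct_um),
                 float(r.flow_um))
        for r in df.itertuples()
    ]
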