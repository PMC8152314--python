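"""Readers and writers for traced networks.

Two dialects are supported:

* the native *segment table*, a UTF-8 CSV with one row per centerline point
  and columns ``segment_id, parent_id, point_index, x_um, y_um, outer_d_um,
  inner_d_um`` (lossless round-trip format), and
* standard 7-column SWC morphology files (``id type x y z radius parent``),
  import only. SWC stores a single radius per point, interpreted as the
  *outer* radius; the lumen is derived from a configured wall model
  ``wall = a + b * outer_d`` so that ``inner_d = outer_d - 2*(a + b*outer_d)``.
  SWC is a 3-D format, but the analysis is planar (the traced collage is a
  horizontal-plane projection), so z is dropped with a warning when nonzero.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError
from .network import CenterlinePoint, CoronaryNetwork, VesselSegment

log = logging.getLogger(__name__)

SEGMENT_TABLE_COLUMNS = [
    "segment_id", "parent_id", "point_index", "x_um", "y_um",
    "outer_d_um", "inner_d_um",
]

#: lumen floor applied when the SWC wall model would close the lumen entirely
_INNER_FLOOR_FRACTION = 0.05


def read_network(path: str | Path, format: str = "segment_table",
                 wall_model: Optional[tuple[float, float]] = None,
                 metadata: Optional[dict] = None,
                 diameter_cutoff: Optional[float] = None) -> CoronaryNetwork:
    """Read a traced network, normalize it to the orifice, and validate it.

    Parameters
    ----------
    path
        Input file.
    format
        ``"segment_table"`` (native CSV) or ``"swc"``.
    wall_model
        ``(a, b)`` of the wall-thickness law ``w = a + b * outer_d`` (a in um,
        b dimensionless). Required for SWC, ignored for the native dialect.
    metadata
        Free-form labels (animal id, group) stored on the network.
    diameter_cutoff
        Preparation cutoff passed to validation; ``None`` uses the 80-um
        default of :meth:`CoronaryNetwork.validate`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "segment_table":
        net = _read_segment_table(path)
    elif format == "swc":
        if wall_model is None:
            raise ValidationError("SWC import requires a wall_model (a, b)")
        net = _read_swc(path, wall_model)
    else:
        raise ValueError(f"unknown format {format!r}")
    net.metadata.update(metadata or {})
    net = net.normalized()
    kwargs = {} if diameter_cutoff is None else {"diameter_cutoff": diameter_cutoff}
    return net.validate(**kwargs)


def write_network(net: CoronaryNetwork, path: str | Path,
                  format: str = "segment_table") -> Path:
    """Write a network; the native dialect round-trips bit-exactly."""
    if format != "segment_table":
        raise ValueError(f"unsupported output format {format!r}")
    if not net.segments:
        raise ValidationError("refusing to write an empty network")
    path = Path(path)
    rows = []
    for seg in net.segments.values():
        for i, p in enumerate(seg.points):
            rows.append((seg.segment_id, seg.parent_id if seg.parent_id is not None else "",
                         i, repr(p.x), repr(p.y), repr(p.outer_d), repr(p.inner_d)))
    df = pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)
    df.to_csv(path, index=False)
    return path


def network_to_frame(net: CoronaryNetwork) -> pd.DataFrame:
    """The segment table as a DataFrame (numeric columns, for analysis use)."""
    rows = [
        (seg.segment_id, seg.parent_id, i, p.x, p.y, p.outer_d, p.inner_d)
        for seg in net.segments.values()
        for i, p in enumerate(seg.points)
    ]
    return pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)


def _read_segment_table(path: Path) -> CoronaryNetwork:
    df = pd.read_csv(path, dtype={"segment_id": str, "parent_id": str},
                     keep_default_na=False, float_precision="round_trip")
    missing = [c for c in SEGMENT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"segment table {path} lacks columns {missing}")
    segments: dict[str, VesselSegment] = {}
    for sid, grp in df.groupby("segment_id", sort=False):
        grp = grp.sort_values("point_index")
        parent = grp["parent_id"].iloc[0]
        parent_id = None if parent == "" else str(parent)
        pts = [
            CenterlinePoint(float(r.x_um), float(r.y_um),
                            float(r.outer_d_um), float(r.inner_d_um))
            for r in grp.itertuples()
        ]
        segments[str(sid)] = VesselSegment(str(sid), parent_id, pts)
    return CoronaryNetwork(segments)


def _read_swc(path: Path, wall_model: tuple[float, float]) -> CoronaryNetwork:
    a, b = wall_model
    recs = {}
    children: dict[int, list[int]] = {}
    roots = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 7:
                raise ValidationError(f"malformed SWC line in {path}: {line!r}")
            nid, _typ = int(f[0]), int(f[1])
            x, y, z, r = (float(v) for v in f[2:6])
            parent = int(f[6])
            recs[nid] = (x, y, z, r)
            if parent == -1:
                roots.append(nid)
            else:
                children.setdefault(parent, []).append(nid)
    if len(roots) != 1:
        raise StructuralError(f"SWC file {path} has {len(roots)} roots; expected 1")
    for parent in children:
        if parent not in recs:
            raise StructuralError(f"SWC node parent {parent} missing in {path}")
    if any(recs[n][2] != 0.0 for n in recs):
        log.warning("SWC file %s has nonzero z coordinates; the analysis is "
                    "planar and z is ignored", path)

    def mk_point(nid: int) -> CenterlinePoint:
        x, y, _z, r = recs[nid]
        outer = 2.0 * r
        inner = outer - 2.0 * (a + b * outer)
        floor = _INNER_FLOOR_FRACTION * outer
        if inner < floor:
            log.warning("SWC node %d: wall model closes the lumen "
                        "(outer %.1f um); clamping inner diameter", nid, outer)
            inner = floor
        return CenterlinePoint(x, y, outer, inner)

    # walk unbranched chains; a branch point ends a segment and seeds each
    # child chain, which starts at the branch vertex itself so that the
    # attachment is exact
    segments: dict[str, VesselSegment] = {}
    counter = 0
    stack: list[tuple[int, Optional[str], Optional[int]]] = [(roots[0], None, None)]
    while stack:
        start, parent_sid, branch_vertex = stack.pop()
        counter += 1
        sid = str(counter)
        chain = [] if branch_vertex is None else [branch_vertex]
        chain.append(start)
        cur = start
        while len(children.get(cur, [])) == 1:
            cur = children[cur][0]
            chain.append(cur)
        pts = [mk_point(n) for n in chain]
        if len(pts) < 2:
            raise ValidationError(
                f"SWC branch starting at node {start} has a single point; "
                "cannot form a segment"
            )
        segments[sid] = VesselSegment(sid, parent_sid, pts)
        for child in reversed(children.get(cur, [])):
            stack.append((child, sid, cur))
    return CoronaryNetwork(segments, metadata={"source": str(path)})
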