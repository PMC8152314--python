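import math

import numpy as np
import pytest
from hypothesis import settings

from coromorph import CenterlinePoint, CoronaryNetwork, VesselSegment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def straight_segment(segment_id="1", parent_id=None, start=(0.0, 0.0),
                     direction=(1.0, 0.0), length=500.0, n_points=2,
                     outer_d=300.0, inner_d=240.0, outer_d_end=None,
                     inner_d_end=None):
    """A straight polyline segment with optional linear taper."""
    ux, uy = direction
    norm = math.hypot(ux, uy)
    ux, uy = ux / norm, uy / norm
    outer_d_end = outer_d if outer_d_end is None else outer_d_end
    inner_d_end = inner_d if inner_d_end is None else inner_d_end
    pts = []
    for i in range(n_points):
        t = i / (n_points - 1)
        s = t * length
        pts.append(CenterlinePoint(start[0] + ux * s, start[1] + uy * s,
                                   outer_d + t * (outer_d_end - outer_d),
                                   inner_d + t * (inner_d_end - inner_d)))
    return VesselSegment(segment_id, parent_id, pts)


def build_network(*segments, metadata=None):
    net = CoronaryNetwork({s.segment_id: s for s in segments},
                          metadata=metadata or {})
    return net


@pytest.fixture
def two_segment_network():
    """Root of 1000 um along +X with one perpendicular child at its tip."""
    root = straight_segment("1", None, length=1000.0, n_points=5,
                            outer_d=400.0, inner_d=320.0)
    child = straight_segment("2", "1", start=(1000.0, 0.0),
                             direction=(0.0, 1.0), length=400.0, n_points=3,
                             outer_d=250.0, inner_d=200.0)
    return build_network(root, child)
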