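"""Seeded generator of planar coronary-like arterial trees.

No traced networks are deposited with the source study, so every pipeline
stage is exercised on synthetic trees built to the same constraints the
tracing obeys: a planar tree rooted at the orifice, grown along the
orifice-apex axis, pruned at the ~80-um outer-diameter preparation cutoff,
with lumen radii at each bifurcation satisfying a tunable branching
exponent (r_d1^g + r_d2^g = r_m^g, Murray's law at g = 3), a linear
wall-thickness law w = a + b * outer_d with Gaussian noise, and a branching
angle law in which small daughters deviate more from the mother's course.

Group presets (MSed, MEx, FSed, FEx) emulate the qualitative sedentary /
swim-trained and male / female contrasts: training raises the wall slope in
the mid-calibre range and enriches specific diameter classes at specific
flow distances in males, while in females it thins large-vessel walls and
inserts a new 200-250-um population close to the orifice.

All randomness flows from one seeded NumPy generator; identical seeds give
byte-identical segment tables.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bifurcations import Bifurcation
from .errors import ValidationError
from .network import CenterlinePoint, CoronaryNetwork, VesselSegment
from .rings import RingUnit
from .spectra import DiameterBinning

log = logging.getLogger(__name__)

#: growth step between generated centerline points (one ring length)
STEP_UM = 50.0

#: branches stop growing beyond this flow distance from the orifice
MAX_FLOW_UM = 20_000.0


@dataclass(frozen=True)
class SideBranchSpec:
    """Extra side branches of a target calibre in a flow-distance window."""

    outer_d_um: float
    flow_lo_mm: float
    flow_hi_mm: float
    count: int


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable description of one synthetic coronary tree.

    Lengths in um, angles in degrees. ``asymmetry`` is the distribution
    bounds of the smaller/larger daughter lumen-radius ratio at each
    bifurcation. The wall model is ``w = wall_a + wall_b * outer_d`` plus
    Gaussian noise of SD ``wall_sigma``; the angle law is
    ``angle = 180 - angle_c * (r_m / r_d - 1)`` plus Gaussian noise of SD
    ``angle_sigma``, clamped to (60, 180]. ``taper`` is the fractional lumen
    loss from the proximal to the distal end of a segment; ``tortuosity``
    is the SD of the direction random walk per 50-um step.
    """

    seed: int = 0
    root_outer_d: float = 550.0
    murray_gamma: float = 3.0
    asymmetry: tuple[float, float] = (0.4, 1.0)
    segment_length_median: float = 900.0
    segment_length_sigma: float = 0.4
    terminal_cutoff: float = 80.0
    wall_a: float = 8.0
    wall_b: float = 0.06
    wall_sigma: float = 3.0
    angle_c: float = 25.0
    angle_sigma: float = 10.0
    taper: float = 0.15
    tortuosity: float = 3.0
    preset: str = "none"
    # preset shaping hooks (inactive by default)
    wall_b_window: Optional[tuple[float, float, float]] = None   # (lo, hi, delta_b)
    side_branches: tuple[SideBranchSpec, ...] = ()

    def __post_init__(self) -> None:
        if min(self.root_outer_d, self.segment_length_median, self.terminal_cutoff,
               self.wall_a, self.angle_c, self.tortuosity) <= 0:
            raise ValidationError("scale parameters must be positive")
        if not (0 < self.terminal_cutoff < self.root_outer_d):
            raise ValidationError("terminal cutoff must lie below the root diameter")
        if not (0 <= self.taper < 1):
            raise ValidationError("taper must be a fraction in [0, 1)")


def group_preset(name: str, seed: int = 0) -> GeneratorConfig:
    """Configuration preset for one of the four study groups.

    ``MSed``/``FSed`` are sedentary baselines with sex-specific calibre
    (female trees start thinner); ``MEx`` thickens mid-calibre walls and
    enriches 400-um vessels near the orifice plus 200-um vessels at
    8-13 mm; ``FEx`` thins large-vessel walls and inserts 200-250-um side
    branches at 5-8 mm. ``none`` is the plain default configuration.
    """
    base = GeneratorConfig(seed=seed)
    presets = {
        "none": base,
        "MSed": dataclasses.replace(base, preset="MSed"),
        "MEx": dataclasses.replace(
            base, preset="MEx",
            wall_b_window=(200.0, 500.0, 0.025),
            side_branches=(
                SideBranchSpec(400.0, 0.0, 5.0, 3),
                SideBranchSpec(200.0, 8.0, 13.0, 5),
            ),
        ),
        "FSed": dataclasses.replace(
            base, preset="FSed", root_outer_d=480.0, wall_a=6.0,
        ),
        "FEx": dataclasses.replace(
            base, preset="FEx", root_outer_d=480.0, wall_a=6.0,
            wall_b_window=(400.0, 700.0, -0.02),
            side_branches=(SideBranchSpec(225.0, 5.0, 8.0, 6),),
        ),
    }
    if name not in presets:
        raise ValidationError(
            f"unknown preset {name!r}; expected one of {sorted(presets)}"
        )
    return presets[name]


# -- wall model ------------------------------------------------------------

def _outer_from_lumen(inner_d: float, cfg: GeneratorConfig) -> float:
    """Noise-free outer diameter consistent with w = a + b * outer."""
    outer = (inner_d + 2.0 * cfg.wall_a) / (1.0 - 2.0 * cfg.wall_b)
    if cfg.wall_b_window is not None:
        lo, hi, delta = cfg.wall_b_window
        if lo <= outer < hi:
            outer = outer + 2.0 * delta * outer
    return outer


def _lumen_from_outer(outer_d: float, cfg: GeneratorConfig) -> float:
    inner = outer_d * (1.0 - 2.0 * cfg.wall_b) - 2.0 * cfg.wall_a
    if inner <= 0:
        raise ValidationError(
            f"wall model closes the lumen at outer diameter {outer_d} um"
        )
    return inner


# -- tree growth -----------------------------------------------------------

@dataclass
class _GrownSegment:
    points: list[CenterlinePoint]
    end_dir_deg: float
    end_lumen_r: float
    end_flow: float
    reached_full_length: bool


def _grow_polyline(rng: np.random.Generator, cfg: GeneratorConfig,
                   start_xy: tuple[float, float], start_dir_deg: float,
                   start_lumen_r: float, start_flow: float,
                   length_um: float) -> Optional[_GrownSegment]:
    """Grow one segment in 50-um steps; returns None if < 2 points survive."""
    n_steps = max(2, int(round(length_um / STEP_UM)))
    x, y = start_xy
    d = start_dir_deg
    pts: list[CenterlinePoint] = []
    flow = start_flow

    def make_point(px: float, py: float, lumen_r: float) -> Optional[CenterlinePoint]:
        inner = 2.0 * lumen_r
        outer = _outer_from_lumen(inner, cfg)
        if cfg.wall_sigma > 0:
            outer = inner + 2.0 * max(
                (outer - inner) / 2.0 + rng.normal(0.0, cfg.wall_sigma), 0.5
            )
        if outer < cfg.terminal_cutoff:
            return None
        return CenterlinePoint(px, py, outer, inner)

    p0 = make_point(x, y, start_lumen_r)
    if p0 is None:
        return None
    pts.append(p0)
    full = True
    for i in range(1, n_steps + 1):
        d += rng.normal(0.0, cfg.tortuosity)
        x += STEP_UM * math.cos(math.radians(d))
        y += STEP_UM * math.sin(math.radians(d))
        flow += STEP_UM
        lumen_r = start_lumen_r * (1.0 - cfg.taper * i / n_steps)
        p = make_point(x, y, lumen_r)
        if p is None or flow > MAX_FLOW_UM:
            full = False
            break
        pts.append(p)
    if len(pts) < 2:
        return None
    return _GrownSegment(points=pts, end_dir_deg=d,
                         end_lumen_r=pts[-1].inner_d / 2.0,
                         end_flow=start_flow + (len(pts) - 1) * STEP_UM,
                         reached_full_length=full)


def _daughter_angles(rng: np.random.Generator, cfg: GeneratorConfig,
                     r_m: float, r_d: float) -> float:
    """Reported daughter-mother angle from the angle law (180 = continues)."""
    angle = 180.0 - cfg.angle_c * (r_m / r_d - 1.0)
    if cfg.angle_sigma > 0:
        angle += rng.normal(0.0, cfg.angle_sigma)
    return float(np.clip(angle, 60.0 + 1e-9, 180.0))


def generate_network(cfg: GeneratorConfig) -> CoronaryNetwork:
    """Grow one validated synthetic tree from the orifice along +X.

    Recursive planar growth: each completed segment bifurcates into two
    daughters whose lumen radii satisfy the configured branching exponent;
    branches terminate at the outer-diameter cutoff or beyond 20 mm of flow
    distance. Identical seeds give identical networks.
    """
    rng = np.random.default_rng(cfg.seed)
    segments: dict[str, VesselSegment] = {}
    # (parent_id, start_xy, dir_deg, lumen_r, flow)
    root_lumen_r = _lumen_from_outer(cfg.root_outer_d, cfg) / 2.0
    stack: list[tuple[Optional[str], tuple[float, float], float, float, float]] = [
        (None, (0.0, 0.0), 0.0, root_lumen_r, 0.0)
    ]
    counter = 0
    gamma = cfg.murray_gamma
    while stack:
        parent_id, xy, dir_deg, lumen_r, flow = stack.pop()
        length = rng.lognormal(math.log(cfg.segment_length_median),
                               cfg.segment_length_sigma)
        grown = _grow_polyline(rng, cfg, xy, dir_deg, lumen_r, flow, length)
        if grown is None:
            continue
        counter += 1
        sid = str(counter)
        segments[sid] = VesselSegment(sid, parent_id, grown.points)
        if not grown.reached_full_length or grown.end_flow >= MAX_FLOW_UM:
            continue
        # bifurcate at the tip: Murray split with sampled asymmetry
        q = rng.uniform(*cfg.asymmetry)
        r_m = grown.end_lumen_r
        r1 = r_m / (1.0 + q ** gamma) ** (1.0 / gamma)
        r2 = q * r1
        side = rng.choice([-1.0, 1.0])
        tip = grown.points[-1]
        for r_d, sgn in ((r1, side), (r2, -side)):
            deviation = 180.0 - _daughter_angles(rng, cfg, r_m, r_d)
            child_dir = grown.end_dir_deg + sgn * deviation
            stack.append((sid, (tip.x, tip.y), child_dir, r_d, grown.end_flow))

    if cfg.side_branches:
        _insert_side_branches(rng, cfg, segments)
    if not segments:
        raise ValidationError("configuration yielded zero segments")
    net = CoronaryNetwork(segments, metadata={"preset": cfg.preset,
                                              "seed": cfg.seed})
    # wall noise may not push any traced point below the preparation cutoff
    return net.validate(diameter_cutoff=min(cfg.terminal_cutoff, 80.0))


def _insert_side_branches(rng: np.random.Generator, cfg: GeneratorConfig,
                          segments: dict[str, VesselSegment]) -> None:
    """Attach preset-specific side branches at sampled flow distances."""
    net = CoronaryNetwork(dict(segments))
    offsets = net.flow_offsets()
    counter = len(segments)
    main_tree = list(segments.items())   # side branches never host further ones
    for spec in cfg.side_branches:
        lo, hi = spec.flow_lo_mm * 1000.0, spec.flow_hi_mm * 1000.0
        candidates: list[tuple[str, int, float]] = []   # (sid, vertex, flow)
        for sid, seg in main_tree:
            cum = seg.cumulative_arc()
            for k in range(1, len(seg.points) - 1):
                f = offsets[sid] + float(cum[k])
                if lo <= f < hi:
                    candidates.append((sid, k, f))
        if not candidates:
            log.info("no attachment candidates for side branches in "
                     "[%.0f, %.0f) mm", spec.flow_lo_mm, spec.flow_hi_mm)
            continue
        picks = rng.choice(len(candidates), size=min(spec.count, len(candidates)),
                           replace=False)
        for i in np.sort(picks):
            sid, k, f = candidates[int(i)]
            parent = segments[sid]
            anchor = parent.points[k]
            # local parent direction from the bracketing vertices
            prev_p, next_p = parent.points[k - 1], parent.points[k + 1]
            base_dir = math.degrees(math.atan2(next_p.y - prev_p.y,
                                               next_p.x - prev_p.x))
            child_dir = base_dir + rng.choice([-1.0, 1.0]) * rng.uniform(45.0, 90.0)
            lumen_r = _lumen_from_outer(spec.outer_d_um, cfg) / 2.0
            length = rng.lognormal(math.log(cfg.segment_length_median * 0.6),
                                   cfg.segment_length_sigma)
            grown = _grow_polyline(rng, cfg, (anchor.x, anchor.y), child_dir,
                                   lumen_r, f, length)
            if grown is None:
                continue
            counter += 1
            segments[str(counter)] = VesselSegment(str(counter), sid, grown.points)


def generate_cohort(cfg: GeneratorConfig, n: int) -> list[CoronaryNetwork]:
    """Generate ``n`` networks with per-network seeds derived from cfg.seed."""
    children = np.random.SeedSequence(cfg.seed).spawn(n)
    nets = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % 2**31)
        sub = dataclasses.replace(cfg, seed=seed)
        net = generate_network(sub)
        net.metadata["animal"] = f"{cfg.preset}-{i + 1}"
        nets.append(net)
    return nets


# -- direct samplers for statistical harnesses ------------------------------

def sample_bifurcations(n: int, gamma: float = 3.0, seed: int = 0,
                        radius_noise_sigma: float = 0.0,
                        asymmetry: tuple[float, float] = (0.4, 1.0),
                        angle_c: float = 25.0,
                        angle_sigma: float = 10.0,
                        r_m_range: tuple[float, float] = (40.0, 250.0)
                        ) -> list[Bifurcation]:
    """Draw bifurcation records directly from the branching model.

    Mother lumen radii are log-uniform over ``r_m_range``; daughter radii
    are generated from the mother by the exponent-``gamma`` split with
    sampled asymmetry, then scattered around that prediction by
    multiplicative log-normal noise of log-SD ``radius_noise_sigma`` (the
    mother is the exogenous regressor of the exponent fit; the scatter
    models deviation of daughter calibres from the optimum). Angles follow
    the configured angle law.
    """
    rng = np.random.default_rng(seed)
    r_m = np.exp(rng.uniform(math.log(r_m_range[0]), math.log(r_m_range[1]), n))
    q = rng.uniform(*asymmetry, n)
    r1 = r_m / (1.0 + q ** gamma) ** (1.0 / gamma)
    r2 = q * r1
    if radius_noise_sigma > 0:
        r1 = r1 * np.exp(rng.normal(0, radius_noise_sigma, n))
        r2 = r2 * np.exp(rng.normal(0, radius_noise_sigma, n))
    bifs = []
    for i in range(n):
        a1 = float(np.clip(180.0 - angle_c * (r_m[i] / r1[i] - 1.0)
                           + rng.normal(0, angle_sigma), 60.0 + 1e-9, 180.0))
        a2 = float(np.clip(180.0 - angle_c * (r_m[i] / r2[i] - 1.0)
                           + rng.normal(0, angle_sigma), 60.0 + 1e-9, 180.0))
        bifs.append(Bifurcation(float(r_m[i]), float(r1[i]), float(r2[i]), a1, a2))
    return bifs


def sample_rings_from_density(joint_p: np.ndarray, n: int, seed: int = 0,
                              binning: Optional[DiameterBinning] = None,
                              flow_bin_mm: float = 1.0) -> list[RingUnit]:
    """Sample ring units from an imposed diameter x flow-distance density.

    ``joint_p`` has shape (n_classes, n_flow_bins) and sums to 1. Diameters
    and flow distances are drawn uniformly within the selected cell, which
    makes the imposed density exactly recoverable by ``histogram2d``.
    """
    binning = binning or DiameterBinning()
    p = np.asarray(joint_p, dtype=float)
    if p.shape[0] != binning.n_classes or not math.isclose(p.sum(), 1.0,
                                                           rel_tol=1e-9):
        raise ValidationError("joint density must match the binning and sum to 1")
    rng = np.random.default_rng(seed)
    cells = rng.choice(p.size, size=n, p=p.ravel())
    d_idx, f_idx = np.unravel_index(cells, p.shape)
    w = binning.class_width
    outer = (np.asarray(binning.class_centers)[d_idx]
             + rng.uniform(-w / 2.0, w / 2.0, n))
    flow = (f_idx + rng.uniform(0.0, 1.0, n)) * flow_bin_mm * 1000.0
    rings = []
    for i in range(n):
        outer_r = float(outer[i]) / 2.0
        wall = 8.0 + 0.06 * float(outer[i])
        rings.append(RingUnit(
            segment_id="synthetic", index=i + 1, outer_r=outer_r,
            inner_r=outer_r - wall, wall_thickness=wall, x=float(flow[i]),
            y=0.0, axis_angle=0.0, direct_distance=float(flow[i]) * 0.9,
            flow_distance=float(flow[i]),
        ))
    return rings
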