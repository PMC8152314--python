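"""Bifurcation extraction, Murray's-law residuals and branching-angle analysis.

Murray's law states that at an arterial bifurcation the cube of the mother
lumen radius equals the sum of the cubes of the daughter lumen radii
(r_m^3 = r_d1^3 + r_d2^3), the configuration that equalizes endothelial
shear. Compliance is measured on a log10 scale: the residual
``log10(r_d1^g + r_d2^g) - log10(r_m^g)`` is zero for exact compliance at
exponent ``g``.

Branching angles follow the convention of the source tracing method: the
reported angle between a daughter axis and the mother axis is 180 deg when
the daughter continues the mother's course and 90 deg when it arises
perpendicularly, i.e. ``180 - arccos(u_m . u_d)``.

All radius-based analyses here use the *lumen* (inner) radii; outer
diameters enter only the ring spectra.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError
from .network import CoronaryNetwork, VesselSegment, arc_length, diameters_at, direction_at

log = logging.getLogger(__name__)

AXIS_WINDOW_UM = 100.0

#: attachments closer than this to the parent tip have no distal continuation
_TIP_TOLERANCE_UM = 1.0

BIFURCATION_TABLE_COLUMNS = [
    "bif_id", "x_um", "y_um", "flow_um", "r_m_um", "r_d1_um", "r_d2_um",
    "angle1_deg", "angle2_deg", "residual",
]


@dataclass(frozen=True)
class Bifurcation:
    """Mother/daughter lumen radii and daughter-mother axis angles (um, deg)."""

    r_m: float
    r_d1: float
    r_d2: float
    angle_1: float
    angle_2: float
    location: tuple[float, float] = (0.0, 0.0)
    flow_distance: float = 0.0

    def __post_init__(self) -> None:
        if min(self.r_m, self.r_d1, self.r_d2) <= 0:
            raise ValidationError("bifurcation radii must be positive")
        for a in (self.angle_1, self.angle_2):
            if not (0 < a <= 180):
                raise ValidationError(f"angle {a} outside (0, 180]")


def _reported_angle(u_m: np.ndarray, u_d: np.ndarray) -> float:
    cosang = float(np.clip(u_m @ u_d, -1.0, 1.0))
    return 180.0 - math.degrees(math.acos(cosang))


def extract_bifurcations(net: CoronaryNetwork,
                         window: float = AXIS_WINDOW_UM) -> list[Bifurcation]:
    """Identify every branch point and measure its radii and angles.

    The mother lumen radius is taken just proximal to the attachment; a
    distal continuation of the parent counts as one daughter. Attachment
    points with a single child and no continuation are treated as a plain
    continuation of the vessel, not a bifurcation (logged). Trifurcations
    are decomposed by keeping the two largest daughters, with a warning.
    """
    offsets = net.flow_offsets()
    bifs: list[Bifurcation] = []
    skipped = 0
    for parent in net.traverse():
        kids = net.children_of(parent.segment_id)
        if not kids:
            continue
        total = arc_length(parent)
        # group children attaching at (numerically) the same arc position
        groups: dict[float, list[VesselSegment]] = {}
        for child in kids:
            s = net.attachment_arc(child)
            key = next((k for k in groups if abs(k - s) <= _TIP_TOLERANCE_UM), s)
            groups.setdefault(key, []).append(child)
        for s_att, children in sorted(groups.items()):
            u_m = direction_at(parent, s_att - window / 2.0, window)
            daughters: list[tuple[float, float]] = []  # (lumen radius, angle)
            for child in children:
                r = float(diameters_at(child, 0.0)[1]) / 2.0
                u_d = direction_at(child, window / 2.0, window)
                daughters.append((r, _reported_angle(u_m, u_d)))
            if s_att < total - _TIP_TOLERANCE_UM:
                # the distal continuation of the parent is itself a daughter
                r_cont = float(diameters_at(parent, s_att)[1]) / 2.0
                u_c = direction_at(parent, s_att + window / 2.0, window)
                daughters.append((r_cont, _reported_angle(u_m, u_c)))
            if len(daughters) < 2:
                skipped += 1
                continue
            if len(daughters) > 2:
                warnings.warn(
                    f"trifurcation at arc {s_att:.0f} um on segment "
                    f"{parent.segment_id!r}: keeping the two largest daughters",
                    stacklevel=2,
                )
                daughters = sorted(daughters, reverse=True)[:2]
            daughters = sorted(daughters, reverse=True)
            r_m = float(diameters_at(parent, s_att)[1]) / 2.0
            x, y = (float(v) for v in
                    parent.coords()[int(np.argmin(np.abs(parent.cumulative_arc() - s_att)))])
            bifs.append(Bifurcation(
                r_m=r_m,
                r_d1=daughters[0][0], r_d2=daughters[1][0],
                angle_1=daughters[0][1], angle_2=daughters[1][1],
                location=(x, y),
                flow_distance=offsets[parent.segment_id] + s_att,
            ))
    if skipped:
        log.info("%d single-child attachments treated as continuations", skipped)
    return bifs


def murray_residual(b: Bifurcation, gamma: float = 3.0) -> float:
    """log10 deviation from Murray's law at exponent ``gamma`` (0 = compliant)."""
    return float(
        np.log10(b.r_d1 ** gamma + b.r_d2 ** gamma) - gamma * np.log10(b.r_m)
    )


@dataclass(frozen=True)
class MurrayFit:
    gamma_hat: float
    residual_sd: float
    n: int


def fit_murray_exponent(bifs: Sequence[Bifurcation],
                        bounds: tuple[float, float] = (1.0, 6.0)) -> MurrayFit:
    """Least-squares estimate of the branching exponent.

    Minimizes the sum of squared log10 Murray residuals over the exponent
    within ``bounds`` by bounded scalar minimization (tolerance 1e-8).
    """
    if len(bifs) < 3:
        raise ValidationError("need >= 3 bifurcations to fit an exponent")
    r_m = np.array([b.r_m for b in bifs])
    r1 = np.array([b.r_d1 for b in bifs])
    r2 = np.array([b.r_d2 for b in bifs])
    rho = np.stack([r1 / r_m, r2 / r_m])
    if float(np.ptp(rho[0]) + np.ptp(rho[1])) < 1e-12:
        warnings.warn(
            "all bifurcations share identical radius ratios; the exponent "
            "is poorly identified", stacklevel=2,
        )

    def objective(g: float) -> float:
        res = np.log10(r1 ** g + r2 ** g) - g * np.log10(r_m)
        return float(res @ res)

    sol = optimize.minimize_scalar(objective, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-8})
    g = float(sol.x)
    res = np.log10(r1 ** g + r2 ** g) - g * np.log10(r_m)
    sd = float(np.std(res, ddof=1)) if len(bifs) > 1 else 0.0
    return MurrayFit(gamma_hat=g, residual_sd=sd, n=len(bifs))


def angle_ratio_correlation(bifs: Sequence[Bifurcation]) -> tuple[float, float]:
    """Pearson correlation of daughter angle on mother/daughter radius ratio.

    Uses one (r_m / r_d, angle) pair per daughter. Smaller daughters (large
    ratios) deviate more from the mother's course, so the expected sign is
    negative.
    """
    if len(bifs) < 3:
        raise ValidationError("need >= 3 bifurcations for a correlation")
    ratios, angles = [], []
    for b in bifs:
        ratios += [b.r_m / b.r_d1, b.r_m / b.r_d2]
        angles += [b.angle_1, b.angle_2]
    x, y = np.asarray(ratios), np.asarray(angles)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bifurcation_table(bifs: Sequence[Bifurcation], gamma: float = 3.0) -> pd.DataFrame:
    """One row per bifurcation, including the Murray residual at ``gamma``."""
    rows = [
        (i + 1, b.location[0], b.location[1], b.flow_distance, b.r_m,
         b.r_d1, b.r_d2, b.angle_1, b.angle_2, murray_residual(b, gamma))
        for i, b in enumerate(bifs)
    ]
    return pd.DataFrame(rows, columns=BIFURCATION_TABLE_COLUMNS)
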