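"""Ring-frequency spectra, diameter x flow-distance histograms and their
chi-square group comparison.

The default binning sorts ring units into 13 outer-diameter classes centred
at 100, 150, ..., 700 um, each spanning ``[centre - 25, centre + 25)``.
Rings thinner than the lowest edge (75 um, just below the ~80-um
preparation cutoff) are dropped with a logged count; rings at or above the
top edge are pooled into the top class. Two pooled spectra are compared
with a two-sample chi-square homogeneity test on the 2 x K contingency
table of class counts (no Yates correction); with all 13 classes occupied
this test has 12 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .rings import RingUnit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiameterBinning:
    """Contiguous half-open outer-diameter classes of equal width (um)."""

    class_centers: tuple[float, ...] = tuple(float(c) for c in range(100, 701, 50))
    class_width: float = 50.0

    def __post_init__(self) -> None:
        c = np.asarray(self.class_centers)
        if len(c) < 2 or np.any(np.diff(c) != self.class_width):
            raise ValidationError(
                "class centres must be evenly spaced by the class width"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_centers)

    @property
    def lower_edge(self) -> float:
        return self.class_centers[0] - self.class_width / 2.0

    @property
    def upper_edge(self) -> float:
        return self.class_centers[-1] + self.class_width / 2.0

    def classify(self, outer_d: np.ndarray) -> np.ndarray:
        """Class index per diameter; -1 marks sub-range rings (dropped)."""
        d = np.asarray(outer_d, dtype=float)
        idx = np.floor((d - self.lower_edge) / self.class_width).astype(int)
        idx = np.minimum(idx, self.n_classes - 1)   # pool oversized into top class
        idx[d < self.lower_edge] = -1
        return idx


@dataclass
class RingSpectrum:
    """Ring-unit counts per outer-diameter class, pooled over animals."""

    counts: np.ndarray
    binning: DiameterBinning
    group: Optional[str] = None
    n_animals: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.binning.n_classes,):
            raise ValidationError("counts length must match the binning")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class_center_um": self.binning.class_centers,
            "count": self.counts,
        })


@dataclass
class Ring2DHistogram:
    """Joint ring counts on the diameter-class x flow-distance-bin grid."""

    counts: np.ndarray                  # shape (n_classes, n_flow_bins)
    binning: DiameterBinning
    flow_bin_mm: float = 1.0
    max_flow_mm: float = 25.0
    group: Optional[str] = None

    @property
    def flow_edges_mm(self) -> np.ndarray:
        return np.arange(0.0, self.max_flow_mm + self.flow_bin_mm, self.flow_bin_mm)

    def marginal(self) -> RingSpectrum:
        """Diameter spectrum of the rings inside the distance ceiling."""
        return RingSpectrum(self.counts.sum(axis=1), self.binning, self.group)

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per (class centre, flow bin) cell."""
        centers = np.repeat(self.binning.class_centers, self.counts.shape[1])
        flows = np.tile(self.flow_edges_mm[:-1], self.counts.shape[0])
        return pd.DataFrame({
            "class_center_um": centers,
            "flow_bin_mm": flows,
            "count": self.counts.ravel(),
        })


def spectrum(rings: Sequence[RingUnit], binning: Optional[DiameterBinning] = None,
             group: Optional[str] = None, n_animals: int = 1) -> RingSpectrum:
    """Count ring units per outer-diameter class."""
    if not rings:
        raise ValidationError("cannot build a spectrum from zero rings")
    binning = binning or DiameterBinning()
    idx = binning.classify(np.array([r.outer_d for r in rings]))
    dropped = int(np.sum(idx < 0))
    if dropped:
        log.info("%d rings below %.0f um dropped from the spectrum",
                 dropped, binning.lower_edge)
    counts = np.bincount(idx[idx >= 0], minlength=binning.n_classes)
    return RingSpectrum(counts, binning, group=group, n_animals=n_animals)


def pool(spectra: Sequence[RingSpectrum]) -> RingSpectrum:
    """Pool per-animal spectra by summing counts (they must share a binning)."""
    if not spectra:
        raise ValidationError("nothing to pool")
    binning = spectra[0].binning
    if any(s.binning != binning for s in spectra):
        raise ValidationError("spectra must share a binning to pool")
    counts = np.sum([s.counts for s in spectra], axis=0)
    return RingSpectrum(counts, binning, group=spectra[0].group,
                        n_animals=sum(s.n_animals for s in spectra))


def histogram2d(rings: Sequence[RingUnit], binning: Optional[DiameterBinning] = None,
                flow_bin_mm: float = 1.0, max_flow_mm: float = 25.0,
                group: Optional[str] = None) -> Ring2DHistogram:
    """Joint counts by outer-diameter class and flow distance from the orifice.

    Flow bins are half-open 1-mm intervals [0, 1), ..., up to ``max_flow_mm``;
    rings at or beyond the ceiling are dropped with a logged count.
    """
    if not rings:
        raise ValidationError("cannot build a histogram from zero rings")
    binning = binning or DiameterBinning()
    n_flow = int(round(max_flow_mm / flow_bin_mm))
    d_idx = binning.classify(np.array([r.outer_d for r in rings]))
    f_idx = np.floor(
        np.array([r.flow_distance for r in rings]) / 1000.0 / flow_bin_mm
    ).astype(int)
    keep = (d_idx >= 0) & (f_idx >= 0) & (f_idx < n_flow)
    dropped = int(np.sum(~keep))
    if dropped:
        log.info("%d rings outside the diameter range or beyond %.0f mm dropped",
                 dropped, max_flow_mm)
    counts = np.zeros((binning.n_classes, n_flow), dtype=int)
    np.add.at(counts, (d_idx[keep], f_idx[keep]), 1)
    return Ring2DHistogram(counts, binning, flow_bin_mm=flow_bin_mm,
                           max_flow_mm=max_flow_mm, group=group)


@dataclass(frozen=True)
class Chi2Report:
    chi2: float
    df: int
    p: float
    dropped_classes: tuple[float, ...]   # class centres empty in both groups

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "dropped_classes": list(self.dropped_classes)}


def chi2_compare(a: RingSpectrum, b: RingSpectrum) -> Chi2Report:
    """Two-sample chi-square homogeneity test of two pooled spectra.

    Classes empty in both groups are dropped, leaving K occupied classes and
    K - 1 degrees of freedom. No continuity correction is applied. A warning
    is logged when any expected count falls below 1.
    """
    if a.binning != b.binning:
        raise ValidationError("spectra must share a binning")
    if a.total == 0 or b.total == 0:
        raise ValidationError("both spectra must have positive totals")
    table = np.stack([a.counts, b.counts])
    occupied = table.sum(axis=0) > 0
    dropped = tuple(
        c for c, occ in zip(a.binning.class_centers, occupied) if not occ
    )
    table = table[:, occupied]
    if table.shape[1] < 2:
        return Chi2Report(0.0, 0, 1.0, dropped)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 1.0):
        log.warning("chi-square comparison has %d cells with expected count < 1",
                    int(np.sum(expected < 1.0)))
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Report(float(chi2), int(df), float(p), dropped)
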