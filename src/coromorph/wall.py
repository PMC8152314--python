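"""Wall-thickness-versus-diameter analysis and its group statistics.

Vascular remodelling shifts the relation between wall thickness and vessel
calibre. Per diameter class this module reports mean wall thickness, SEM
and ring count, plus the overall Pearson correlation of wall thickness with
outer diameter. Groups (e.g. sedentary vs trained, male vs female) are
compared with a two-way ANOVA (factors: group and diameter class, with
interaction; type-II sums of squares for unbalanced layouts) followed by
per-class Tukey HSD pairwise comparisons.

The unit of analysis is the ring unit; pooling thousands of rings across
animals inflates n (pseudo-replication), which is documented rather than
corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ValidationError
from .rings import RingUnit
from .spectra import DiameterBinning

log = logging.getLogger(__name__)

WALL_PROFILE_COLUMNS = ["group", "class_center_um", "n", "mean_wall_um", "sem_um"]


@dataclass
class WallByDiameter:
    """Per-class wall-thickness summary for one group."""

    table: pd.DataFrame            # columns: WALL_PROFILE_COLUMNS
    pearson_r: float
    pearson_p: float
    group: Optional[str] = None


def wall_profile(rings: Sequence[RingUnit],
                 binning: Optional[DiameterBinning] = None,
                 group: Optional[str] = None) -> WallByDiameter:
    """Mean wall thickness +/- SEM per outer-diameter class.

    SEM is reported as missing (NaN) for classes with fewer than two rings.
    Also returns the Pearson correlation of wall thickness with outer
    diameter over all in-range rings.
    """
    if not rings:
        raise ValidationError("cannot profile zero rings")
    binning = binning or DiameterBinning()
    outer = np.array([r.outer_d for r in rings])
    wall = np.array([r.wall_thickness for r in rings])
    idx = binning.classify(outer)
    keep = idx >= 0
    rows = []
    for k, centre in enumerate(binning.class_centers):
        w = wall[keep & (idx == k)]
        n = len(w)
        mean = float(np.mean(w)) if n else np.nan
        sem = float(stats.sem(w)) if n >= 2 else np.nan
        rows.append((group, centre, n, mean, sem))
    table = pd.DataFrame(rows, columns=WALL_PROFILE_COLUMNS)
    if np.ptp(outer[keep]) > 0 and np.ptp(wall[keep]) > 0:
        r, p = stats.pearsonr(outer[keep], wall[keep])
    else:
        r, p = np.nan, np.nan
    return WallByDiameter(table=table, pearson_r=float(r), pearson_p=float(p),
                          group=group)


@dataclass
class WallAnova:
    """Two-way ANOVA report with per-class Tukey comparisons."""

    anova: pd.DataFrame                    # index: effects; F, df, PR(>F)
    tukey: dict[float, pd.DataFrame]       # class centre -> pairwise table
    excluded_classes: tuple[float, ...]

    def effect(self, name: str) -> dict:
        row = self.anova.loc[name]
        return {"F": float(row["F"]), "df": float(row["df"]),
                "p": float(row["PR(>F)"])}

    def to_dict(self) -> dict:
        return {
            "effects": {
                str(i): {"F": _f(r["F"]), "df": _f(r["df"]), "p": _f(r["PR(>F)"])}
                for i, r in self.anova.iterrows()
            },
            "excluded_classes": list(self.excluded_classes),
        }


def _f(v: float) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def compare_wall_profiles(ring_groups: Mapping[str, Sequence[RingUnit]],
                          binning: Optional[DiameterBinning] = None) -> WallAnova:
    """Two-way ANOVA of wall thickness on group x diameter class.

    Classes in which any group has zero rings are excluded (logged), so the
    factorial layout has no empty cells. Tukey HSD pairwise group
    comparisons are computed within each retained class.
    """
    if len(ring_groups) < 2:
        raise ValidationError("need at least two groups to compare")
    binning = binning or DiameterBinning()
    frames = []
    for name, rings in ring_groups.items():
        outer = np.array([r.outer_d for r in rings])
        wall = np.array([r.wall_thickness for r in rings])
        idx = binning.classify(outer)
        keep = idx >= 0
        frames.append(pd.DataFrame({
            "group": name,
            "dclass": np.asarray(binning.class_centers)[idx[keep]],
            "wall": wall[keep],
        }))
    data = pd.concat(frames, ignore_index=True)
    cell_n = data.groupby(["group", "dclass"]).size().unstack(fill_value=0)
    full = cell_n.columns[(cell_n > 0).all(axis=0)]
    excluded = tuple(float(c) for c in cell_n.columns if c not in set(full))
    if excluded:
        log.info("classes excluded from ANOVA for empty cells: %s", excluded)
    data = data[data["dclass"].isin(full)]
    if data["dclass"].nunique() < 2:
        raise ValidationError("fewer than two diameter classes shared by all groups")

    model = ols("wall ~ C(group) * C(dclass)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index={
        "C(group)": "group", "C(dclass)": "diameter_class",
        "C(group):C(dclass)": "interaction", "Residual": "residual",
    })

    tukey: dict[float, pd.DataFrame] = {}
    for centre in full:
        sub = data[data["dclass"] == centre]
        if sub["group"].nunique() < 2 or sub.groupby("group").size().min() < 2:
            continue
        if np.ptp(sub["wall"].to_numpy()) == 0:
            continue  # studentized range undefined with zero spread
        tukey[float(centre)] = tukey_pairwise(sub["wall"].to_numpy(),
                                              sub["group"].to_numpy())
    return WallAnova(anova=anova, tukey=tukey, excluded_classes=excluded)


def tukey_pairwise(values: np.ndarray, labels: np.ndarray,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons as a tidy table.

    Columns: group1, group2, meandiff, p-adj, lower, upper, reject.
    """
    res = pairwise_tukeyhsd(np.asarray(values, float), np.asarray(labels),
                            alpha=alpha)
    out = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out["p-adj"] = res.pvalues
    out["reject"] = res.reject
    return out
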