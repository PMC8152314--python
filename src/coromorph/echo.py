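"""Echocardiographic morphometry formulas.

M-mode/short-axis linear dimensions of the left ventricle (in cm) feed the
standard rodent formulas:

* LV mass (g)   = [[(LVEDD + AWTd + PWTd)^3 - LVEDD^3] * 1.04] * 0.8 + 0.14
* LV mass index = LV mass / body weight, in g per kg
* FS (%)        = (LVEDD - LVESD) / LVEDD * 100
* Teichholz volume (ml) of a diameter D: V = 7 D^3 / (2.4 + D)
* EF (%)        = (LVEDV - LVESV) / LVEDV * 100 on Teichholz volumes

LVEDD/LVESD are end-diastolic/end-systolic internal diameters; AWTd/PWTd
the diastolic anterior/posterior wall thicknesses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

ECHO_INPUT_COLUMNS = ["animal_id", "group", "lvedd_cm", "lvesd_cm",
                      "awtd_cm", "pwtd_cm", "bw_g"]


@dataclass(frozen=True)
class EchoMeasurement:
    """LV cavity and wall dimensions (cm) plus body weight (g)."""

    lvedd: float
    lvesd: float
    awtd: float
    pwtd: float
    bw: float

    def __post_init__(self) -> None:
        if self.lvedd <= 0 or self.lvesd <= 0 or self.bw <= 0:
            raise ValidationError("diameters and body weight must be positive")
        if self.awtd < 0 or self.pwtd < 0:
            raise ValidationError("wall thicknesses must be non-negative")
        if self.lvesd > self.lvedd:
            raise ValidationError("LVESD cannot exceed LVEDD")


def lv_mass(m: EchoMeasurement) -> float:
    """Cube-formula LV mass in grams (inputs in cm)."""
    return ((m.lvedd + m.awtd + m.pwtd) ** 3 - m.lvedd ** 3) * 1.04 * 0.8 + 0.14


def lv_mass_index(mass: float, bw: float) -> float:
    """LV mass standardized for body mass, in g/kg (mass g, body weight g)."""
    if bw <= 0:
        raise ValidationError("body weight must be positive")
    return mass / (bw / 1000.0)


def fractional_shortening(m: EchoMeasurement) -> float:
    """FS = (LVEDD - LVESD) / LVEDD * 100, in percent."""
    return (m.lvedd - m.lvesd) / m.lvedd * 100.0


def teichholz_volume(d: float) -> float:
    """Teichholz LV volume (ml) of a linear diameter d (cm)."""
    if d <= 0:
        raise ValidationError("diameter must be positive")
    return 7.0 / (2.4 + d) * d ** 3


def ejection_fraction(m: EchoMeasurement) -> float:
    """EF = (LVEDV - LVESV) / LVEDV * 100 on Teichholz volumes, in percent."""
    edv = teichholz_volume(m.lvedd)
    esv = teichholz_volume(m.lvesd)
    return (edv - esv) / edv * 100.0


def derive_measures(df: pd.DataFrame) -> pd.DataFrame:
    """Batch version: derived columns appended to an echo input table.

    Expects the columns ``animal_id, group, lvedd_cm, lvesd_cm, awtd_cm,
    pwtd_cm, bw_g``; appends LV mass, LV mass index, FS, Teichholz volumes
    and EF.
    """
    missing = [c for c in ECHO_INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"echo table lacks columns {missing}")
    out = df.copy()
    derived = []
    for r in df.itertuples():
        m = EchoMeasurement(float(r.lvedd_cm), float(r.lvesd_cm),
                            float(r.awtd_cm), float(r.pwtd_cm), float(r.bw_g))
        mass = lv_mass(m)
        derived.append((
            mass, lv_mass_index(mass, m.bw), fractional_shortening(m),
            teichholz_volume(m.lvedd), teichholz_volume(m.lvesd),
            ejection_fraction(m),
        ))
    out[["lv_mass_g", "lv_mass_index_g_per_kg", "fs_pct",
         "lvedv_ml", "lvesv_ml", "ef_pct"]] = pd.DataFrame(derived, index=df.index)
    return out
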