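"""Lot-level seedling vigor quantities from emergence assays.

Vigor is scored per lot and stress condition by the emergence percentage,
the mean seedling dry weight (SDW, mg per emerged plant), and the simplified
vigor index SVI = emergence percentage x SDW.  Gravimetric soil water
content tracks the watering regime of pot assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import UndefinedStatisticError, ValidationError

CONDITIONS = (
    "control",
    "water_stress",
    "salinity_stress",
    "deep_sowing",
    "cold_stress",
    "field_sowing_1",
    "field_sowing_2",
)

#: Dry soil mass per pot (g) used as the reference in soil water content.
DEFAULT_DRY_SOIL_G = 950.0


@dataclass
class VigorRecord:
    """Emergence performance of one seed lot under one condition."""

    lot_id: str
    condition: str
    emergence_pct: float
    sdw_mg: float
    svi: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not 0 <= self.emergence_pct <= 100:
            raise ValidationError(
                f"emergence_pct={self.emergence_pct} outside [0, 100]"
            )
        if self.sdw_mg < 0:
            raise ValidationError(f"sdw_mg must be >= 0 (got {self.sdw_mg})")
        if self.svi < 0:
            raise ValidationError(f"svi must be >= 0 (got {self.svi})")


@dataclass(frozen=True)
class SoilWaterSample:
    """One daily weighing of a reference pot."""

    wet_mass_g: float
    dry_mass_g: float
    swc_pct: float


def soil_water_content(wet_mass_g: float, dry_mass_g: float = DEFAULT_DRY_SOIL_G) -> float:
    """Gravimetric soil water content, % = 100 x (wet - dry) / wet."""
    if dry_mass_g <= 0:
        raise ValidationError(f"dry_mass_g must be > 0 (got {dry_mass_g})")
    if wet_mass_g < dry_mass_g:
        raise ValidationError(
            f"wet mass {wet_mass_g} g below dry mass {dry_mass_g} g: "
            "negative water content"
        )
    return 100.0 * (wet_mass_g - dry_mass_g) / wet_mass_g


def simplified_vigor_index(emergence_pct: float, sdw_mg: float) -> float:
    """SVI = emergence percentage x seedling dry weight (mg/plant)."""
    if emergence_pct < 0 or sdw_mg < 0:
        raise ValidationError("emergence_pct and sdw_mg must be non-negative")
    return emergence_pct * sdw_mg


def summarize_emergence(
    emerged_count: int,
    sown_count: int,
    total_dry_mass_mg: float,
    lot_id: str = "",
    condition: str = "control",
) -> VigorRecord:
    """Per-pot summary: emergence %, mean SDW per emerged plant, and SVI.

    SDW is total dried shoot mass divided by the number of emerged seedlings
    (0 when none emerged).
    """
    if sown_count == 0:
        raise UndefinedStatisticError("sown_count is zero; emergence undefined")
    if not 0 <= emerged_count <= sown_count:
        raise ValidationError(
            f"emerged_count={emerged_count} outside [0, sown_count={sown_count}]"
        )
    emergence_pct = 100.0 * emerged_count / sown_count
    sdw_mg = 0.0 if emerged_count == 0 else total_dry_mass_mg / emerged_count
    return VigorRecord(
        lot_id=lot_id,
        condition=condition,
        emergence_pct=emergence_pct,
        sdw_mg=sdw_mg,
        svi=simplified_vigor_index(emergence_pct, sdw_mg),
    )


def vigor_records_to_frame(records: Iterable[VigorRecord]) -> pd.DataFrame:
    """Tidy table: lot_id, condition, emergence_pct, sdw_mg, svi."""
    return pd.DataFrame(
        [
            {
                "lot_id": r.lot_id,
                "condition": r.condition,
                "emergence_pct": r.emergence_pct,
                "sdw_mg": r.sdw_mg,
                "svi": r.svi,
            }
            for r in records
        ]
    )


def read_vigor_records(path) -> list[VigorRecord]:
    """Read a tidy vigor CSV written by :func:`vigor_records_to_frame`."""
    df = pd.read_csv(path)
    return [
        VigorRecord(
            lot_id=str(r.lot_id),
            condition=str(r.condition),
            emergence_pct=float(r.emergence_pct),
            sdw_mg=float(r.sdw_mg),
            svi=float(r.svi),
        )
        for r in df.itertuples()
    ]
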