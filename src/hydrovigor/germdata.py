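"""Data model and I/O for germination time-course panels.

A germination assay incubates replicate dishes of seeds at a fixed water
potential (imposed osmotically, e.g. with PEG-6000) and records the cumulative
number of germinated seeds at a schedule of observation times.  The tidy
on-disk representation is a long CSV with one row per (lot, water potential,
replicate, observation time):

    lot_id, psi_mpa, replicate, n_sown, time_h, cum_germinated

Water potential is stored in MPa with the field's sign convention (0 for pure
water, negative under osmotic stress); a positive value is rejected rather
than silently negated.  Times are hours; counts are cumulative and
non-decreasing.

The module also ships transcriptions of published lot-level summary tables
(germination percentages by water potential, fitted hydrotime parameters,
pot-emergence vigor measures, and seed-lot provenance) as packaged CSV
resources, loadable by name via :func:`load_paper_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

TIME_COURSE_COLUMNS = [
    "lot_id",
    "psi_mpa",
    "replicate",
    "n_sown",
    "time_h",
    "cum_germinated",
]

FIXTURE_NAMES = ("table1", "table2", "table3", "table5")


@dataclass
class GerminationTimeCourse:
    """Cumulative germination counts for one lot x water potential x replicate.

    Parameters
    ----------
    lot_id : str
        Seed-lot identifier.
    psi : float
        Water potential of the incubation medium, MPa (<= 0).
    replicate : str
        Replicate (dish) identifier.
    n_sown : int
        Number of seeds sown in the dish.
    times_h : ndarray
        Strictly increasing observation times, hours (> 0).
    cum_germinated : ndarray
        Cumulative germinated count at each observation time.  Float-valued
        so that noiseless expected (fractional) counts can be represented;
        observed data are integers.
    """

    lot_id: str
    psi: float
    replicate: str
    n_sown: int
    times_h: np.ndarray
    cum_germinated: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.cum_germinated = np.asarray(self.cum_germinated, dtype=float)

    @property
    def fractions(self) -> np.ndarray:
        """Cumulative germinated fraction g(t) = count / n_sown."""
        return self.cum_germinated / self.n_sown

    @property
    def final_count(self) -> float:
        return float(self.cum_germinated[-1])


@dataclass
class SeedLotMeta:
    """Provenance and physical descriptors of one seed lot."""

    lot_id: str
    production_year: int
    storage_years: float
    seed_moisture_pct: float
    thousand_seed_weight_g: float
    hard_seed_pct: float

    def __post_init__(self) -> None:
        if self.storage_years < 0:
            raise ValidationError(f"lot {self.lot_id}: storage_years must be >= 0")
        for name in ("seed_moisture_pct", "hard_seed_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"lot {self.lot_id}: {name}={v} outside [0, 100]")


@dataclass
class FixtureTable:
    """A packaged transcription of one published lot-level table."""

    name: str
    df: pd.DataFrame = field(repr=False)

    @property
    def rows(self) -> pd.DataFrame:
        return self.df


def validate_time_course(tc: GerminationTimeCourse) -> GerminationTimeCourse:
    """Check every invariant of a time course; return it unchanged if valid.

    Raises
    ------
    ValidationError
        Naming the violated field and offending index.
    """
    label = f"lot={tc.lot_id} psi={tc.psi} rep={tc.replicate}"
    if tc.psi > 0:
        raise ValidationError(f"{label}: psi must be <= 0 MPa (got {tc.psi})")
    if tc.n_sown <= 0:
        raise ValidationError(f"{label}: n_sown must be positive (got {tc.n_sown})")
    if tc.times_h.size == 0:
        raise ValidationError(f"{label}: at least one observation required")
    if tc.times_h.size != tc.cum_germinated.size:
        raise ValidationError(
            f"{label}: times_h ({tc.times_h.size}) and cum_germinated "
            f"({tc.cum_germinated.size}) differ in length"
        )
    if tc.times_h[0] <= 0:
        raise ValidationError(f"{label}: times_h must be > 0 (index 0)")
    bad = np.nonzero(np.diff(tc.times_h) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{label}: times_h not strictly increasing at index {bad[0] + 1}"
        )
    if np.any(tc.cum_germinated < 0):
        i = int(np.argmax(tc.cum_germinated < 0))
        raise ValidationError(f"{label}: negative cum_germinated at index {i}")
    over = np.nonzero(tc.cum_germinated > tc.n_sown)[0]
    if over.size:
        raise ValidationError(
            f"{label}: cum_germinated exceeds n_sown={tc.n_sown} at index {over[0]}"
        )
    dec = np.nonzero(np.diff(tc.cum_germinated) < 0)[0]
    if dec.size:
        raise ValidationError(
            f"{label}: cum_germinated decreases at index {dec[0] + 1}"
        )
    return tc


def read_time_courses(path: str | Path) -> list[GerminationTimeCourse]:
    """Read a tidy long CSV into validated time courses.

    One :class:`GerminationTimeCourse` is returned per (lot_id, psi_mpa,
    replicate) group, with observations sorted by time.
    """
    df = pd.read_csv(path)
    missing = [c for c in TIME_COURSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    courses = []
    for (lot, psi, rep), g in df.groupby(["lot_id", "psi_mpa", "replicate"], sort=True):
        g = g.sort_values("time_h")
        n_sown = g["n_sown"].unique()
        if n_sown.size != 1:
            raise ValidationError(
                f"lot={lot} psi={psi} rep={rep}: n_sown not constant within group"
            )
        tc = GerminationTimeCourse(
            lot_id=str(lot),
            psi=float(psi),
            replicate=str(rep),
            n_sown=int(n_sown[0]),
            times_h=g["time_h"].to_numpy(dtype=float),
            cum_germinated=g["cum_germinated"].to_numpy(dtype=float),
        )
        courses.append(validate_time_course(tc))
    return courses


def time_courses_to_frame(courses: Iterable[GerminationTimeCourse]) -> pd.DataFrame:
    """Flatten time courses back to the tidy long layout."""
    records = []
    for tc in courses:
        for t, c in zip(tc.times_h, tc.cum_germinated):
            records.append(
                {
                    "lot_id": tc.lot_id,
                    "psi_mpa": round(tc.psi, 4),
                    "replicate": tc.replicate,
                    "n_sown": tc.n_sown,
                    "time_h": t,
                    "cum_germinated": c,
                }
            )
    return pd.DataFrame(records, columns=TIME_COURSE_COLUMNS)


def write_time_courses(courses: Iterable[GerminationTimeCourse], path: str | Path) -> None:
    """Write time courses as the tidy long CSV read by :func:`read_time_courses`."""
    time_courses_to_frame(courses).to_csv(path, index=False)


def load_paper_fixture(name: str) -> FixtureTable:
    """Load a packaged lot-level table transcription by name.

    Available names: ``table1`` (germination % by lot and water potential),
    ``table2`` (fitted hydrotime parameters per lot), ``table3``
    (pot-emergence vigor measures per lot and stress condition), ``table5``
    (lot provenance).  Cell values equal the published means exactly; the
    tables store 3-replicate averages, not replicate-level raw data.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    with resources.files("hydrovigor.data").joinpath(f"{name}.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    return FixtureTable(name=name, df=df)


def load_seed_lot_meta() -> list[SeedLotMeta]:
    """Seed-lot provenance records from the packaged table5 fixture."""
    df = load_paper_fixture("table5").df
    return [
        SeedLotMeta(
            lot_id=str(r.lot_id),
            production_year=int(r.production_year),
            storage_years=float(r.storage_years),
            seed_moisture_pct=float(r.seed_moisture_pct),
            thousand_seed_weight_g=float(r.thousand_seed_weight_g),
            hard_seed_pct=float(r.hard_seed_pct),
        )
        for r in df.itertuples()
    ]


def group_by_lot(
    courses: Iterable[GerminationTimeCourse],
) -> dict[str, list[GerminationTimeCourse]]:
    """Group time courses by lot_id, preserving input order within lots."""
    out: dict[str, list[GerminationTimeCourse]] = {}
    for tc in courses:
        out.setdefault(tc.lot_id, []).append(tc)
    return out
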