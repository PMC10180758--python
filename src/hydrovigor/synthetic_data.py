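"""Synthetic germination panels and vigor tables with known truth.

The generator emulates the design of a standard multi-lot hydrotime assay:
12 seed lots x 5 water potentials {0.0, -0.2, -0.4, -0.6, -0.8} MPa x
3 replicate dishes of 30 seeds, observed every 8 h for the first 4 days and
then daily to a 504-h (21-day) censoring horizon.  Per-lot true parameters
default to the fitted values shipped in the ``table2`` fixture, so simulated
panels have realistic spreads of theta_H (8.8-14.8 MPa.h), psi_b50 (-0.52 to
-0.28 MPa) and sigma_phib (0.27-0.33 MPa).

Two noise modes are provided:

* ``noiseless`` — the expected cumulative count n * g(t) at each scheduled
  time, rounded half-up to an integer (or kept fractional for oracle use);
* ``binomial`` — each seed draws its base water potential from
  Normal(psi_b50, sigma_phib^2) and germinates at theta_H / (psi - psi_b)
  when psi exceeds its threshold, never otherwise; counts accumulate on the
  observation schedule.  This is exact sampling from the model, so empirical
  fractions are Binomial(n, g(t)) at every scheduled time.

Lot-level emergence tables are generated from a linear dependence of
emergence percentage (and seedling dry weight) on psi_b50 plus Gaussian
noise, mirroring the strong negative psi_b50-vigor association the analysis
is designed to detect.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .germdata import GerminationTimeCourse, load_paper_fixture
from .hydrotime_fit import HydrotimeParams, predict_fraction
from .vigor_metrics import VigorRecord, simplified_vigor_index

#: Water potentials (MPa) of the standard germination assay.
DEFAULT_PSI_LEVELS = (0.0, -0.2, -0.4, -0.6, -0.8)

NoiseMode = Literal["noiseless", "binomial"]


@dataclass(frozen=True)
class ObservationSchedule:
    """Censored observation times (hours) of a germination assay."""

    times_h: tuple[float, ...]
    horizon_h: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h)
        if t.size == 0 or t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times_h must be strictly increasing and > 0")
        if np.any(t > self.horizon_h):
            raise ValidationError("all times must be <= horizon_h")


def default_schedule() -> ObservationSchedule:
    """Counts every 8 h to 96 h, then every 24 h to the 504-h horizon (29 points)."""
    times = tuple(float(t) for t in range(8, 97, 8)) + tuple(
        float(t) for t in range(120, 505, 24)
    )
    return ObservationSchedule(times_h=times, horizon_h=504.0)


@dataclass
class SimulationConfig:
    """Full panel design: per-lot truths, assay layout, noise mode, seed."""

    true_params: Mapping[str, HydrotimeParams]
    psi_levels: Sequence[float] = DEFAULT_PSI_LEVELS
    n_seeds: int = 30
    n_replicates: int = 3
    noise_mode: NoiseMode = "binomial"
    rng_seed: int = 0
    schedule: ObservationSchedule = field(default_factory=default_schedule)

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValidationError("n_seeds must be >= 1")
        if any(p > 0 for p in self.psi_levels):
            raise ValidationError("psi_levels must be <= 0 MPa")


def default_lot_params() -> dict[str, HydrotimeParams]:
    """Per-lot hydrotime truths from the packaged table2 fixture."""
    df = load_paper_fixture("table2").df
    return {
        str(r.lot_id): HydrotimeParams(
            theta_H=float(r.theta_H_MPah),
            psi_b50=float(r.psi_b50_MPa),
            sigma_phib=float(r.sigma_phib),
            lot_id=str(r.lot_id),
        )
        for r in df.itertuples()
    }


def _cell_seed(rng_seed: int, lot_id: str, psi: float, replicate: str) -> int:
    """Deterministic per-cell seed: CRC-32 of the (lot, psi, replicate) key.

    Hash-based splitting makes each cell's stream independent of iteration
    order; psi is keyed at 4-decimal precision to match the stored convention.
    """
    key = f"{rng_seed}|{lot_id}|{psi:.4f}|{replicate}".encode()
    return zlib.crc32(key)


def simulate_time_course(
    true_params: HydrotimeParams,
    psi: float,
    n_seeds: int,
    schedule: ObservationSchedule | None = None,
    noise_mode: NoiseMode = "noiseless",
    rng_seed: int | None = None,
    lot_id: str | None = None,
    replicate: str = "r1",
    fractional: bool = False,
) -> GerminationTimeCourse:
    """Simulate one dish on the observation schedule.

    Noiseless mode records round(n * g(t)) at each time (round half-up), or
    the exact expected fraction times n when ``fractional`` is true — the
    latter equals :func:`~hydrovigor.hydrotime_fit.predict_fraction` by
    construction and serves as the oracle in tests.  Binomial mode draws one
    base water potential per seed from Normal(psi_b50, sigma_phib^2); a seed
    with threshold at or above psi never germinates.
    """
    if psi > 0:
        raise ValidationError(f"psi must be <= 0 MPa (got {psi})")
    if schedule is None:
        schedule = default_schedule()
    times = np.asarray(schedule.times_h, dtype=float)
    if noise_mode == "noiseless":
        g = predict_fraction(true_params, psi, times)
        expected = n_seeds * np.asarray(g)
        counts = expected if fractional else np.floor(expected + 0.5)
    elif noise_mode == "binomial":
        rng = np.random.default_rng(rng_seed)
        psi_b = rng.normal(true_params.psi_b50, true_params.sigma_phib, n_seeds)
        with np.errstate(divide="ignore"):
            t_germ = np.where(
                psi_b < psi, true_params.theta_H / (psi - psi_b), math.inf
            )
        counts = (t_germ[None, :] <= times[:, None]).sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    return GerminationTimeCourse(
        lot_id=lot_id if lot_id is not None else (true_params.lot_id or "sim"),
        psi=float(psi),
        replicate=replicate,
        n_sown=n_seeds,
        times_h=times,
        cum_germinated=counts,
    )


def simulate_lot_panel(config: SimulationConfig) -> list[GerminationTimeCourse]:
    """One time course per lot x water potential x replicate."""
    courses = []
    for lot_id, params in config.true_params.items():
        for psi in config.psi_levels:
            for r in range(1, config.n_replicates + 1):
                rep = f"r{r}"
                courses.append(
                    simulate_time_course(
                        params,
                        psi,
                        config.n_seeds,
                        config.schedule,
                        noise_mode=config.noise_mode,
                        rng_seed=_cell_seed(config.rng_seed, lot_id, psi, rep),
                        lot_id=lot_id,
                        replicate=rep,
                    )
                )
    return courses


def simulate_emergence_panel(
    params_by_lot: Mapping[str, HydrotimeParams],
    slope: float = -118.0,
    intercept: float = 21.5,
    noise_sd: float = 5.0,
    rng_seed: int = 0,
    condition: str = "control",
    sdw_slope: float = -65.0,
    sdw_intercept: float = 21.6,
    sdw_noise_sd: float = 3.0,
) -> list[VigorRecord]:
    """Lot-level emergence records linearly driven by psi_b50.

    emergence_pct = clamp(intercept + slope * psi_b50 + N(0, noise_sd^2), 0, 100)
    and SDW analogously (clamped below at 0); SVI is their product.  The
    default slopes and intercepts interpolate the control-condition extremes
    of the vigor fixture (lowest- and highest-vigor lots), so the default
    panel reproduces a strongly negative psi_b50-emergence association.
    """
    if noise_sd < 0 or sdw_noise_sd < 0:
        raise ValidationError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(rng_seed)
    records = []
    for lot_id, params in params_by_lot.items():
        emergence = intercept + slope * params.psi_b50 + rng.normal(0.0, noise_sd)
        emergence = float(np.clip(emergence, 0.0, 100.0))
        sdw = sdw_intercept + sdw_slope * params.psi_b50 + rng.normal(0.0, sdw_noise_sd)
        sdw = float(max(sdw, 0.0))
        records.append(
            VigorRecord(
                lot_id=lot_id,
                condition=condition,
                emergence_pct=emergence,
                sdw_mg=sdw,
                svi=simplified_vigor_index(emergence, sdw),
            )
        )
    return records
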