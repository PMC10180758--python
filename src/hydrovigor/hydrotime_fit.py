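"""The hydrotime population-threshold model and its probit estimation.

Model
-----
Each seed in a lot germinates once it has accumulated a fixed amount of
hydrotime theta_H (MPa.h): germination of fraction g occurs at time t_g
satisfying

    theta_H = (psi - psi_b(g)) * t_g,

where psi is the water potential of the medium (MPa) and psi_b(g) is the base
(threshold) water potential of the g-th percentile seed.  psi_b varies across
seeds following a normal distribution with median psi_b50 and standard
deviation sigma_phib, so the cumulative germinated fraction at time t is

    g(t; psi) = Phi((psi - theta_H/t - psi_b50) / sigma_phib),

with Phi the standard normal CDF.  A seed whose threshold lies at or above
the ambient psi never germinates, which caps the time course below 1 at
reduced water potentials.

Estimation
----------
For a trial value of theta_H every usable observation (psi, t, g) with
0 < g < 1 becomes a point (x, probit(g)) with x = psi - theta_H/t; under the
model these points are collinear:

    probit(g) = (x - psi_b50) / sigma_phib.

Repeated probit analysis profiles theta_H: for each candidate, ordinary least
squares of probit(g) on x gives a candidate (psi_b50, sigma_phib) and an r2;
theta_H is chosen to maximize that r2 (coarse log-spaced grid, then
golden-section refinement).  Replicates are pooled by summing counts before
fractions are formed, matching the convention of fitting replicate-averaged
time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    FitFailureError,
    IdentifiabilityError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .germdata import GerminationTimeCourse

#: Sentinel returned by :func:`time_to_fraction` for fractions that never
#: germinate at the given water potential (threshold not exceeded).
NEVER = math.inf


@dataclass
class HydrotimeParams:
    """Fitted (or true) hydrotime parameters for one seed lot.

    theta_H is in MPa.h, psi_b50 and sigma_phib in MPa.  ``r2`` is the model
    goodness of fit on the fraction scale (squared correlation of observed and
    predicted cumulative fractions over all observations); it is NaN for
    parameter sets that have not been scored against data, e.g. simulation
    truths.
    """

    theta_H: float
    psi_b50: float
    sigma_phib: float
    r2: float = math.nan
    lot_id: str | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if self.theta_H <= 0:
            raise ValueError(f"theta_H must be > 0 (got {self.theta_H})")
        if self.sigma_phib <= 0:
            raise ValueError(f"sigma_phib must be > 0 (got {self.sigma_phib})")
        if not math.isnan(self.r2) and not 0 <= self.r2 <= 1:
            raise ValueError(f"r2 must be in [0, 1] (got {self.r2})")


@dataclass(frozen=True)
class ProbitPoint:
    """One usable observation on the probit-linearized scale."""

    psi: float
    time_h: float
    fraction: float
    predictor_x: float  # psi - theta_H / time_h, MPa
    probit_g: float  # inverse normal CDF of fraction


@dataclass(frozen=True)
class ThetaSearchConfig:
    """Settings for the theta_H profile search and point filtering.

    The default bracket [0.5, 200] MPa.h comfortably spans hydrotime
    constants reported for small-seeded legumes (order 10 MPa.h); 200
    log-spaced grid points followed by golden-section refinement to
    ``tol`` = 1e-3 MPa.h resolve the profile maximum well below reporting
    precision.
    """

    theta_lo: float = 0.5
    theta_hi: float = 200.0
    tol: float = 1e-3
    min_points: int = 3
    min_distinct_psi: int = 2
    n_grid: int = 200
    continuity_correction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.theta_lo < self.theta_hi:
            raise ValueError("need 0 < theta_lo < theta_hi")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if self.min_distinct_psi < 2:
            raise ValueError("min_distinct_psi must be >= 2")


def _pool_observations(
    courses: Sequence[GerminationTimeCourse], continuity_correction: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool replicates by summing counts at each (psi, time).

    Returns (psi, time_h, fraction) arrays, one entry per distinct
    (psi, time) cell.  With the continuity correction fractions are
    (k + 0.5) / (n + 1), keeping boundary counts usable for the probit.
    """
    cells: dict[tuple[float, float], list[float]] = {}
    for tc in courses:
        for t, c in zip(tc.times_h, tc.cum_germinated):
            key = (tc.psi, float(t))
            if key in cells:
                cells[key][0] += float(c)
                cells[key][1] += tc.n_sown
            else:
                cells[key] = [float(c), float(tc.n_sown)]
    psi = np.array([k[0] for k in cells])
    t = np.array([k[1] for k in cells])
    k = np.array([v[0] for v in cells.values()])
    n = np.array([v[1] for v in cells.values()])
    if continuity_correction:
        frac = (k + 0.5) / (n + 1.0)
    else:
        frac = k / n
    return psi, t, frac


def _usable(
    psi: np.ndarray, t: np.ndarray, frac: np.ndarray, config: ThetaSearchConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = (frac > 0.0) & (frac < 1.0)
    psi_u, t_u, frac_u = psi[mask], t[mask], frac[mask]
    if psi_u.size < config.min_points:
        raise InsufficientDataError(
            f"only {psi_u.size} observations with fraction strictly inside (0, 1); "
            f"need at least {config.min_points}"
        )
    if np.unique(psi_u).size < config.min_distinct_psi:
        raise IdentifiabilityError(
            f"usable observations span {np.unique(psi_u).size} distinct water "
            f"potential(s); need at least {config.min_distinct_psi}"
        )
    return psi_u, t_u, frac_u


def build_probit_points(
    courses: Sequence[GerminationTimeCourse],
    theta_H: float,
    config: ThetaSearchConfig = ThetaSearchConfig(),
) -> list[ProbitPoint]:
    """Probit-linearized points for one lot at a trial theta_H.

    Replicates are pooled by summed counts; fractions of exactly 0 or 1 are
    excluded (the probit is undefined there) unless the continuity correction
    is enabled in ``config``.
    """
    if theta_H <= 0:
        raise ValueError(f"theta_H must be > 0 (got {theta_H})")
    psi, t, frac = _pool_observations(courses, config.continuity_correction)
    psi, t, frac = _usable(psi, t, frac, config)
    x = psi - theta_H / t
    z = stats.norm.ppf(frac)
    return [
        ProbitPoint(psi=float(p), time_h=float(ti), fraction=float(f),
                    predictor_x=float(xi), probit_g=float(zi))
        for p, ti, f, xi, zi in zip(psi, t, frac, x, z)
    ]


def probit_regression_at_theta(
    points: Sequence[ProbitPoint],
) -> tuple[float, float, float]:
    """OLS of probit(g) on x = psi - theta_H/t; returns (psi_b50, sigma_phib, r2).

    The model line is probit(g) = (x - psi_b50) / sigma_phib, so the slope s
    must be positive; sigma_phib = 1/s and psi_b50 = -intercept/s.  ``r2``
    here is the squared correlation on the probit scale (the profile
    criterion), not the fraction-scale goodness of fit.
    """
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 probit points (got {len(points)})")
    x = np.array([p.predictor_x for p in points])
    z = np.array([p.probit_g for p in points])
    if np.unique(x).size < 2:
        raise IdentifiabilityError("zero variance in the probit predictor x")
    sxx = np.sum((x - x.mean()) ** 2)
    sxz = np.sum((x - x.mean()) * (z - z.mean()))
    slope = sxz / sxx
    if slope <= 0:
        raise FitFailureError(
            "non-positive probit slope: germination does not increase with "
            "psi - theta_H/t, inconsistent with the hydrotime model"
        )
    intercept = z.mean() - slope * x.mean()
    szz = np.sum((z - z.mean()) ** 2)
    r2 = 1.0 if szz == 0 else float(sxz**2 / (sxx * szz))
    return float(-intercept / slope), float(1.0 / slope), min(r2, 1.0)


def _profile_r2(
    psi: np.ndarray, t: np.ndarray, z: np.ndarray, thetas: np.ndarray
) -> np.ndarray:
    """Signed-slope-guarded probit r2 for each candidate theta (vectorized).

    Entries where the probit slope would be non-positive are -inf so they can
    never win the profile search.
    """
    x = psi[None, :] - thetas[:, None] / t[None, :]  # (n_theta, n_pts)
    xc = x - x.mean(axis=1, keepdims=True)
    zc = z - z.mean()
    sxz = xc @ zc
    sxx = np.einsum("ij,ij->i", xc, xc)
    szz = float(zc @ zc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sxx > 0, sxz**2 / (sxx * szz), -np.inf)
    return np.where(sxz > 0, r2, -np.inf)


def _golden_section_max(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximization of a scalar function on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:  # ties toward smaller theta
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_hydrotime(
    courses: Sequence[GerminationTimeCourse],
    config: ThetaSearchConfig = ThetaSearchConfig(),
) -> HydrotimeParams:
    """Estimate (theta_H, psi_b50, sigma_phib) for one lot by repeated probit analysis.

    theta_H maximizes the probit-regression r2 over a coarse log-spaced grid
    on [theta_lo, theta_hi] followed by golden-section refinement to
    ``config.tol``; the grid pass guards against local maxima on flat or
    multi-modal profiles, with ties broken toward smaller theta_H.  The
    returned ``r2`` is the fraction-scale goodness of fit
    (:func:`goodness_of_fit`), the scale on which fitted time courses are
    conventionally reported.
    """
    psi_all, t_all, frac_all = _pool_observations(courses, config.continuity_correction)
    psi, t, frac = _usable(psi_all, t_all, frac_all, config)
    z = stats.norm.ppf(frac)

    thetas = np.geomspace(config.theta_lo, config.theta_hi, config.n_grid)
    prof = _profile_r2(psi, t, z, thetas)
    if not np.any(np.isfinite(prof)):
        raise FitFailureError(
            "no candidate theta_H yields a positive probit slope; data are "
            "inconsistent with the hydrotime model"
        )
    i = int(np.argmax(prof))  # first (smallest-theta) winner on ties
    lo = thetas[max(i - 1, 0)]
    hi = thetas[min(i + 1, thetas.size - 1)]

    def f(theta: float) -> float:
        return float(_profile_r2(psi, t, z, np.array([theta]))[0])

    theta_hat = _golden_section_max(f, lo, hi, config.tol)
    points = build_probit_points(courses, theta_hat, config)
    psi_b50, sigma_phib, _ = probit_regression_at_theta(points)
    params = HydrotimeParams(
        theta_H=theta_hat,
        psi_b50=psi_b50,
        sigma_phib=sigma_phib,
        lot_id=courses[0].lot_id if courses else None,
        n_points=len(points),
    )
    try:
        r2 = goodness_of_fit(params, courses)
    except UndefinedStatisticError:
        r2 = math.nan
    return replace(params, r2=r2)


def predict_fraction(
    params: HydrotimeParams, psi: float, time_h: float | np.ndarray
) -> float | np.ndarray:
    """Cumulative germinated fraction g(t) = Phi((psi - theta_H/t - psi_b50)/sigma_phib).

    Non-decreasing in both ``time_h`` and ``psi``; tends to the predicted
    maximum germination as t -> infinity.
    """
    t = np.asarray(time_h, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time_h must be > 0")
    g = stats.norm.cdf((psi - params.theta_H / t - params.psi_b50) / params.sigma_phib)
    return float(g) if np.isscalar(time_h) else g


def predicted_max_germination(params: HydrotimeParams, psi: float) -> float:
    """Asymptotic germinated fraction Phi((psi - psi_b50)/sigma_phib).

    This is the fraction of seeds whose base water potential lies below the
    ambient psi; exactly 0.5 at psi = psi_b50.
    """
    return float(stats.norm.cdf((psi - params.psi_b50) / params.sigma_phib))


def time_to_fraction(params: HydrotimeParams, psi: float, g: float) -> float:
    """Time (h) for fraction ``g`` to germinate: t_g = theta_H / (psi - psi_b(g)).

    psi_b(g) = psi_b50 + sigma_phib * probit(g).  When psi <= psi_b(g) the
    g-th percentile seed never exceeds its threshold and the :data:`NEVER`
    sentinel (inf) is returned instead of raising.
    """
    if not 0 < g < 1:
        raise ValueError(f"g must be in (0, 1) (got {g})")
    psi_b_g = params.psi_b50 + params.sigma_phib * stats.norm.ppf(g)
    if psi <= psi_b_g:
        return NEVER
    return params.theta_H / (psi - psi_b_g)


def goodness_of_fit(
    params: HydrotimeParams, courses: Sequence[GerminationTimeCourse]
) -> float:
    """Fraction-scale r2: squared correlation of observed vs predicted fractions.

    Observations are replicate-pooled and all (psi, time) cells contribute,
    including fractions of exactly 0 and 1 (no probit transform is involved).
    """
    psi, t, frac = _pool_observations(courses)
    if np.allclose(frac, frac[0]):
        raise UndefinedStatisticError("observed fractions are constant; r2 undefined")
    pred = stats.norm.cdf(
        (psi - params.theta_H / t - params.psi_b50) / params.sigma_phib
    )
    r = np.corrcoef(frac, pred)[0, 1]
    return float(r**2)
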