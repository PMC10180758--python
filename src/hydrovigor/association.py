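"""Correlation and regression screening of hydrotime parameters against vigor.

The screening question is which of the three hydrotime parameters — theta_H,
psi_b50, sigma_phib — tracks lot-to-lot differences in germination and
seedling-emergence performance.  Each parameter is paired with each vigor
variable across seed lots; Pearson r with a two-sided t-based p-value (and
optionally the OLS line) is reported per pair, assembled into a
parameters-by-variables matrix.

Percentage variables enter untransformed: the arcsine transform customary
for ANOVA of proportions is not applied to correlation inputs, and lot-level
germination percentage is summarized as the unweighted mean over the assay's
water-potential levels (which equals the grand replicate mean under a
balanced design).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError
from .germdata import load_paper_fixture

#: Parameter column labels used throughout tabular output.
PARAMETER_COLUMNS = {
    "theta_H": "theta_H_MPah",
    "psi_b50": "psi_b50_MPa",
    "sigma_phib": "sigma_phib",
}


@dataclass(frozen=True)
class CorrelationEntry:
    """Pearson correlation between one parameter and one vigor variable."""

    x_name: str
    y_name: str
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line y = slope * x + intercept."""

    slope: float
    intercept: float
    r2: float


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise InsufficientDataError(
            f"length mismatch: x has {x.size}, y has {y.size}"
        )
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 pairs (got {x.size})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y"
) -> CorrelationEntry:
    """Pearson r with the two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    res = stats.pearsonr(x, y)
    return CorrelationEntry(
        x_name=x_name, y_name=y_name, r=float(res.statistic),
        p=float(res.pvalue), n=int(x.size),
    )


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS fit of y on x; r2 is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def correlation_table(
    params: pd.DataFrame,
    variables: pd.DataFrame,
    holm: bool = False,
) -> pd.DataFrame:
    """Parameter-by-variable Pearson correlation matrix in tidy form.

    ``params`` must be indexed by lot_id with the three parameter columns of
    :data:`PARAMETER_COLUMNS`; ``variables`` is indexed by lot_id with one
    column per vigor/germination variable.  Lots missing either member of a
    pair are dropped pairwise and the remaining pair count recorded in ``n``.
    Variables with zero variance yield a flagged row (r and p NaN) rather
    than failing the whole table.  With ``holm=True`` a Holm-adjusted p
    column is appended (raw p-values are always reported).
    """
    common = params.index.intersection(variables.index)
    if common.size < 3:
        raise InsufficientDataError(
            f"only {common.size} lots common to parameters and variables; need >= 3"
        )
    rows = []
    for pname, pcol in PARAMETER_COLUMNS.items():
        for var in variables.columns:
            joined = pd.concat(
                [params.loc[common, pcol], variables.loc[common, var]], axis=1
            ).dropna()
            try:
                entry = pearson_correlation(
                    joined.iloc[:, 0], joined.iloc[:, 1], pname, var
                )
                rows.append(
                    {
                        "parameter": pname,
                        "variable": var,
                        "r": entry.r,
                        "p": entry.p,
                        "n": entry.n,
                        "undefined": False,
                    }
                )
            except (UndefinedStatisticError, InsufficientDataError):
                rows.append(
                    {
                        "parameter": pname,
                        "variable": var,
                        "r": np.nan,
                        "p": np.nan,
                        "n": len(joined),
                        "undefined": True,
                    }
                )
    table = pd.DataFrame(rows)
    if holm:
        defined = ~table["undefined"]
        adj = np.full(len(table), np.nan)
        adj[defined.to_numpy()] = holm_adjust(table.loc[defined, "p"])
        table["p_holm"] = adj
    return table


def lot_mean_germination(table1: pd.DataFrame | None = None) -> pd.Series:
    """Per-lot germination percentage: unweighted mean over water potentials."""
    if table1 is None:
        table1 = load_paper_fixture("table1").df
    s = table1.groupby("lot_id")["germination_pct"].mean()
    s.index = s.index.astype(str)
    return s.rename("germination_pct")


def paper_variable_table() -> pd.DataFrame:
    """Lot-indexed vigor/germination variables from the packaged fixtures.

    Columns: ``germination_pct`` (mean over the five water potentials of the
    germination fixture) and ``<condition>__<measure>`` for each pot stress
    condition and measure in the vigor fixture.  Published SVI cells are used
    as printed, never recomputed from the printed means of their factors.
    """
    sgp = lot_mean_germination()
    t3 = load_paper_fixture("table3").df
    wide = t3.pivot(index="lot_id", columns="condition",
                    values=["emergence_pct", "sdw_mg", "svi"])
    wide.columns = [f"{cond}__{measure}" for measure, cond in wide.columns]
    wide.index = wide.index.astype(str)
    return pd.concat([sgp, wide], axis=1)


def paper_parameter_table() -> pd.DataFrame:
    """Lot-indexed fitted hydrotime parameters from the packaged fixture."""
    df = load_paper_fixture("table2").df.set_index("lot_id")
    df.index = df.index.astype(str)
    return df


def load_reference_correlations() -> pd.DataFrame:
    """Published correlation cells reproducible from the packaged fixtures."""
    with resources.files("hydrovigor.data").joinpath("table4_reference.csv").open(
        "rb"
    ) as fh:
        return pd.read_csv(fh, dtype={"p_printed": str})


def reproduce_paper_correlations(tol: float = 0.005) -> pd.DataFrame:
    """Recompute every fixture-derivable published correlation cell.

    Returns one row per cell with the recomputed r, the printed r, their
    difference, and a boolean ``within_tol``.  Cells involving variables not
    printed at lot level (germination rate/index, field sowings) are not in
    the reference and are not attempted.
    """
    params = paper_parameter_table()
    variables = paper_variable_table()
    computed = correlation_table(params, variables)
    computed["key"] = computed["variable"]
    ref = load_reference_correlations()
    ref["key"] = np.where(
        ref["condition"] == "germination_test",
        ref["variable"],
        ref["condition"] + "__" + ref["variable"],
    )
    merged = ref.merge(
        computed[["parameter", "key", "r", "p", "n"]],
        on=["parameter", "key"],
        how="left",
        validate="one_to_one",
    )
    merged["r_diff"] = merged["r"] - merged["r_printed"]
    merged["within_tol"] = merged["r_diff"].abs() <= tol
    return merged.drop(columns="key")
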