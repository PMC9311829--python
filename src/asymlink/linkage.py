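"""Linear models linking pooled chemical body burdens to individual FA.

Chemical concentrations are measured on *pooled* samples (many
individuals homogenized into one measurement), so every member of a
pool shares its pool's concentration as a covariate: the number of
distinct covariate values equals the number of pools, and effective
replication for the chemical term is at pool level.  The models are
ordinary least squares,

    FA ~ inbreeding index + analyte concentration [+ location],

reporting per-predictor t-values (t1 inbreeding, t2 analyte, t3
location), adjusted R^2, and a Kolmogorov-Smirnov normality check of
the standardized residuals.  Responses that fail the residual check
are re-expressed once with Tukey's ladder of powers (the power lambda
maximizing the Shapiro-Wilk statistic over a fine grid) and the models
re-fit.

A full battery crosses every FA response with both inbreeding indices
(MLH and d^2) and each of the seven analytes (Hg and the six indicator
PCB congeners).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ANALYTES",
    "PooledBurdenError",
    "expand_pools",
    "tukey_transform",
    "LinkageModelResult",
    "fit_linkage_model",
    "residual_diagnostics",
    "run_model_battery",
]

#: analyte order fixed as printed in the study tables
ANALYTES = ["Hg", "PCB28", "PCB52", "PCB101", "PCB138", "PCB153", "PCB180"]

BURDEN_COLUMNS = ["pool_id", "location", "taxon", "analyte", "conc_ugkg_fw"]


class PooledBurdenError(ValueError):
    """Invalid pooled-burden table or membership map."""


def expand_pools(burdens: pd.DataFrame, membership) -> pd.DataFrame:
    """Expand pool-level concentrations to per-individual covariates.

    ``burdens`` is long-format with columns pool_id, location, taxon,
    analyte, conc_ugkg_fw; ``membership`` maps individual id to
    pool_id (a Series, dict, or DataFrame with columns individual and
    pool_id).  Every individual receives its pool's concentration for
    each analyte.  Individuals mapping to no pool raise an error that
    lists them; the mapping is insensitive to row order.
    """
    missing_cols = [c for c in ("pool_id", "analyte", "conc_ugkg_fw") if c not in burdens.columns]
    if missing_cols:
        raise PooledBurdenError(f"burden table lacks columns {missing_cols}")
    if (burdens["conc_ugkg_fw"] < 0).any():
        raise PooledBurdenError("concentrations must be non-negative")
    if isinstance(membership, pd.DataFrame):
        membership = membership.set_index("individual")["pool_id"]
    membership = pd.Series(membership)
    wide = burdens.pivot_table(
        index="pool_id", columns="analyte", values="conc_ugkg_fw", aggfunc="first"
    )
    unmapped = sorted(membership.index[~membership.isin(wide.index)])
    if unmapped:
        raise PooledBurdenError(f"individuals mapped to unknown or no pool: {unmapped}")
    out = wide.loc[membership.to_numpy()].set_index(membership.index)
    out.columns.name = None
    out.index.name = "individual"
    n_pools = membership.nunique()
    if n_pools <= 1:
        warnings.warn("single pool: analyte covariates are constant (rank-deficient downstream)")
    out.attrs["n_pools"] = int(n_pools)
    return out


_DEFAULT_GRID = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.025), 3)


def tukey_transform(values, lambda_grid=None) -> tuple[float, np.ndarray]:
    """Tukey's ladder-of-powers re-expression chosen by normality.

    For each lambda on the grid the data are transformed as
    ``x**lambda`` (lambda > 0), ``log(x)`` (lambda = 0) or
    ``-x**lambda`` (lambda < 0, sign flip preserving order); the
    lambda maximizing the Shapiro-Wilk W statistic is returned with the
    transformed vector.  Non-positive inputs are shifted up by
    ``min + eps`` first (logged).  The transform is strictly monotone,
    so rank order is always preserved.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("constant input: no normalizing transformation is defined")
    if x.min() <= 0:
        shift = -x.min() + 1e-6 * max(np.ptp(x), 1.0)
        warnings.warn(f"non-positive values; shifting by {shift:.3g} before the power ladder")
        x = x + shift
    grid = _DEFAULT_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)

    def apply(lam):
        if lam > 0:
            return x**lam
        if lam == 0:
            return np.log(x)
        return -(x**lam)

    best_lam, best_w, best_t = None, -np.inf, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lam in grid:
            t = apply(lam)
            if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
                continue
            w = stats.shapiro(t).statistic
            if w > best_w:
                best_lam, best_w, best_t = float(lam), float(w), t
    if best_lam is None:
        raise ValueError("no lambda on the grid produced a finite transform")
    return best_lam, best_t


@dataclass
class LinkageModelResult:
    """One fitted FA ~ inbreeding + analyte [+ location] model."""

    formula: str
    response: str
    index_name: str
    analyte: str
    n: int
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2_adj: float
    ks_p: float
    lam: float | None  # power used on the response, None = untransformed
    n_analyte_levels: int
    rank_deficient: bool = False
    collinear: tuple = ()
    note: str = ""

    @property
    def t1(self) -> float:
        return float(self.tvalues.get(self.index_name, np.nan))

    @property
    def t2(self) -> float:
        return float(self.tvalues.get(self.analyte, np.nan))

    @property
    def t3(self) -> float:
        return float(self.tvalues.get("location", np.nan))


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fit_linkage_model(
    response: pd.Series,
    inbreeding: pd.Series,
    analyte: pd.Series,
    location: pd.Series | None = None,
    response_name: str = "FA",
    index_name: str = "index",
    analyte_name: str = "analyte",
    lam: float | None = None,
) -> LinkageModelResult:
    """Fit one OLS linkage model on individuals shared by all inputs.

    ``location``, when supplied, enters as a fixed factor (dummy
    coded); it is omitted for designs where the locations were pooled.
    Rank deficiency (e.g. a single pool making the analyte constant) is
    flagged on the result -- with the offending columns named -- rather
    than raised.
    """
    data = pd.concat(
        {
            "y": response,
            index_name: inbreeding,
            analyte_name: analyte,
            **({"location": location} if location is not None else {}),
        },
        axis=1,
        join="inner",
    ).dropna()
    n = len(data)
    n_params = 3 + (data["location"].nunique() - 1 if location is not None else 0)
    if n < n_params + 2:
        raise ValueError(f"too few complete observations ({n}) for {n_params} parameters")

    X = pd.DataFrame({"const": 1.0, index_name: data[index_name], analyte_name: data[analyte_name]})
    if location is not None:
        dummies = pd.get_dummies(data["location"], prefix="location", drop_first=True, dtype=float)
        if dummies.shape[1] == 1:
            dummies.columns = ["location"]
        X = pd.concat([X, dummies], axis=1)

    collinear = tuple(c for c in X.columns[1:] if X[c].nunique() == 1)
    rank_deficient = np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]

    model = sm.OLS(data["y"].to_numpy(), X)
    fit = model.fit()
    resid = fit.resid
    ks_p, note = np.nan, ""
    if rank_deficient:
        note = f"rank-deficient design; collinear columns: {collinear or ('unidentified',)}"
    elif n >= 10:
        std = np.std(resid, ddof=1)
        if std == 0:
            note = "degenerate residuals (all identical); diagnostics skipped"
        else:
            z = (resid - np.mean(resid)) / std
            ks_p = float(stats.kstest(z, "norm").pvalue)
    else:
        note = "fewer than 10 residuals; diagnostics skipped"

    parts = [index_name, analyte_name] + (["location"] if location is not None else [])
    formula = f"{response_name} ~ " + " + ".join(parts)
    return LinkageModelResult(
        formula=formula,
        response=response_name,
        index_name=index_name,
        analyte=analyte_name,
        n=n,
        params=fit.params,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r2_adj=float(fit.rsquared_adj),
        ks_p=ks_p,
        lam=lam,
        n_analyte_levels=int(data[analyte_name].nunique()),
        rank_deficient=bool(rank_deficient),
        collinear=collinear,
        note=note,
    )


def residual_diagnostics(fit_result, alpha: float = 0.05):
    """KS normality check of standardized residuals plus a plotting table.

    Accepts a statsmodels results object (or anything with ``resid``
    and ``fittedvalues``).  Returns ``(ks_p, passed, table)`` where
    ``table`` has columns fitted, residual, std_residual.  With fewer
    than 10 residuals the test is skipped (ks_p NaN, passed None).
    """
    resid = np.asarray(fit_result.resid, dtype=float)
    fitted = np.asarray(fit_result.fittedvalues, dtype=float)
    table = pd.DataFrame({"fitted": fitted, "residual": resid})
    if len(resid) < 10:
        table["std_residual"] = np.nan
        return np.nan, None, table
    std = np.std(resid, ddof=1)
    if std == 0:
        table["std_residual"] = 0.0
        return np.nan, None, table
    z = (resid - resid.mean()) / std
    table["std_residual"] = z
    ks_p = float(stats.kstest(z, "norm").pvalue)
    return ks_p, bool(ks_p >= alpha), table


def run_model_battery(
    responses: pd.DataFrame,
    indices: pd.DataFrame,
    analytes: pd.DataFrame,
    location: pd.Series | None = None,
    alpha: float = 0.05,
    index_names: tuple = ("mlh", "d2"),
    analyte_names: list[str] | None = None,
) -> pd.DataFrame:
    """Cartesian battery of linkage models: responses x indices x analytes.

    All inputs are keyed by individual id.  For each response, the
    models are first fit untransformed; if any of them fails the
    residual KS check at ``alpha``, the response is re-expressed once
    with :func:`tukey_transform` and all its models re-fit, with the
    chosen lambda recorded.  Output rows follow the fixed response /
    index / analyte order with significance stars at 0.05, 0.01 and
    0.001; results are invariant to the row order of the inputs.
    """
    if responses.empty or indices.empty or analytes.empty:
        raise ValueError("empty input set")
    analyte_names = list(analyte_names or [a for a in ANALYTES if a in analytes.columns])
    if not analyte_names:
        raise ValueError("no recognised analyte columns")
    rows = []
    for response_name in responses.columns:
        y = responses[response_name].dropna()
        variants = [(None, y)]
        results = _fit_block(variants[0], responses, indices, analytes, location,
                             response_name, index_names, analyte_names)
        ks = [r.ks_p for r in results if np.isfinite(r.ks_p)]
        if ks and min(ks) < alpha:
            lam, transformed = tukey_transform(y.to_numpy())
            y2 = pd.Series(transformed, index=y.index)
            results = _fit_block((lam, y2), responses, indices, analytes, location,
                                 response_name, index_names, analyte_names)
        rows.extend(results)

    table = pd.DataFrame(
        {
            "response": [r.response for r in rows],
            "index": [r.index_name for r in rows],
            "analyte": [r.analyte for r in rows],
            "formula": [r.formula for r in rows],
            "n": [r.n for r in rows],
            "n_analyte_levels": [r.n_analyte_levels for r in rows],
            "t1": [r.t1 for r in rows],
            "t2": [r.t2 for r in rows],
            "t3": [r.t3 for r in rows],
            "p2": [float(r.pvalues.get(r.analyte, np.nan)) for r in rows],
            "stars_t2": [_stars(float(r.pvalues.get(r.analyte, np.nan))) for r in rows],
            "r2_adj": [r.r2_adj for r in rows],
            "ks_p": [r.ks_p for r in rows],
            "lambda": [r.lam if r.lam is not None else 1.0 for r in rows],
            "rank_deficient": [r.rank_deficient for r in rows],
        }
    )
    table.attrs["alpha"] = alpha
    return table


def _fit_block(variant, responses, indices, analytes, location,
               response_name, index_names, analyte_names):
    lam, y = variant
    out = []
    for index_name in index_names:
        for analyte_name in analyte_names:
            out.append(
                fit_linkage_model(
                    y,
                    indices[index_name],
                    analytes[analyte_name],
                    location=location,
                    response_name=response_name,
                    index_name=index_name,
                    analyte_name=analyte_name,
                    lam=lam,
                )
            )
    return out
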