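"""Inferential layer: OLS with adjusted means, a random-intercept linear
mixed model fitted by REML, and Pearson correlation.

Per-person wear percentages are compared between cohorts with ordinary
least squares adjusted for age at the index date and race/ethnicity, and
group effects are reported as estimated marginal means (EMMs): model
predictions averaged over a reference grid that holds continuous
covariates at their sample mean and weights the levels of non-focus
factors equally (frequency weighting is available via the configuration).

Daily hours worn are compared with a linear mixed model carrying a
person-level random intercept, because each woman contributes many days.
The REML criterion is profiled over the variance ratio
``lambda = sigma2_between / sigma2_within``: at fixed lambda the GLS
solution is closed-form (the person-block structure of the marginal
covariance inverts via the rank-one Sherman–Morrison identity), so only a
one-dimensional bounded search over lambda remains. Inference on fixed
effects uses a t reference with residual degrees of freedom
(n_obs - n_fixed_params).

All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .config import AnalysisConfig
from .phenotyping import Cohort

__all__ = [
    "StatsError",
    "DesignInfo",
    "LinearModelFit",
    "MixedModelFit",
    "EmmResult",
    "CorrelationResult",
    "CohortComparisonResult",
    "build_design",
    "fit_ols",
    "estimated_marginal_means",
    "adjusted_mean",
    "fit_lmm_random_intercept",
    "pearson",
    "compare_cohorts",
    "compare_cohorts_hours",
]


class StatsError(ValueError):
    """Raised on degenerate designs or undefined statistics."""


@dataclass(frozen=True)
class DesignInfo:
    """Encoding metadata of a fitted design (treatment coding).

    ``factors`` maps factor name to its levels with the reference level
    first; ``level_freqs`` carries the observed level frequencies used for
    proportional reference-grid weighting; ``covariate_means`` are the
    sample means at which continuous covariates are held.
    """

    columns: tuple[str, ...]
    factors: dict[str, tuple[str, ...]]
    level_freqs: dict[str, dict[str, float]]
    covariate_means: dict[str, float]


@dataclass(frozen=True)
class LinearModelFit:
    params: np.ndarray
    cov_params: np.ndarray
    resid_var: float
    df_resid: int
    design: DesignInfo
    nobs: int


@dataclass(frozen=True)
class MixedModelFit:
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_between: float
    sigma2_within: float
    reml_loglik: float
    df_resid: int
    design: DesignInfo
    nobs: int
    n_groups: int
    lambda_ratio: float

    @property
    def resid_var(self) -> float:
        return self.sigma2_within


@dataclass(frozen=True)
class EmmResult:
    level: str
    emm: float
    se: float
    contrast_p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CohortComparisonResult:
    period: str
    metric: str
    emm_ppd: float
    se_ppd: float
    emm_nonppd: float
    se_nonppd: float
    p_value: float
    n_ppd: int
    n_nonppd: int


def _factor_levels(values: pd.Series, reference: str | None) -> tuple[str, ...]:
    """Observed levels, reference first (modal level when unspecified)."""
    counts = values.value_counts()
    if reference is None or reference not in counts.index:
        # modal level as reference, alphabetical tie-break
        top = counts[counts == counts.max()].index
        reference = sorted(top)[0]
    others = sorted(l for l in counts.index if l != reference)
    return (str(reference), *[str(l) for l in others])


def build_design(
    factors: dict[str, Sequence],
    covariates: dict[str, Sequence],
    references: dict[str, str] | None = None,
    n_obs: int | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Intercept + treatment-coded factors + raw continuous covariates.

    ``n_obs`` is only needed for an intercept-only design (no factors or
    covariates).
    """
    references = references or {}
    lengths = {len(v) for v in (*factors.values(), *covariates.values())}
    if len(lengths) > 1:
        raise StatsError(f"design inputs have unequal lengths {sorted(lengths)}")
    if not lengths:
        if n_obs is None:
            raise StatsError("intercept-only design needs n_obs")
        lengths = {n_obs}
    n = lengths.pop()
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    level_map: dict[str, tuple[str, ...]] = {}
    freqs: dict[str, dict[str, float]] = {}
    for name, values in factors.items():
        s = pd.Series(values).astype(str)
        levels = _factor_levels(s, references.get(name))
        level_map[name] = levels
        freqs[name] = {l: float((s == l).mean()) for l in levels}
        for level in levels[1:]:
            cols.append((s == level).to_numpy(float))
            names.append(f"{name}[{level}]")
    means: dict[str, float] = {}
    for name, values in covariates.items():
        arr = np.asarray(values, float)
        means[name] = float(arr.mean())
        cols.append(arr)
        names.append(name)
    X = np.column_stack(cols)
    info = DesignInfo(
        columns=tuple(names),
        factors=level_map,
        level_freqs=freqs,
        covariate_means=means,
    )
    return X, info


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [columns[j] for j in piv[rank:]]
        raise StatsError(f"rank-deficient design; collinear columns: {bad}")


def fit_ols(
    response: Sequence[float],
    cohort: Sequence | None = None,
    age: Sequence[float] | None = None,
    race: Sequence | None = None,
    references: dict[str, str] | None = None,
) -> LinearModelFit:
    """Least squares of a per-person outcome on cohort, age and race.

    Cohort and race are treatment-coded with configurable reference levels
    (defaults: the non-PPD cohort and the modal race/ethnicity level); any
    of the three terms may be omitted.
    """
    y = np.asarray(response, float)
    refs = dict(references or {})
    refs.setdefault("cohort", Cohort.NON_PPD.value)
    factors: dict[str, Sequence] = {}
    if cohort is not None:
        factors["cohort"] = cohort
    if race is not None:
        factors["race"] = race
    covariates: dict[str, Sequence] = {}
    if age is not None:
        covariates["age"] = age
    X, info = build_design(factors, covariates, refs, n_obs=len(y))
    n, p = X.shape
    if n <= p:
        raise StatsError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, info.columns)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return LinearModelFit(
        params=beta,
        cov_params=s2 * xtx_inv,
        resid_var=s2,
        df_resid=df,
        design=info,
        nobs=n,
    )


def _grid_weights(
    design: DesignInfo, focus: str, level: str, weights: str
) -> tuple[np.ndarray, list[str]]:
    """Weight vector over model columns for one focus-level EMM cell."""
    p = len(design.columns)
    w = np.zeros(p)
    col_index = {c: j for j, c in enumerate(design.columns)}
    w[col_index["intercept"]] = 1.0
    if level != design.factors[focus][0]:
        w[col_index[f"{focus}[{level}]"]] = 1.0
    for name, levels in design.factors.items():
        if name == focus:
            continue
        for other in levels[1:]:
            freq = (
                design.level_freqs[name][other]
                if weights == "proportional"
                else 1.0 / len(levels)
            )
            w[col_index[f"{name}[{other}]"]] = freq
    for name, mean in design.covariate_means.items():
        w[col_index[name]] = mean
    return w, list(design.columns)


def estimated_marginal_means(
    fit: LinearModelFit | MixedModelFit,
    focus: str = "cohort",
    weights: str | None = None,
) -> list[EmmResult]:
    """Adjusted (estimated marginal) means of the focus factor's levels.

    Each EMM is the model prediction averaged over a reference grid:
    continuous covariates at their sample mean, non-focus factor levels
    weighted equally by default ("proportional" uses observed
    frequencies). When the focus factor has exactly two levels the
    difference is tested with a t statistic on the fit's residual degrees
    of freedom; the two-sided p is attached to every level.
    """
    if focus not in fit.design.factors:
        raise StatsError(f"focus factor {focus!r} not in fitted design")
    weights = weights or "equal"
    if weights not in ("equal", "proportional"):
        raise StatsError(f"unknown reference-grid weighting {weights!r}")
    levels = fit.design.factors[focus]
    rows = [
        _grid_weights(fit.design, focus, level, weights)[0] for level in levels
    ]
    emms = [float(w @ fit.params) for w in rows]
    ses = [float(np.sqrt(w @ fit.cov_params @ w)) for w in rows]
    if len(levels) == 2:
        c = rows[1] - rows[0]
        diff = float(c @ fit.params)
        se_diff = float(np.sqrt(c @ fit.cov_params @ c))
        t = diff / se_diff
        p = 2.0 * float(sps.t.sf(abs(t), fit.df_resid))
    else:
        p = float("nan")
    return [
        EmmResult(level=l, emm=m, se=s, contrast_p=p)
        for l, m, s in zip(levels, emms, ses)
    ]


def adjusted_mean(
    fit: LinearModelFit | MixedModelFit,
    weights: str = "equal",
) -> tuple[float, float]:
    """Overall adjusted mean: prediction averaged over the full grid.

    Continuous covariates at their sample mean, every factor averaged over
    its levels (equally by default). Returns (mean, standard error). This
    is the one-group analogue of an EMM — useful when a model is fitted
    within a single cohort.
    """
    if weights not in ("equal", "proportional"):
        raise StatsError(f"unknown reference-grid weighting {weights!r}")
    p = len(fit.design.columns)
    w = np.zeros(p)
    col_index = {c: j for j, c in enumerate(fit.design.columns)}
    w[col_index["intercept"]] = 1.0
    for name, levels in fit.design.factors.items():
        for other in levels[1:]:
            freq = (
                fit.design.level_freqs[name][other]
                if weights == "proportional"
                else 1.0 / len(levels)
            )
            w[col_index[f"{name}[{other}]"]] = freq
    for name, mean in fit.design.covariate_means.items():
        w[col_index[name]] = mean
    return float(w @ fit.params), float(np.sqrt(w @ fit.cov_params @ w))


def fit_lmm_random_intercept(
    response: Sequence[float],
    person_ids: Sequence,
    cohort: Sequence | None = None,
    age: Sequence[float] | None = None,
    race: Sequence | None = None,
    references: dict[str, str] | None = None,
    rel_tol: float = 1e-8,
) -> MixedModelFit:
    """REML fit of y = X beta + b_person + e with scalar random intercepts.

    The likelihood is profiled over lambda = sigma2_between/sigma2_within:
    at each lambda the marginal precision of person i's block is
    (I - lambda/(1 + lambda n_i) J)/sigma2_within (Sherman–Morrison), so
    the GLS estimate, the profiled residual variance and the REML
    criterion are all closed-form in per-person sums. lambda is then
    optimized by a bounded scalar search to relative tolerance ``rel_tol``,
    with the boundary lambda = 0 checked explicitly.
    """
    y = np.asarray(response, float)
    ids = pd.Series(person_ids)
    if ids.isna().any():
        raise StatsError("person_ids contain missing values")
    if len(ids) != len(y):
        raise StatsError("response and person_ids have different lengths")
    codes, uniques = pd.factorize(ids)
    m = len(uniques)
    if m < 2:
        raise StatsError(f"need at least 2 persons, got {m}")
    refs = dict(references or {})
    refs.setdefault("cohort", Cohort.NON_PPD.value)
    factors: dict[str, Sequence] = {}
    if cohort is not None:
        factors["cohort"] = cohort
    if race is not None:
        factors["race"] = race
    covariates: dict[str, Sequence] = {}
    if age is not None:
        covariates["age"] = age
    X, info = build_design(factors, covariates, refs, n_obs=len(y))
    n, p = X.shape
    if n <= p:
        raise StatsError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, info.columns)

    counts = np.bincount(codes, minlength=m).astype(float)
    Sx = np.zeros((m, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=m)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profile(lam: float):
        c = lam / (1.0 + lam * counts)  # Sherman–Morrison shrinkage per person
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        beta = np.linalg.solve(A, b)
        rss = yty - float(np.sum(c * Sy**2)) - float(beta @ b)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise StatsError("GLS normal matrix not positive definite")
        crit = (
            (n - p) * np.log(rss / (n - p))
            + float(np.sum(np.log1p(lam * counts)))
            + logdetA
        )
        return crit, beta, A, rss

    def objective(u: float) -> float:
        return profile(np.expm1(u))[0]

    # u = log(1 + lambda); the upper bound allows a between:within ratio of
    # ~e^30, far beyond anything identifiable from data.
    res = optimize.minimize_scalar(
        objective, bounds=(0.0, 30.0), method="bounded",
        options={"xatol": rel_tol / 10},
    )
    if not res.success:
        raise StatsError(
            f"REML search failed to converge on u in [0, 30]: {res.message}"
        )
    crit0, *_ = profile(0.0)
    lam = 0.0 if crit0 <= res.fun else float(np.expm1(res.x))
    crit, beta, A, rss = profile(lam)
    sigma2_w = rss / (n - p)
    cov = sigma2_w * np.linalg.inv(A)
    loglik = -0.5 * (crit + (n - p) * (np.log(2 * np.pi) + 1.0))
    return MixedModelFit(
        params=beta,
        cov_params=cov,
        sigma2_between=lam * sigma2_w,
        sigma2_within=sigma2_w,
        reml_loglik=float(loglik),
        df_resid=n - p,
        design=info,
        nobs=n,
        n_groups=m,
        lambda_ratio=lam,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided t-based p-value.

    Pairs with a missing value on either side (e.g. from an empty-flagged
    period summary) are dropped first. p comes from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape != ya.shape:
        raise StatsError("x and y have different lengths")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise StatsError(f"need at least 3 complete pairs, got {n}")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise StatsError("correlation undefined: zero variance input")
    r = float(xd @ yd / np.sqrt(sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def _require_both_cohorts(data: pd.DataFrame, period: str, metric: str) -> None:
    present = set(data["cohort"].astype(str))
    for needed in (Cohort.PPD.value, Cohort.NON_PPD.value):
        if needed not in present:
            raise StatsError(
                f"cohort {needed} has no usable {metric} rows in period "
                f"{period!r}"
            )


def compare_cohorts(
    data: pd.DataFrame,
    metric: str,
    period: str,
    config: AnalysisConfig | None = None,
    adjust: bool = True,
) -> CohortComparisonResult:
    """Adjusted cohort comparison of a per-person percentage in one period.

    ``data`` is the person x period summary table joined with cohort, age
    and race columns. Rows from empty-flagged summaries are dropped; one
    OLS is fitted per period and the two cohorts' EMMs, their standard
    errors and the contrast p-value are returned. With ``adjust=False`` the
    model is cohort-only and the EMMs equal the raw group means.
    """
    config = config or AnalysisConfig()
    empty = (
        data["empty"].astype(bool)
        if "empty" in data.columns
        else pd.Series(False, index=data.index)
    )
    rows = data.loc[
        (data["period"].astype(str) == str(period))
        & ~empty
        & data[metric].notna()
    ]
    _require_both_cohorts(rows, period, metric)
    fit = fit_ols(
        rows[metric],
        cohort=rows["cohort"],
        age=rows["age"] if adjust else None,
        race=rows["race"] if adjust else None,
    )
    emms = {
        e.level: e
        for e in estimated_marginal_means(fit, "cohort", config.emm_weights)
    }
    ppd, non = emms[Cohort.PPD.value], emms[Cohort.NON_PPD.value]
    n_by = rows["cohort"].astype(str).value_counts()
    return CohortComparisonResult(
        period=str(period),
        metric=metric,
        emm_ppd=ppd.emm,
        se_ppd=ppd.se,
        emm_nonppd=non.emm,
        se_nonppd=non.se,
        p_value=ppd.contrast_p,
        n_ppd=int(n_by[Cohort.PPD.value]),
        n_nonppd=int(n_by[Cohort.NON_PPD.value]),
    )


def compare_cohorts_hours(
    daily: pd.DataFrame,
    period: str,
    config: AnalysisConfig | None = None,
) -> CohortComparisonResult:
    """Cohort comparison of daily hours worn via the random-intercept LMM.

    ``daily`` is day-level data joined with cohort/age/race, restricted to
    the period of interest and to days the device was actually worn (at
    least one wear hour) — the question is how long the device stays on on
    days it is worn at all.
    """
    config = config or AnalysisConfig()
    rows = daily.loc[daily["worn"].astype(bool)]
    _require_both_cohorts(rows, period, "hours_worn")
    fit = fit_lmm_random_intercept(
        rows["hours_worn"],
        rows["person_id"],
        cohort=rows["cohort"],
        age=rows["age"],
        race=rows["race"],
    )
    emms = {
        e.level: e
        for e in estimated_marginal_means(fit, "cohort", config.emm_weights)
    }
    ppd, non = emms[Cohort.PPD.value], emms[Cohort.NON_PPD.value]
    persons = rows.groupby("cohort")["person_id"].nunique()
    return CohortComparisonResult(
        period=str(period),
        metric="hours_per_day",
        emm_ppd=ppd.emm,
        se_ppd=ppd.se,
        emm_nonppd=non.emm,
        se_nonppd=non.se,
        p_value=ppd.contrast_p,
        n_ppd=int(persons[Cohort.PPD.value]),
        n_nonppd=int(persons[Cohort.NON_PPD.value]),
    )
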