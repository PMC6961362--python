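"""Farm-random-intercept linear models for ADD_kg prices.

Two model families share one engine: product-level price determinants
(number of AAIs, WHO type, formulation purity, district) and farm-week price
determinants (owner demographics, flock size/age, disease, mortality,
district). Selection is forward stepwise: candidates screened at univariable
p < 0.20, added in ascending univariable-p order and retained at
multivariable p <= 0.05. The response defaults to natural-log price in ₵.

Estimation is exact restricted maximum likelihood for the scalar
random-intercept model (1-D profile likelihood in the variance ratio);
reported p-values are Wald z tests of the fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "farm_adjusted_mean",
    "stepwise_select",
    "fit_price_model",
    "fit_farmweek_model",
    "refit_without_outliers",
]


@dataclass(frozen=True)
class ModelSpec:
    response: str = "log"  # "log" or "identity" transform of price_cents
    screen_p: float = 0.20
    retain_p: float = 0.05
    outlier_z: float = 3.0

    def __post_init__(self) -> None:
        if not (self.screen_p > self.retain_p > 0):
            raise ValueError("need screen_p > retain_p > 0")
        if self.response not in ("log", "identity"):
            raise ValueError(f"unknown response transform {self.response!r}")


@dataclass
class ModelFit:
    """Result of a stepwise mixed-model fit.

    ``params`` holds the multivariable fixed effects (beta/se/p per design
    column); ``univariable`` one row per candidate design column from its
    single-candidate fit. ``data``/``candidates`` are retained so the fit can
    be reproduced after outlier exclusion.
    """

    params: pd.DataFrame
    intercept: tuple[float, float]
    farm_var: float
    resid_var: float
    n_obs: int
    converged: bool
    selected: list[str]
    univariable: pd.DataFrame
    response: str = "log"
    data: pd.DataFrame | None = field(default=None, repr=False)
    candidates: dict | None = field(default=None, repr=False)
    spec: ModelSpec | None = field(default=None, repr=False)
    n_excluded: int = 0
    contrasts: dict = field(default_factory=dict)
    _result: object = field(default=None, repr=False)


def _transform(y: np.ndarray, response: str) -> np.ndarray:
    if response == "log":
        if np.any(y <= 0):
            raise ValueError("log response requires strictly positive prices")
        return np.log(y)
    return np.asarray(y, float)


@dataclass
class RandomInterceptResult:
    """REML fit of ``y = X b + u_group + e`` with a scalar random intercept."""

    fe_params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_re: np.ndarray  # 1x1 matrix, group variance
    scale: float  # residual variance
    converged: bool
    resid: np.ndarray  # marginal residuals y - X b
    n_obs: int


def _fit_mixed(df: pd.DataFrame, ycol: str, cols: Sequence[str],
               group_col: str) -> RandomInterceptResult:
    """Exact profile-REML fit of the random-intercept linear model.

    With ``V = sigma_e^2 (I + lambda Z Z')`` the GLS transform is partial
    group-mean centering, ``y* = y - theta_g * ybar_g`` with
    ``theta_g = 1 - 1 / sqrt(1 + n_g lambda)``, which reduces the REML
    criterion to a 1-D profile in the variance ratio ``lambda``. Wald z
    p-values, matching the reference mixed-model tooling to within
    optimizer tolerance (cross-checked against statsmodels in the tests).
    """
    cols = list(cols)
    dropped = [c for c in cols if df[c].nunique() < 2]
    if dropped:
        # constant columns are inestimable alongside the intercept
        cols = [c for c in cols if c not in dropped]
    names = ["const"] + cols
    X = np.column_stack([np.ones(len(df))]
                        + [df[c].to_numpy(float) for c in cols])
    y = df[ycol].to_numpy(float)
    codes, _ = pd.factorize(df[group_col].to_numpy())
    n_groups = codes.max() + 1
    n_g = np.bincount(codes).astype(float)
    N, p = X.shape

    ybar = np.bincount(codes, weights=y) / n_g
    Xbar = np.column_stack(
        [np.bincount(codes, weights=X[:, j]) / n_g for j in range(p)])

    def profile(lam: float):
        theta = 1.0 - 1.0 / np.sqrt(1.0 + n_g * lam)
        yt = y - theta[codes] * ybar[codes]
        Xt = X - theta[codes, None] * Xbar[codes]
        XtX = Xt.T @ Xt
        beta = np.linalg.solve(XtX, Xt.T @ yt)
        rss = float(np.sum((yt - Xt @ beta) ** 2))
        sigma2 = max(rss / (N - p), 1e-300)  # guard exact-fit degeneracy
        sign, logdet = np.linalg.slogdet(XtX)
        m2ll = ((N - p) * np.log(sigma2) + np.sum(np.log1p(n_g * lam)) + logdet)
        return m2ll, beta, sigma2, XtX

    def objective(log_lam: float) -> float:
        return profile(np.exp(log_lam))[0]

    opt = optimize.minimize_scalar(objective, bounds=(-12.0, 8.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(opt.x))
    # boundary check: variance ratio may be effectively zero
    if objective(-30.0) <= opt.fun + 1e-10:
        lam = 0.0
    m2ll, beta, sigma2, XtX = profile(lam)
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    fe = pd.Series(beta, index=names)
    bse = pd.Series(se, index=names)
    pv = pd.Series(pvals, index=names)
    for c in dropped:  # inestimable level: report as null effect
        fe[c], bse[c], pv[c] = np.nan, np.nan, 1.0
    return RandomInterceptResult(
        fe_params=fe,
        bse=bse,
        pvalues=pv,
        cov_re=np.array([[lam * sigma2]]),
        scale=float(sigma2),
        converged=bool(opt.success) and n_groups >= 1,
        resid=y - X @ beta,
        n_obs=N,
    )


def _fixed_table(res, cols: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in cols:
        rows.append({"term": c, "beta": float(res.fe_params[c]),
                     "se": float(res.bse[c]), "p": float(res.pvalues[c])})
    return pd.DataFrame(rows).set_index("term")


def farm_adjusted_mean(
    df: pd.DataFrame,
    price_col: str = "price_cents",
    group_col: str = "farm_id",
    response: str = "log",
) -> tuple[float, float]:
    """Farm-adjusted mean price (₵) with SE.

    The intercept of an intercept-only farm-random-intercept model on the
    (transformed) price, back-transformed. With a single farm the crude mean
    is returned with a warning.
    """
    work = df[[price_col, group_col]].dropna()
    if work[group_col].nunique() < 2:
        warnings.warn("single farm: falling back to crude mean", stacklevel=2)
        vals = work[price_col].to_numpy(float)
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        return float(vals.mean()), float(se)
    work = work.assign(_y=_transform(work[price_col].to_numpy(float), response))
    res = _fit_mixed(work, "_y", [], group_col)
    b0, se0 = float(res.fe_params["const"]), float(res.bse["const"])
    if response == "log":
        return float(np.exp(b0)), float(np.exp(b0) * se0)  # delta method
    return b0, se0


def _univariable_fits(df, ycol, candidates, group_col) -> pd.DataFrame:
    rows = []
    for name, cols in candidates.items():
        res = _fit_mixed(df, ycol, cols, group_col)
        tab = _fixed_table(res, cols)
        for term, r in tab.iterrows():
            rows.append({"candidate": name, "term": term, "beta": r["beta"],
                         "se": r["se"], "p": r["p"]})
    return pd.DataFrame(rows, columns=["candidate", "term", "beta", "se", "p"])


def stepwise_select(
    univariable: pd.DataFrame,
    df: pd.DataFrame,
    ycol: str,
    candidates: Mapping[str, Sequence[str]],
    spec: ModelSpec,
    group_col: str = "farm_id",
) -> list[str]:
    """Forward stepwise selection of candidate covariates.

    Candidates whose best univariable p is < ``screen_p`` enter in ascending
    univariable-p order (name-tiebroken, so the result is independent of
    input order); each is retained only while its multivariable p stays
    <= ``retain_p``. A final backward sweep drops any candidate pushed above
    ``retain_p`` by later additions.
    """
    best_p = univariable.groupby("candidate")["p"].min()
    screened = sorted(
        (name for name in candidates if best_p.get(name, 1.0) < spec.screen_p),
        key=lambda name: (best_p[name], name),
    )

    def cand_p(selected: list[str], name: str) -> float:
        cols = [c for s in selected for c in candidates[s]]
        res = _fit_mixed(df, ycol, cols, group_col)
        return min(float(res.pvalues[c]) for c in candidates[name])

    selected: list[str] = []
    for name in screened:
        trial = selected + [name]
        if cand_p(trial, name) <= spec.retain_p:
            selected.append(name)
    # backward sweep: later additions can inflate earlier candidates' p
    changed = True
    while changed and selected:
        changed = False
        for name in list(selected):
            if cand_p(selected, name) > spec.retain_p:
                selected.remove(name)
                changed = True
    return selected


def _stepwise_fit(
    df: pd.DataFrame,
    candidates: Mapping[str, Sequence[str]],
    spec: ModelSpec,
    group_col: str = "farm_id",
    price_col: str = "price_cents",
    multivariable_candidates: Mapping[str, Sequence[str]] | None = None,
) -> ModelFit:
    """Shared engine: univariable fits, stepwise selection, final fit.

    ``multivariable_candidates`` optionally substitutes a candidate's design
    columns at the multivariable stage (used to collapse the WHO-type factor
    into a binary contrast).
    """
    work = df.copy()
    work["_y"] = _transform(work[price_col].to_numpy(float), spec.response)
    univ = _univariable_fits(work, "_y", candidates, group_col)
    multi_cand = dict(candidates)
    if multivariable_candidates:
        multi_cand.update(multivariable_candidates)
    selected = stepwise_select(univ, work, "_y", multi_cand, spec, group_col)
    cols = [c for s in selected for c in multi_cand[s]]
    res = _fit_mixed(work, "_y", cols, group_col)
    params = _fixed_table(res, cols)
    farm_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    fit = ModelFit(
        params=params,
        intercept=(float(res.fe_params["const"]), float(res.bse["const"])),
        farm_var=farm_var,
        resid_var=float(res.scale),
        n_obs=len(work),
        converged=bool(res.converged),
        selected=selected,
        univariable=univ,
        response=spec.response,
        data=work,
        candidates=dict(multi_cand),
        spec=spec,
        _result=res,
    )
    if not fit.converged:
        warnings.warn("mixed model did not converge; inspect fit diagnostics",
                      stacklevel=2)
    return fit


def _dummy(series: pd.Series, positive) -> pd.Series:
    return (series == positive).astype(float)


def fit_price_model(df: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> ModelFit:
    """Product-level price determinants on standardized ADD_kg prices.

    Expects one row per price record with columns ``price_cents, farm_id,
    n_aais, who_type, pure_aai, district``. ``who_type`` is the top-ranked
    WHO category present in the product (baseline ``HIGHLY_IMPORTANT``);
    baselines elsewhere: 1 AAI, mixed formulation, ``THAP_MUOI``. Records
    with more than two AAIs are excluded (the model covers one- and two-AAI
    products). At the multivariable stage the WHO factor is collapsed to a
    ``HIGH_PRIORITY`` vs all-others contrast.
    """
    work = df[df["n_aais"].isin([1, 2])].copy()
    n_dropped = len(df) - len(work)
    work["two_aais"] = (work["n_aais"] == 2).astype(float)
    work["who_highest"] = _dummy(work["who_type"], "HIGHEST_PRIORITY")
    work["who_high"] = _dummy(work["who_type"], "HIGH_PRIORITY")
    work["who_other"] = _dummy(work["who_type"], "OTHER")
    work["who_high_vs_rest"] = work["who_high"]
    work["pure"] = work["pure_aai"].astype(float)
    work["caolanh"] = _dummy(work["district"], "CAO_LANH")
    candidates = {
        "two_aais": ["two_aais"],
        "who_type": ["who_highest", "who_high", "who_other"],
        "pure_aai": ["pure"],
        "district": ["caolanh"],
    }
    fit = _stepwise_fit(
        work, candidates, spec,
        multivariable_candidates={"who_type": ["who_high_vs_rest"]},
    )
    fit.n_excluded = n_dropped
    # pairwise contrast mirroring the collapsed WHO comparison
    univ = fit.univariable
    high = univ[univ["term"] == "who_high"]
    if len(high):
        fit.contrasts["high_priority_vs_highly_important"] = {
            "beta": float(high["beta"].iloc[0]),
            "se": float(high["se"].iloc[0]),
            "p": float(high["p"].iloc[0]),
        }
    return fit


def fit_farmweek_model(df: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> ModelFit:
    """Farm-week price determinants on the ADD_kg price of products used.

    Expects one row per AMU week with columns ``price_cents, farm_id,
    week_of_age, flock_size, disease, mortality_high, district,
    owner_age_group (<36 | 36-54 | >54), owner_gender (F | M),
    owner_experience (0-2 | >2-4 | >4), owner_education (post_high | primary
    | secondary | high_school)``. Flock age and size enter on the log scale.
    """
    work = df.copy()
    work["log_week"] = np.log(work["week_of_age"].astype(float))
    work["log_size"] = np.log(work["flock_size"].astype(float))
    work["age_36_54"] = _dummy(work["owner_age_group"], "36-54")
    work["age_gt54"] = _dummy(work["owner_age_group"], ">54")
    work["male"] = _dummy(work["owner_gender"], "M")
    work["exp_2_4"] = _dummy(work["owner_experience"], ">2-4")
    work["exp_gt4"] = _dummy(work["owner_experience"], ">4")
    work["edu_primary"] = _dummy(work["owner_education"], "primary")
    work["edu_secondary"] = _dummy(work["owner_education"], "secondary")
    work["edu_high"] = _dummy(work["owner_education"], "high_school")
    work["disease_flag"] = work["disease"].astype(float)
    work["mort_high"] = work["mortality_high"].astype(float)
    work["caolanh"] = _dummy(work["district"], "CAO_LANH")
    candidates = {
        "owner_age": ["age_36_54", "age_gt54"],
        "owner_gender": ["male"],
        "owner_experience": ["exp_2_4", "exp_gt4"],
        "owner_education": ["edu_primary", "edu_secondary", "edu_high"],
        "flock_size_log": ["log_size"],
        "flock_age_log": ["log_week"],
        "disease": ["disease_flag"],
        "mortality": ["mort_high"],
        "district": ["caolanh"],
    }
    return _stepwise_fit(work, candidates, spec)


def refit_without_outliers(fit: ModelFit, threshold: float | None = None) -> ModelFit:
    """Drop records with |standardized marginal residual| > threshold and refit.

    Both fits are meant to be reported side by side; with no outliers the
    refit equals the original. Raises if an exclusion empties a design-column
    level.
    """
    if fit.data is None or fit.spec is None or fit._result is None:
        raise ValueError("fit does not carry the data needed for a refit")
    threshold = fit.spec.outlier_z if threshold is None else threshold
    resid = np.asarray(fit._result.resid, float)
    sd = resid.std(ddof=1)
    if sd == 0:
        return fit
    keep = np.abs(resid / sd) <= threshold
    if keep.all():
        return fit
    kept = fit.data.loc[keep]
    cols = [c for s in fit.selected for c in fit.candidates[s]]
    for c in cols:
        if kept[c].nunique() < 2 and fit.data[c].nunique() > 1:
            raise ValueError(f"outlier exclusion empties level of {c!r}")
    res = _fit_mixed(kept, "_y", cols, "farm_id")
    farm_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    return ModelFit(
        params=_fixed_table(res, cols),
        intercept=(float(res.fe_params["const"]), float(res.bse["const"])),
        farm_var=farm_var,
        resid_var=float(res.scale),
        n_obs=int(keep.sum()),
        converged=bool(res.converged),
        selected=list(fit.selected),
        univariable=fit.univariable,
        response=fit.response,
        data=kept,
        candidates=fit.candidates,
        spec=fit.spec,
        n_excluded=fit.n_excluded + int((~keep).sum()),
        contrasts=dict(fit.contrasts),
        _result=res,
    )
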