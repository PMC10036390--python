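"""Link trait variability and environment to network structure.

Two statistical stages follow network construction:

1. *Screening* — across water bodies, each network topology metric
   (ED, AL, AC, Q) is correlated (Pearson, two-sided) with each
   environmental variable; variables significant at ``alpha`` are
   carried forward.
2. *Backward multiple regression* — ordinary least squares on the
   screened variables, iteratively dropping the predictor with the
   largest p-value above ``p_remove`` (default 0.10) and refitting,
   until every remaining predictor is retained or only one is left.
   With a single screened variable this reduces to simple regression.

A third helper regresses node metrics (k, C, B) on per-trait CV and
topology metrics on group mean CV, the variability-to-structure link.

Model fitting is delegated to statsmodels OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, InsufficientDataError, JoinError
from .trait_data import CVTable, EnvTable


@dataclass
class ScreenResult:
    """Pearson screen of one (topology metric, environment variable) pair."""

    metric_name: str
    variable_name: str
    pearson_r: float
    p_value: float
    selected: bool


@dataclass
class RegressionResult:
    """A fitted linear model with its elimination history."""

    response_name: str
    predictor_names: list[str]
    coefficients: np.ndarray  # intercept first, then slopes
    stderr: np.ndarray
    r_squared: float
    f_statistic: float
    p_value: float
    n_obs: int
    eliminated_predictors: list[tuple[str, float]] = field(default_factory=list)
    significant: bool = True

    def equation(self, digits: int = 2) -> str:
        """Human-readable equation, e.g. ``AL = 1.22 - 24.30*TP + 0.15*DO``."""
        terms = [f"{self.coefficients[0]:.{digits}f}"]
        for name, b in zip(self.predictor_names, self.coefficients[1:]):
            sign = "-" if b < 0 else "+"
            terms.append(f"{sign} {abs(b):.{digits}f}*{name}")
        return f"{self.response_name} = " + " ".join(terms)


def screen_environment(
    topo: pd.DataFrame, env: EnvTable, alpha: float = 0.05
) -> list[ScreenResult]:
    """Pearson screening of topology metrics against environment.

    ``topo`` has one row per water body (index = group) and one column
    per topology metric. Requires at least 3 groups shared with the
    environmental table; constant environmental variables are skipped
    with a warning.
    """
    common = [g for g in topo.index if g in env.data.index]
    if len(common) < 3:
        raise InsufficientDataError(
            f"screening needs >= 3 groups with both topology and environment, "
            f"got {len(common)}"
        )
    t = topo.loc[common]
    e = env.data.loc[common]
    out: list[ScreenResult] = []
    for var in e.columns:
        x = e[var].to_numpy(float)
        if not np.isfinite(x).all() or np.std(x) == 0:
            warnings.warn(
                f"environmental variable {var!r} constant or incomplete; skipped",
                stacklevel=2,
            )
            continue
        for metric in t.columns:
            y = t[metric].to_numpy(float)
            if np.std(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            out.append(ScreenResult(metric, var, float(r), float(p), bool(p < alpha)))
    return out


def _fit_ols(y: np.ndarray, X: pd.DataFrame, response_name: str) -> sm.regression.linear_model.RegressionResultsWrapper:
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy(float))
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols: list[str] = []
        for c in design.columns:
            trial = design[cols + [c]].to_numpy(float)
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise CollinearityError(
            f"design matrix for {response_name!r} is rank deficient "
            f"(columns {bad})",
            columns=bad,
        )
    return sm.OLS(y, design).fit()


def backward_regression(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    p_remove: float = 0.10,
    response_name: str = "y",
) -> RegressionResult:
    """Backward-elimination multiple linear regression.

    Starting from the full OLS model, the predictor with the largest
    p-value above ``p_remove`` is dropped and the model refitted, until
    all remaining predictors satisfy p <= ``p_remove`` or one predictor
    remains. The elimination order and p-values are recorded.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientDataError(
            f"backward regression needs n_obs > predictors + 1; "
            f"got n={n}, predictors={k}"
        )
    if k > 0 and n / k < 5:
        warnings.warn(
            f"only {n} observations for {k} candidate predictors; "
            "estimates will be unstable",
            stacklevel=2,
        )
    eliminated: list[tuple[str, float]] = []
    current = list(X.columns)
    with warnings.catch_warnings():
        # degenerate fits (constant response, perfect fit) divide by ~0
        # inside statsmodels; the flags below report them explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        while True:
            fit = _fit_ols(y, X[current], response_name)
            pvals = fit.pvalues.drop("const")
            if len(current) <= 1:
                break
            worst = pvals.idxmax()
            if pvals[worst] <= p_remove:
                break
            eliminated.append((str(worst), float(pvals[worst])))
            current.remove(worst)
        fvalue = float(fit.fvalue) if np.isfinite(fit.fvalue) else float("inf")
        if fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0):
            fvalue = float("inf")  # perfect fit
        r_squared = float(fit.rsquared)
        f_pvalue = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 0.0
        params = np.asarray(fit.params)
        bse = np.asarray(fit.bse)
    return RegressionResult(
        response_name=response_name,
        predictor_names=[str(c) for c in current],
        coefficients=params,
        stderr=bse,
        r_squared=r_squared,
        f_statistic=fvalue,
        p_value=f_pvalue,
        n_obs=int(n),
        eliminated_predictors=eliminated,
        significant=bool(f_pvalue < 0.05),
    )


def simple_regression(
    y: np.ndarray | pd.Series, x: np.ndarray | pd.Series, response_name: str = "y",
    predictor_name: str = "x",
) -> RegressionResult:
    """Univariate OLS; the fallback when one variable survives screening."""
    X = pd.DataFrame({predictor_name: np.asarray(x, float)})
    return backward_regression(y, X, p_remove=1.0, response_name=response_name)


def screen_and_regress(
    topo: pd.DataFrame,
    env: EnvTable,
    alpha: float = 0.05,
    p_remove: float = 0.10,
) -> tuple[list[ScreenResult], dict[str, RegressionResult]]:
    """The full environment workflow: Pearson screen, then backward OLS.

    For each topology metric, the environmental variables selected by
    screening become candidate predictors; metrics with no selected
    variable are skipped.
    """
    screens = screen_environment(topo, env, alpha=alpha)
    common = [g for g in topo.index if g in env.data.index]
    models: dict[str, RegressionResult] = {}
    for metric in topo.columns:
        chosen = [s.variable_name for s in screens
                  if s.metric_name == metric and s.selected]
        if not chosen:
            continue
        y = topo.loc[common, metric].to_numpy(float)
        X = env.data.loc[common, chosen]
        models[metric] = backward_regression(
            y, X, p_remove=p_remove, response_name=metric
        )
    return screens, models


def cv_vs_node_metrics(
    cvt: CVTable, node_frames: dict[object, pd.DataFrame]
) -> dict[str, RegressionResult]:
    """Regress node centrality on trait variability.

    ``node_frames`` maps group -> node-metrics frame with columns
    (trait, k, C, B). Each of k, C, B is regressed on the per-trait,
    per-group CV across all matched (trait, group) observations.
    Nonsignificant slopes are flagged via ``significant``.
    """
    nm_all = []
    for g, frame in node_frames.items():
        f = frame.copy()
        f["group"] = g
        nm_all.append(f[["trait", "group", "k", "C", "B"]])
    nm = pd.concat(nm_all, ignore_index=True)
    merged = nm.merge(cvt.per_group, on=["trait", "group"], how="outer",
                      indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", ["trait", "group"]]
    if len(unmatched):
        raise JoinError(
            "trait/group keys differ between CV table and node metrics",
            unmatched=list(unmatched.itertuples(index=False, name=None)),
        )
    merged = merged.dropna(subset=["cv"])
    if merged["trait"].nunique() < 2:
        raise InsufficientDataError("need CVs for at least 2 traits to regress")
    out: dict[str, RegressionResult] = {}
    for metric in ("k", "C", "B"):
        out[metric] = simple_regression(
            merged[metric], merged["cv"], response_name=metric, predictor_name="cv"
        )
    return out


def topology_vs_group_cv(
    cvt: CVTable, topo: pd.DataFrame
) -> dict[str, RegressionResult]:
    """Regress ED, AL, AC, Q on each group's mean trait CV."""
    common = [g for g in topo.index if g in cvt.group_mean_cv.index]
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >= 3 groups with both topology and CV, got {len(common)}"
        )
    x = cvt.group_mean_cv.loc[common]
    out = {}
    for metric in topo.columns:
        out[metric] = simple_regression(
            topo.loc[common, metric], x, response_name=metric,
            predictor_name="mean_cv",
        )
    return out


def regression_report(models: dict[str, RegressionResult]) -> pd.DataFrame:
    """Tidy summary: one row per fitted model."""
    rows = []
    for name, m in models.items():
        rows.append(
            {
                "response": name,
                "predictors": "+".join(m.predictor_names),
                "equation": m.equation(),
                "r_squared": m.r_squared,
                "f_statistic": m.f_statistic,
                "p_value": m.p_value,
                "n_obs": m.n_obs,
                "eliminated": ";".join(f"{n}({p:.3f})" for n, p in m.eliminated_predictors),
            }
        )
    return pd.DataFrame(rows)
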