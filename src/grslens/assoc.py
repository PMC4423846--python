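"""Regression-based evaluation of genetic risk scores.

All models share the covariate set {age, age², sex}. Lipid outcomes are
analyzed on their measured scale except triglycerides, which enter as the
natural logarithm. The module provides:

* ``fit_model`` — OLS / maximum-likelihood logistic fits with named
  coefficients;
* ``delta_r2`` — the increase in R² when a score is added to the
  covariate-only model, with a nested F-test and a seeded case-resampling
  percentile bootstrap CI;
* ``moderation_test`` — the population x GRS interaction F-test (does the
  score-phenotype slope depend on population group?);
* ``joint_noncorresponding_test`` — do the other three traits' scores add
  information beyond a trait's own score?
* ``nagelkerke_r2`` and ``outcome_panel`` — joint 4-score association with
  clinical outcomes, ΔR² for continuous and ΔNagelkerke-R² (likelihood-ratio
  test) for binary outcomes.

P-values are reported without multiple-testing correction. Continuous
ancestry axes (principal components) are deliberately not modeled: they are
collinear with the population factor and would distort population-level
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError

log = logging.getLogger("grslens")

COVARIATES = ("age", "age2", "sex")
TRAITS = ("HDL", "LDL", "TC", "TG")
GRS_COLUMNS = tuple(f"{t}_GRS" for t in TRAITS)


@dataclass
class ModelSpec:
    """Declarative description of one regression model.

    ``predictors`` may contain data columns (e.g. ``"HDL_GRS"``), the token
    ``"population"`` (dummy-coded main effects against ``reference_level``)
    and interaction tokens ``"population:<column>"``. ``transform`` applies
    to the outcome: ``"log"`` (natural log, used for TG) or ``"identity"``;
    ``"auto"`` selects log iff the outcome is TG. The age² covariate always
    accompanies age.
    """

    outcome: str
    predictors: list[str] = field(default_factory=list)
    family: str = "linear"
    transform: str = "auto"
    covariates: tuple[str, ...] = COVARIATES
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.transform == "auto":
            self.transform = "log" if self.outcome == "TG" else "identity"

    def required_columns(self) -> list[str]:
        cols = [self.outcome, "age", "sex"]
        for p in self.predictors:
            if p == "population":
                cols.append("population")
            elif p.startswith("population:"):
                cols.extend(["population", p.split(":", 1)[1]])
            else:
                cols.append(p)
        return list(dict.fromkeys(cols))


@dataclass
class FitResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    df_resid: int
    r2: float | None         # linear only
    loglik: float | None     # logistic only
    fitted: np.ndarray
    family: str


@dataclass(frozen=True)
class NestedTestResult:
    statistic: float
    df1: int
    df2: int | None          # None for likelihood-ratio chi2
    p: float
    kind: str                # "F" or "LRT"


@dataclass
class DeltaR2Result:
    delta_r2: float
    ci_lower: float
    ci_upper: float
    level: float
    n_boot: int
    p: float
    r2_reduced: float
    r2_full: float
    n: int


# ---------------------------------------------------------------------------
# design-matrix construction and fast linear algebra


def _complete_cases(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    sub = data[cols]
    mask = sub.notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        log.info("dropped %d incomplete rows for model fitting", n_drop)
    return data.loc[mask]


def build_design(data: pd.DataFrame, predictors: list[str],
                 covariates: tuple[str, ...] = COVARIATES,
                 reference_level: str | None = None) -> pd.DataFrame:
    """Assemble the design matrix (with intercept and age² alongside age)."""
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    if "age" in covariates:
        X["age"] = data["age"].astype(float)
        X["age2"] = X["age"] ** 2
    if "sex" in covariates:
        X["sex"] = data["sex"].astype(float)
    pop_dummies: pd.DataFrame | None = None
    for p in predictors:
        if p == "population":
            levels = sorted(data["population"].astype(str).unique())
            ref = reference_level if reference_level in levels else levels[0]
            pop_dummies = pd.get_dummies(
                data["population"].astype(str), prefix="pop", dtype=float
            ).drop(columns=f"pop_{ref}")
            for c in pop_dummies.columns:
                X[c] = pop_dummies[c]
        elif p.startswith("population:"):
            col = p.split(":", 1)[1]
            if pop_dummies is None:
                raise ValidationError(
                    "population main effects must precede population interactions"
                )
            for c in pop_dummies.columns:
                X[f"{c}:{col}"] = pop_dummies[c] * data[col].astype(float)
        else:
            X[p] = data[p].astype(float)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) == A.shape[1]:
        return
    # name the first column linearly dependent on its predecessors
    for j in range(1, A.shape[1]):
        if np.linalg.matrix_rank(A[:, : j + 1]) <= j:
            raise FitError(f"perfect collinearity: column {X.columns[j]!r} "
                           "is aliased with earlier predictors")
    raise FitError("design matrix is rank-deficient")


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit via Cholesky normal equations (SVD fallback).

    The fallback handles rank-deficient designs (e.g. a score column that is
    an exact combination of the covariates), where the minimum-norm solution
    still yields the correct residual sum of squares.
    """
    from scipy.linalg import cho_factor, cho_solve

    xtx = X.T @ X
    try:
        c = cho_factor(xtx, check_finite=False)
        beta = cho_solve(c, X.T @ y, check_finite=False)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    _, rss = _ols_rss(X, y)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        raise FitError("outcome has zero variance")
    return 1.0 - rss / tss


def nested_f_test(r2_reduced: float, r2_full: float, df1: int, df2: int
                  ) -> NestedTestResult:
    """F-test comparing nested OLS fits from their R² values."""
    if df1 < 1 or df2 < 1:
        raise ValidationError("invalid degrees of freedom for nested F-test")
    num = max(r2_full - r2_reduced, 0.0) / df1
    den = (1.0 - r2_full) / df2
    if den <= 0:
        return NestedTestResult(np.inf, df1, df2, 0.0, "F")
    F = num / den
    return NestedTestResult(F, df1, df2, float(stats.f.sf(F, df1, df2)), "F")


# ---------------------------------------------------------------------------
# public fitting API


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one model by OLS (linear) or maximum likelihood (logistic).

    Complete-case analysis: rows missing any required value are dropped with
    a logged count. Perfect collinearity raises a :class:`FitError` naming
    the aliased column; logistic separation/non-convergence also raises.
    """
    import statsmodels.api as sm

    cols = spec.required_columns()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"model columns absent from data: {missing}")
    sub = _complete_cases(data, cols)
    X = build_design(sub, spec.predictors, spec.covariates, spec.reference_level)
    y = sub[spec.outcome].astype(float).to_numpy()
    if spec.transform == "log":
        if (y <= 0).any():
            raise ValidationError(f"log transform undefined: {spec.outcome} <= 0")
        y = np.log(y)
    if len(y) <= X.shape[1]:
        raise FitError(f"n={len(y)} does not exceed parameter count {X.shape[1]}")
    _check_full_rank(X)
    if spec.family == "linear":
        res = sm.OLS(y, X).fit()
        return FitResult(res.params, res.bse, res.pvalues, int(res.nobs),
                         int(res.df_resid), float(res.rsquared), None,
                         np.asarray(res.fittedvalues), "linear")
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0} or len(classes) < 2:
        raise FitError("logistic outcome must contain both classes coded 0/1")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation / convergence failures
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError("logistic fit did not converge (possible separation)")
    return FitResult(res.params, res.bse, res.pvalues, int(res.nobs),
                     int(res.df_resid), None, float(res.llf),
                     np.asarray(res.predict()), "logistic")


def delta_r2(outcome: str, grs_column: str, data: pd.DataFrame,
             n_boot: int = 1000, seed: int | None = None,
             transform: str = "auto", ci_level: float = 0.95) -> DeltaR2Result:
    """ΔR² of one score over the covariate-only model, with bootstrap CI.

    Point estimate: R²(age + age² + sex + GRS) − R²(age + age² + sex),
    both unadjusted. The p-value is the 1-df nested F-test. The CI is a
    case-resampling percentile bootstrap (rows resampled, both models refit
    per replicate); degenerate resamples are redrawn a bounded number of
    times.
    """
    if n_boot < 100:
        log.warning("n_boot=%d < 100; bootstrap CI will be unstable", n_boot)
    spec = ModelSpec(outcome, [grs_column], transform=transform)
    sub = _complete_cases(data, spec.required_columns())
    y = sub[outcome].astype(float).to_numpy()
    if spec.transform == "log":
        if (y <= 0).any():
            raise ValidationError(f"log transform undefined: {outcome} <= 0")
        y = np.log(y)
    Xf = build_design(sub, [grs_column]).to_numpy(dtype=float)
    Xr = Xf[:, :-1]
    n, p_full = Xf.shape
    if n <= p_full:
        raise FitError("too few complete cases")
    r2_full = _ols_r2(Xf, y)
    r2_red = _ols_r2(Xr, y)
    point = r2_full - r2_red
    test = nested_f_test(r2_red, r2_full, 1, n - p_full)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(20):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            try:
                d = _ols_r2(Xf[idx], yb) - _ols_r2(Xr[idx], yb)
            except FitError:
                continue
            deltas[b] = d
            break
        else:
            raise FitError("bootstrap resamples persistently degenerate")
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
    return DeltaR2Result(point, float(lo), float(hi), ci_level, n_boot,
                         test.p, r2_red, r2_full, n)


def moderation_test(outcome: str, grs_column: str, data: pd.DataFrame,
                    population_column: str = "population",
                    transform: str = "auto") -> NestedTestResult:
    """Population x GRS interaction: does the score's slope differ by group?

    Full model: covariates + population main effects + GRS + population x GRS
    interactions. Reduced: same without the interactions. F-test with
    df1 = K - 1 for K population levels.
    """
    if population_column != "population":
        data = data.rename(columns={population_column: "population"})
    spec = ModelSpec(outcome, ["population", grs_column], transform=transform)
    sub = _complete_cases(data, spec.required_columns())
    levels = sorted(sub["population"].astype(str).unique())
    if len(levels) < 2:
        raise ValidationError("moderation test needs at least 2 populations")
    counts = sub["population"].value_counts()
    empty = [l for l in levels if counts.get(l, 0) == 0]
    if empty:
        log.warning("dropping empty population levels: %s", empty)
    y = sub[outcome].astype(float).to_numpy()
    if spec.transform == "log":
        y = np.log(y)
    Xr = build_design(sub, ["population", grs_column])
    Xf = build_design(sub, ["population", grs_column,
                            f"population:{grs_column}"])
    _check_full_rank(Xf)
    Ar, Af = Xr.to_numpy(float), Xf.to_numpy(float)
    r2_red, r2_full = _ols_r2(Ar, y), _ols_r2(Af, y)
    df1 = Af.shape[1] - Ar.shape[1]
    df2 = len(y) - Af.shape[1]
    return nested_f_test(r2_red, r2_full, df1, df2)


def joint_noncorresponding_test(outcome_trait: str, data: pd.DataFrame,
                                include_covariates: bool = True
                                ) -> tuple[NestedTestResult, pd.DataFrame]:
    """Do the other three traits' scores add information beyond the trait's own?

    Full model: covariates + all four scores; reduced: covariates + the
    corresponding score (3-df F-test). Also returns the full-model per-score
    coefficient table. ``include_covariates=False`` drops age/age²/sex from
    both models (the literal reduced-form comparison).
    """
    if outcome_trait not in TRAITS:
        raise ValidationError(f"unknown trait {outcome_trait!r}")
    own = f"{outcome_trait}_GRS"
    missing = [c for c in GRS_COLUMNS if c not in data.columns]
    if missing:
        raise ValidationError(f"missing GRS columns: {missing}")
    covs = COVARIATES if include_covariates else ()
    spec = ModelSpec(outcome_trait, list(GRS_COLUMNS), covariates=covs)
    needed = [outcome_trait, *GRS_COLUMNS] + (["age", "sex"] if covs else [])
    sub = _complete_cases(data, needed)
    y = sub[outcome_trait].astype(float).to_numpy()
    if spec.transform == "log":
        y = np.log(y)
    Xf = build_design(sub, list(GRS_COLUMNS), covariates=covs)
    Xr = build_design(sub, [own], covariates=covs)
    _check_full_rank(Xf)
    Af, Ar = Xf.to_numpy(float), Xr.to_numpy(float)
    r2_red, r2_full = _ols_r2(Ar, y), _ols_r2(Af, y)
    df1 = Af.shape[1] - Ar.shape[1]
    test = nested_f_test(r2_red, r2_full, df1, len(y) - Af.shape[1])
    import statsmodels.api as sm

    res = sm.OLS(y, Xf).fit()
    coefs = pd.DataFrame({"coef": res.params, "se": res.bse, "p": res.pvalues})
    coefs = coefs.loc[[c for c in GRS_COLUMNS]]
    return test, coefs.reset_index(names="grs")


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Nagelkerke's normalized likelihood-ratio pseudo-R².

        R²_N = [1 − exp(2(ll0 − ll1)/n)] / [1 − exp(2·ll0/n)]

    0 when the full model adds nothing; 1 at a perfect fit.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValidationError("full-model log-likelihood below null model's")
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom == 0.0:
        raise ValidationError("degenerate outcome: null log-likelihood is 0")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    return float(min(1.0, max(0.0, cox_snell / denom)))


def outcome_panel(data: pd.DataFrame, outcomes: list[str],
                  by_population: bool = True) -> pd.DataFrame:
    """Joint 4-score association with clinical outcomes, per population.

    Continuous outcomes: ΔR² over covariates with a 4-df F-test. Binary
    outcomes: ΔNagelkerke-R² with a 4-df likelihood-ratio test. A population
    where a binary outcome has a single observed class (or a fit fails)
    yields an undefined row rather than an error.
    """
    from .data_io import BINARY_OUTCOMES

    rows = []
    groups = (data.groupby("population", sort=True) if by_population
              else [("all", data)])
    for pop, grp in groups:
        for outcome in outcomes:
            if outcome not in grp.columns:
                raise ValidationError(f"outcome column {outcome!r} absent")
            family = "logistic" if outcome in BINARY_OUTCOMES else "linear"
            row = {"population": pop, "outcome": outcome, "family": family,
                   "delta_r2": np.nan, "p": np.nan, "n": 0}
            coefs: dict[str, float] = {f"coef_{g}": np.nan for g in GRS_COLUMNS}
            try:
                full = fit_model(ModelSpec(outcome, list(GRS_COLUMNS),
                                           family=family), grp)
                red = fit_model(ModelSpec(outcome, [], family=family), grp)
                if family == "linear":
                    test = nested_f_test(red.r2, full.r2, 4, full.df_resid)
                    row.update(delta_r2=full.r2 - red.r2, p=test.p, n=full.n)
                else:
                    lr = 2.0 * (full.loglik - red.loglik)
                    # ΔNagelkerke is referenced to the intercept-only likelihood
                    null = fit_model(
                        ModelSpec(outcome, [], family=family, covariates=()), grp
                    )
                    dn = (nagelkerke_r2(null.loglik, full.loglik, full.n)
                          - nagelkerke_r2(null.loglik, red.loglik, red.n))
                    row.update(delta_r2=dn,
                               p=float(stats.chi2.sf(max(lr, 0.0), 4)), n=full.n)
                for g in GRS_COLUMNS:
                    coefs[f"coef_{g}"] = float(full.params[g])
            except (FitError, ValidationError) as exc:
                log.warning("outcome %s in population %s undefined: %s",
                            outcome, pop, exc)
            rows.append({**row, **coefs})
    return pd.DataFrame(rows)
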