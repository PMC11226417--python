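"""The statistical association battery.

Stratified correlations between scores and parental lifespan, top-vs-bottom
decile lifespan contrasts, covariate-adjusted linear models on dead parents,
right-censored Cox proportional-hazards models on all parents, disease and
COVID-death logistic models co-adjusted for the disease risk score, and a
per-variant linear scan.

Conventions shared by the model functions:

* the analysis cohort always excludes adopted participants and rows with no
  parental record; linear/correlation/decile analyses additionally require
  the parent to be dead (lifespan observed), while the Cox model keeps
  alive parents as right-censored observations;
* lifespan models adjust for participant birth year, genotyping batch,
  assessment center and the leading genotype principal components (40 by
  default; 10 for the per-variant scan, which adjusts for batch but not
  center); disease models adjust for the disease risk score, age, sex
  (omitted for single-sex diseases) and 40 PCs; the COVID-death model
  adjusts for sex, birth year and 40 PCs only;
* every result records the design columns actually used, so the covariate
  contract is inspectable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .panel import DosagePanel

__all__ = [
    "AssociationResult",
    "CohortEmptyError",
    "SeparationError",
    "analysis_cohort",
    "lifespan_correlations",
    "decile_contrast",
    "lifespan_linear_model",
    "lifespan_cox_model",
    "disease_logistic_model",
    "covid_death_model",
    "single_variant_scan",
    "lifespan_battery",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

PARENTS = ("father", "mother")
SEXES = ("male", "female")


class CohortEmptyError(ValueError):
    """No individuals satisfy the cohort filters."""


class SeparationError(RuntimeError):
    """Perfect separation in a logistic model; retry with penalized=True."""


@dataclass(frozen=True)
class AssociationResult:
    """One fitted term of one model in one stratum."""

    model: str  # pearson | spearman | welch_t | linear | coxph | logistic
    outcome: str
    term: str
    estimate: float
    se: float
    p_value: float
    n_used: int
    stratum: str
    design_columns: tuple[str, ...] = ()
    note: str | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def ci(self) -> tuple[float, float]:
        """Wald 95% interval on the estimate's own scale."""
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def ratio(self) -> float:
        """exp(estimate): hazard or odds ratio for coxph/logistic terms."""
        return math.exp(self.estimate)

    @property
    def ratio_ci(self) -> tuple[float, float]:
        lo, hi = self.ci
        return (math.exp(lo), math.exp(hi))


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy table: one row per model x stratum x term."""
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "outcome": r.outcome,
                "term": r.term,
                "estimate": r.estimate,
                "se": r.se,
                "p_value": r.p_value,
                "n_used": r.n_used,
                "stratum": r.stratum,
                "note": r.note or "",
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def analysis_cohort(
    phenos: pd.DataFrame,
    parent: str,
    require_dead: bool = True,
    participant_sex: str = "all",
) -> pd.DataFrame:
    """Filter to the analysis cohort for one parent.

    Removes adopted participants (non-biological parents) and rows without
    a parental record; with ``require_dead`` (the regression path) alive
    parents are excluded, without it they stay for right censoring.
    """
    if parent not in PARENTS:
        raise ValueError(f"parent must be one of {PARENTS}, got {parent!r}")
    df = phenos[phenos["adopted"].astype(float) != 1]
    df = df[df[f"{parent}_age"].notna() & df[f"{parent}_alive"].notna()]
    if participant_sex != "all":
        if participant_sex not in SEXES:
            raise ValueError(f"participant_sex must be 'male', 'female' or 'all'")
        df = df[df["sex"] == participant_sex]
    if require_dead:
        df = df[df[f"{parent}_alive"] == 0]
    if df.empty:
        raise CohortEmptyError(
            f"empty cohort: parent={parent}, require_dead={require_dead}, "
            f"sex={participant_sex}"
        )
    return df


def _aligned_score(scores: pd.Series, df: pd.DataFrame) -> np.ndarray:
    s = scores.reindex(df["sample_id"])
    if s.isna().any():
        missing = s.index[s.isna()][:3].tolist()
        raise ValueError(f"scores missing for samples {missing} ...")
    return s.to_numpy(dtype=float)


def _pc_columns(df: pd.DataFrame, n_pcs: int) -> list[str]:
    cols = [f"pc{i + 1}" for i in range(n_pcs)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks PC columns {missing[:3]} ...")
    return cols


def _design(
    df: pd.DataFrame,
    primary: dict[str, np.ndarray],
    *,
    birth_year: bool = False,
    batch: bool = False,
    center: bool = False,
    age: bool = False,
    sex: bool = False,
    n_pcs: int = 0,
) -> pd.DataFrame:
    """Assemble a design matrix; degenerate (constant) columns are dropped
    with a logged notice, and an intercept is prepended."""
    parts: dict[str, np.ndarray] = dict(primary)
    if birth_year:
        parts["birth_year"] = df["birth_year"].to_numpy(dtype=float)
    if age:
        parts["age"] = df["age"].to_numpy(dtype=float)
    if sex:
        parts["sex_male"] = (df["sex"] == "male").to_numpy(dtype=float)
    X = pd.DataFrame(parts, index=df.index)
    for cat, flag in (("batch", batch), ("center", center)):
        if flag:
            dummies = pd.get_dummies(df[cat], prefix=cat, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    if n_pcs:
        X = pd.concat([X, df[_pc_columns(df, n_pcs)]], axis=1)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.info("dropping degenerate design columns: %s", constant)
        X = X.drop(columns=constant)
    X.insert(0, "const", 1.0)
    return X.astype(float)


# ---------------------------------------------------------------------------
# correlations and decile contrasts
# ---------------------------------------------------------------------------

def lifespan_correlations(
    scores: pd.Series,
    phenos: pd.DataFrame,
    parent: str,
    participant_sex: str = "all",
) -> tuple[AssociationResult, AssociationResult]:
    """Pearson and Spearman correlations between score and parental
    lifespan among dead parents, with two-sided p-values."""
    df = analysis_cohort(phenos, parent, require_dead=True, participant_sex=participant_sex)
    if len(df) < 3:
        raise ValueError(f"need >= 3 observations, got {len(df)}")
    s = _aligned_score(scores, df)
    y = df[f"{parent}_age"].to_numpy(dtype=float)
    stratum = f"{participant_sex}/{parent}"
    pear = stats.pearsonr(s, y)
    spear = stats.spearmanr(s, y)
    n = len(df)
    se_r = math.sqrt((1 - pear.statistic**2) / max(n - 2, 1))
    return (
        AssociationResult("pearson", f"{parent}_lifespan", scores.name or "score",
                          float(pear.statistic), se_r, float(pear.pvalue), n, stratum),
        AssociationResult("spearman", f"{parent}_lifespan", scores.name or "score",
                          float(spear.statistic), se_r, float(spear.pvalue), n, stratum),
    )


def decile_contrast(
    scores: pd.Series,
    phenos: pd.DataFrame,
    parent: str,
    quantile: float = 0.10,
    participant_sex: str = "all",
) -> AssociationResult:
    """Welch t-test of lifespan between the score's upper and lower tails.

    Group membership is value-based: everyone at or above the (1-q)
    quantile vs everyone at or below the q quantile, so a tied score value
    is never split across groups (important for few-valued scores).
    Estimate = upper-group mean minus lower-group mean, in years.
    """
    if not (0.0 < quantile < 0.5):
        raise ValueError("quantile must lie in (0, 0.5)")
    df = analysis_cohort(phenos, parent, require_dead=True, participant_sex=participant_sex)
    s = _aligned_score(scores, df)
    if np.unique(s).size < 2:
        raise ValueError("score has fewer than 2 distinct values")
    lo_thr = np.quantile(s, quantile)
    hi_thr = np.quantile(s, 1.0 - quantile)
    lower = s <= lo_thr
    upper = s >= hi_thr
    if (lower & upper).any():
        raise ValueError(
            f"tie structure collapses the tails: threshold values "
            f"{lo_thr:.4g} and {hi_thr:.4g} select overlapping groups"
        )
    y = df[f"{parent}_age"].to_numpy(dtype=float)
    y_up, y_lo = y[upper], y[lower]
    if len(y_up) == 0 or len(y_lo) == 0:
        raise ValueError("empty tail group after tie handling")
    t = stats.ttest_ind(y_up, y_lo, equal_var=False)
    est = float(y_up.mean() - y_lo.mean())
    se = math.sqrt(y_up.var(ddof=1) / len(y_up) + y_lo.var(ddof=1) / len(y_lo))
    return AssociationResult(
        "welch_t", f"{parent}_lifespan", scores.name or "score",
        est, se, float(t.pvalue), int(len(y_up) + len(y_lo)),
        f"{participant_sex}/{parent}",
        note=f"n_upper={len(y_up)},n_lower={len(y_lo)}",
    )


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

def lifespan_linear_model(
    scores: pd.Series,
    phenos: pd.DataFrame,
    parent: str,
    participant_sex: str = "all",
    n_pcs: int = 40,
) -> AssociationResult:
    """OLS of dead parents' lifespan on the score, adjusting for birth
    year, batch, center and the leading PCs.  Returns the score term
    (years per score unit)."""
    df = analysis_cohort(phenos, parent, require_dead=True, participant_sex=participant_sex)
    X = _design(df, {"score": _aligned_score(scores, df)},
                birth_year=True, batch=True, center=True, n_pcs=n_pcs)
    y = df[f"{parent}_age"].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        "linear", f"{parent}_lifespan", scores.name or "score",
        float(fit.params["score"]), float(fit.bse["score"]),
        float(fit.pvalues["score"]), int(fit.nobs),
        f"{participant_sex}/{parent}", design_columns=tuple(X.columns),
    )


def lifespan_cox_model(
    scores: pd.Series,
    phenos: pd.DataFrame,
    parent: str,
    participant_sex: str = "all",
    n_pcs: int = 40,
) -> AssociationResult:
    """Cox proportional-hazards fit on all parents, alive ones
    right-censored at their age at assessment.  Same covariates as the
    linear model; Efron handling for tied event times.  Returns the
    log-hazard per score unit (protective scores have HR < 1)."""
    df = analysis_cohort(phenos, parent, require_dead=False, participant_sex=participant_sex)
    event = (df[f"{parent}_alive"] == 0).astype(int)
    if event.sum() == 0:
        raise ValueError(f"no death events for parent={parent}")
    X = _design(df, {"score": _aligned_score(scores, df)},
                birth_year=True, batch=True, center=True, n_pcs=n_pcs)
    frame = X.drop(columns=["const"]).copy()
    frame["duration"] = df[f"{parent}_age"].to_numpy(dtype=float)
    frame["event"] = event.to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="duration", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox model failed to converge for parent={parent}: {exc}"
        ) from exc
    row = cph.summary.loc["score"]
    return AssociationResult(
        "coxph", f"{parent}_survival", scores.name or "score",
        float(row["coef"]), float(row["se(coef)"]), float(row["p"]),
        int(len(frame)), f"{participant_sex}/{parent}",
        design_columns=tuple(X.columns),
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame, penalized: bool, context: str):
    """Maximum-likelihood logistic fit; optional ridge fallback for
    separated data (small L2 penalty, Wald SEs from the penalized
    Hessian)."""
    if penalized:
        return _ridge_logit(y, X, alpha=1.0)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and kin
        raise SeparationError(
            f"{context}: logistic fit failed ({exc}); consider penalized=True"
        ) from exc
    if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse).all():
        raise SeparationError(
            f"{context}: logistic fit did not converge (possible separation); "
            "consider penalized=True"
        )
    return fit


class _RidgeLogitFit:
    def __init__(self, params: pd.Series, bse: pd.Series, pvalues: pd.Series, nobs: int):
        self.params, self.bse, self.pvalues, self.nobs = params, bse, pvalues, nobs


def _ridge_logit(y: np.ndarray, X: pd.DataFrame, alpha: float = 1.0) -> _RidgeLogitFit:
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    pen = np.full(p, alpha)
    pen[list(X.columns).index("const")] = 0.0  # do not shrink the intercept
    beta = np.zeros(p)
    for _ in range(100):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = A.T @ (y - mu) - pen * beta
        H = A.T @ (A * W[:, None]) + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    idx = X.columns
    return _RidgeLogitFit(
        pd.Series(beta, index=idx), pd.Series(se, index=idx),
        pd.Series(pvals, index=idx), n,
    )


def disease_logistic_model(
    scores: pd.Series,
    prs: pd.Series,
    phenos: pd.DataFrame,
    disease: str,
    n_pcs: int = 40,
    penalized: bool = False,
) -> list[AssociationResult]:
    """Logistic model of disease status on the longevity score, co-adjusted
    for the disease risk score, age, sex and the leading PCs.

    For single-sex diseases (only one sex carries a non-missing indicator)
    the sex column is omitted from the design.  Returns the longevity-score
    term first, then the co-adjusted risk-score term.
    """
    df = phenos[phenos[disease].notna()]
    y = df[disease].to_numpy(dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError(f"disease {disease!r} needs >= 1 case and >= 1 control")
    both_sexes = df["sex"].nunique() > 1
    X = _design(
        df,
        {"score": _aligned_score(scores, df), "prs": _aligned_score(prs, df)},
        age=True, sex=both_sexes, n_pcs=n_pcs,
    )
    fit = _fit_logit(y, X, penalized, context=f"disease {disease!r}")
    out = []
    for term, label in (("score", scores.name or "score"), ("prs", prs.name or "prs")):
        out.append(
            AssociationResult(
                "logistic", disease, label,
                float(fit.params[term]), float(fit.bse[term]),
                float(fit.pvalues[term]), int(len(df)),
                f"all/{disease}", design_columns=tuple(X.columns),
            )
        )
    return out


def covid_death_model(
    scores: pd.Series,
    phenos: pd.DataFrame,
    n_pcs: int = 40,
    penalized: bool = False,
) -> AssociationResult:
    """Logistic model of COVID death among the COVID-infected, on the
    score plus sex, birth year and the leading PCs (no batch/center)."""
    df = phenos[phenos["covid_infected"].astype(float) == 1]
    if df.empty:
        raise CohortEmptyError("no COVID-infected individuals")
    y = df["covid_death"].to_numpy(dtype=float)
    if y.sum() < 1:
        raise ValueError("no COVID deaths among the infected")
    X = _design(df, {"score": _aligned_score(scores, df)},
                birth_year=True, sex=True, n_pcs=n_pcs)
    fit = _fit_logit(y, X, penalized, context="covid death")
    return AssociationResult(
        "logistic", "covid_death", scores.name or "score",
        float(fit.params["score"]), float(fit.bse["score"]),
        float(fit.pvalues["score"]), int(len(df)), "covid_infected",
        design_columns=tuple(X.columns),
    )


# ---------------------------------------------------------------------------
# per-variant scan
# ---------------------------------------------------------------------------

def single_variant_scan(
    panel: DosagePanel,
    phenos: pd.DataFrame,
    parent: str,
    participant_sex: str = "all",
    n_pcs: int = 10,
) -> list[AssociationResult]:
    """One linear model per panel variant: dead parents' lifespan on
    dosage, adjusting for birth year, batch and the first ``n_pcs`` PCs.

    Fitted by residualizing outcome and dosages against the shared
    covariates once (Frisch–Waugh–Lovell), which is algebraically the full
    per-variant OLS.  Monomorphic variants are returned flagged, not
    fitted.  Results follow panel variant order.
    """
    df = analysis_cohort(phenos, parent, require_dead=True, participant_sex=participant_sex)
    Z = _design(df, {}, birth_year=True, batch=True, n_pcs=n_pcs)
    design_cols = tuple(Z.columns) + ("dosage",)
    Zm = Z.to_numpy(dtype=float)
    y = df[f"{parent}_age"].to_numpy(dtype=float)

    pos = {s: i for i, s in enumerate(panel.samples)}
    rows = np.array([pos[s] for s in df["sample_id"]], dtype=int)
    D = panel.dosages[rows, :].copy()
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])

    Q, _ = np.linalg.qr(Zm)
    ry = y - Q @ (Q.T @ y)
    RD = D - Q @ (Q.T @ D)
    n, p = Zm.shape
    dof = n - p - 1
    stratum = f"{participant_sex}/{parent}"

    results: list[AssociationResult] = []
    denom = np.einsum("ij,ij->j", RD, RD)
    num = RD.T @ ry
    for j in range(panel.n_variants):
        vid = panel.variants.at[j, "variant_id"]
        if np.nanstd(D[:, j]) == 0 or denom[j] <= 1e-12:
            results.append(
                AssociationResult(
                    "linear", f"{parent}_lifespan", vid,
                    float("nan"), float("nan"), float("nan"), n, stratum,
                    design_columns=design_cols, note="monomorphic",
                )
            )
            continue
        beta = num[j] / denom[j]
        rss = float(ry @ ry) - beta * num[j]
        sigma2 = rss / dof
        se = math.sqrt(max(sigma2, 0.0) / denom[j])
        tval = beta / se if se > 0 else float("nan")
        pval = 2.0 * stats.t.sf(abs(tval), dof) if se > 0 else float("nan")
        results.append(
            AssociationResult(
                "linear", f"{parent}_lifespan", vid,
                float(beta), float(se), float(pval), n, stratum,
                design_columns=design_cols,
            )
        )
    return results


# ---------------------------------------------------------------------------
# convenience battery
# ---------------------------------------------------------------------------

def lifespan_battery(
    scores: pd.DataFrame,
    phenos: pd.DataFrame,
    n_pcs: int = 40,
    quantile: float = 0.10,
) -> list[AssociationResult]:
    """Run correlations, decile contrast, linear and Cox models for every
    score over all four participant-sex x parent strata."""
    results: list[AssociationResult] = []
    for score_id in scores.columns:
        s = scores[score_id]
        for sex in SEXES:
            for parent in PARENTS:
                pear, spear = lifespan_correlations(s, phenos, parent, sex)
                results.extend([pear, spear])
                results.append(decile_contrast(s, phenos, parent, quantile, sex))
                results.append(lifespan_linear_model(s, phenos, parent, sex, n_pcs))
                results.append(lifespan_cox_model(s, phenos, parent, sex, n_pcs))
    return results
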