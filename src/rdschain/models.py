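"""Design-weighted logistic regression for the healthcare-use outcome.

The multivariate model uses the published dichotomizations: age 15-24 vs
25+, college education yes/no, pregnant yes/no, fair/poor vs good self-rated
health, and irregular vs not-irregular (asylum seeker or resident) migratory
status. Fitting maximizes the weight-weighted log-likelihood by iteratively
reweighted least squares. RDS weights are not classical survey weights, so
the default confidence intervals come from the chain bootstrap (refitting
on every replicate); a recruiter-clustered sandwich covariance is available
as a fast alternative, and the naive model-based covariance backs the Wald
p-values of the bivariate screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bootstrap import chain_bootstrap_resample
from .estimation import WeightSet
from .exceptions import ConvergenceError, DesignError, EstimationError, SchemaError
from .records import StudyDataset

#: Default covariate set of the multivariate model (reference level second).
DICHOTOMIES: dict[str, tuple[str, str]] = {
    "age_15_24": ("15-24", "25+"),
    "college": ("yes", "no"),
    "pregnant": ("yes", "no"),
    "fair_poor_health": ("fair/poor", "good"),
    "irregular": ("irregular", "not irregular"),
}


def dichotomize(df: pd.DataFrame) -> pd.DataFrame:
    """0/1 design columns for the published covariate groupings.

    Accepts any frame with the study attribute columns (participant tables
    and synthetic-population frames alike).
    """
    out = pd.DataFrame(index=df.index)
    out["age_15_24"] = (df["age_group"] == "15-24").astype(float)
    out["college"] = (df["education"] == "college").astype(float)
    out["pregnant"] = df["pregnant"].astype(float)
    out["fair_poor_health"] = df["self_rated_health"].isin(["fair", "poor"]).astype(float)
    out["irregular"] = (df["migratory_status"] == "irregular").astype(float)
    return out


@dataclass
class LogisticFit:
    """A converged weighted logistic fit with its reference-coding map."""

    outcome: str
    terms: list[str]  # including "const"
    coefficients: pd.Series
    cov: np.ndarray
    n_obs: int
    deviance: float
    n_iter: int
    converged: bool
    coding: dict[str, tuple[str, str]] = field(default_factory=dict)
    ci_lower: Optional[pd.Series] = None  # on the OR scale
    ci_upper: Optional[pd.Series] = None
    ci_method: Optional[str] = None
    level: float = 0.95

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.terms)

    def p_values(self) -> pd.Series:
        from scipy import stats

        z = self.coefficients / self.standard_errors()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.terms)


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    term_names: Optional[Sequence[str]] = None,
    on_separation: str = "error",
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Weighted logistic maximum likelihood via IRLS with step-halving.

    Returns (beta, model_based_covariance, deviance, iterations, converged).
    Convergence = max absolute coefficient change below ``tol``. Under
    (quasi-)separation the likelihood is monotone and a coefficient runs away;
    ``on_separation='error'`` raises :class:`ConvergenceError` naming the
    runaway term, while ``'clip'`` pins the estimate at +-15 on the log-odds
    scale and returns it flagged unconverged (used by bootstrap refits, where
    a diverged replicate belongs in the percentile tail rather than being
    dropped). A rank-deficient design raises :class:`DesignError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")
    names = list(term_names) if term_names is not None else [f"x{j}" for j in range(p)]

    def deviance_of(beta: np.ndarray) -> float:
        eta = X @ beta
        # log(1+exp(eta)) - y*eta, numerically stable
        ll = w * (y * eta - np.logaddexp(0.0, eta))
        return float(-2.0 * ll.sum())

    beta = np.zeros(p)
    dev = deviance_of(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(mu * (1.0 - mu), 1e-12, None)
        W = w * v
        z = eta + (y - mu) / v
        XtW = X.T * W
        try:
            step_target = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise DesignError(f"singular weighted design: {exc}") from exc
        delta = step_target - beta
        new_dev = deviance_of(step_target)
        halvings = 0
        while new_dev > dev + 1e-10 and halvings < 30:
            delta = delta / 2.0
            step_target = beta + delta
            new_dev = deviance_of(step_target)
            halvings += 1
        beta, dev = step_target, new_dev
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged or np.max(np.abs(beta)) > 30:
        if on_separation == "clip":
            beta = np.clip(beta, -15.0, 15.0)
            converged = False
        else:
            runaway = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"no convergence after {it} iterations "
                f"(possible separation on term {runaway!r})"
            )
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = w * np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X.T * W) @ X
    cov = np.linalg.inv(info) if converged else np.linalg.pinv(info)
    return beta, cov, deviance_of(beta), it, converged


def _design_matrix(
    dataset: StudyDataset,
    outcome: str,
    covariates: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    recruits = dataset.recruits()
    if outcome not in recruits.columns:
        raise SchemaError(f"outcome {outcome!r} not in dataset")
    design = dichotomize(recruits)
    unknown = [c for c in covariates if c not in design.columns]
    if unknown:
        raise SchemaError(f"unknown covariates {unknown}")
    frame = recruits[["participant_id", "recruiter_id", outcome]].copy()
    frame = pd.concat([frame, design[list(covariates)]], axis=1)
    frame = frame.dropna(subset=[outcome])
    y = frame[outcome].astype(float).to_numpy()
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in covariates]
    )
    terms = ["const"] + list(covariates)
    return X, y, terms, frame


def fit_weighted_logistic(
    dataset: StudyDataset,
    weights: Optional[WeightSet],
    outcome: str = "used_health_service_15d",
    covariates: Sequence[str] = tuple(DICHOTOMIES),
    robust: Optional[str] = None,
    on_separation: str = "error",
) -> LogisticFit:
    """Fit the design-weighted multivariate logistic model on non-seeds.

    Weights are rescaled to mean 1 before fitting so deviances are comparable
    across datasets; with ``weights=None`` this is an ordinary unit-weight
    fit. ``robust='cluster'`` replaces the model-based covariance with a
    sandwich clustered on the recruiter.
    """
    X, y, terms, frame = _design_matrix(dataset, outcome, covariates)
    if y.min() == y.max():
        raise EstimationError(f"outcome {outcome!r} is constant; model degenerate")
    if weights is None:
        w = np.ones(len(y))
    else:
        w = weights.weights.reindex(frame["participant_id"]).to_numpy(dtype=float)
        if np.isnan(w).any():
            raise EstimationError("weights missing for some modeled participants")
        w = w / w.mean()
    beta, cov, dev, n_iter, converged = irls_logistic(
        X, y, w, term_names=terms, on_separation=on_separation
    )
    if robust == "cluster":
        cov = _cluster_sandwich(X, y, w, beta, cov, frame["recruiter_id"])
    return LogisticFit(
        outcome=outcome,
        terms=terms,
        coefficients=pd.Series(beta, index=terms),
        cov=cov,
        n_obs=len(y),
        deviance=dev,
        n_iter=n_iter,
        converged=converged,
        coding={c: DICHOTOMIES[c] for c in covariates if c in DICHOTOMIES},
    )


def _cluster_sandwich(X, y, w, beta, bread_inv, cluster_ids) -> np.ndarray:
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    score = (w * (y - mu))[:, None] * X
    groups = pd.Series(range(len(y))).groupby(cluster_ids.to_numpy()).groups
    meat = np.zeros((X.shape[1], X.shape[1]))
    for _, idx in groups.items():
        s = score[list(idx)].sum(axis=0)
        meat += np.outer(s, s)
    return bread_inv @ meat @ bread_inv


def add_bootstrap_ci(
    fit: LogisticFit,
    dataset: StudyDataset,
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    bounds: tuple[int, int] = (3, 150),
) -> LogisticFit:
    """Percentile chain-bootstrap CIs for the odds ratios, refitting the
    model (weights included) on every chain replicate."""
    from .estimation import compute_rds2_weights

    rng = np.random.default_rng(seed)
    covariates = [t for t in fit.terms if t != "const"]
    rows = []
    failures = 0
    for _ in range(B):
        replicate = chain_bootstrap_resample(dataset, rng)
        try:
            w = compute_rds2_weights(replicate, bounds=bounds)
            refit = fit_weighted_logistic(
                replicate, w, outcome=fit.outcome, covariates=covariates,
                on_separation="clip",
            )
            rows.append(refit.coefficients)
        except Exception:  # noqa: BLE001 - replicate-level failure tolerated
            failures += 1
    if failures > 0.1 * B:
        raise EstimationError(f"model failed on {failures}/{B} bootstrap replicates")
    coefs = pd.DataFrame(rows)
    alpha = (1.0 - level) / 2.0
    fit.ci_lower = np.exp(coefs.quantile(alpha))
    fit.ci_upper = np.exp(coefs.quantile(1.0 - alpha))
    fit.ci_method = "chain-bootstrap percentile"
    fit.level = level
    return fit


@dataclass
class AssociationTable:
    """Bivariate screen of the outcome against one explanatory variable."""

    outcome: str
    explanatory: str
    categories: list
    prevalence: pd.Series  # weighted outcome prevalence per category
    statistic: float
    df: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": self.categories,
            "outcome_prevalence": self.prevalence.values,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        })


def bivariate_association(
    dataset: StudyDataset,
    weights: Optional[WeightSet],
    outcome: str,
    explanatory: str,
) -> AssociationTable:
    """Weighted outcome prevalence per category of one explanatory variable,
    with a Wald chi-square from the bivariate weighted logistic model."""
    from scipy import stats

    recruits = dataset.recruits()
    for col in (outcome, explanatory):
        if col not in recruits.columns:
            raise SchemaError(f"variable {col!r} not in dataset")
    frame = recruits[["participant_id", outcome, explanatory]].dropna()
    if frame[outcome].astype(float).nunique() < 2:
        raise EstimationError(f"outcome {outcome!r} is constant; association undefined")
    if weights is None:
        w = np.ones(len(frame))
    else:
        w = weights.weights.reindex(frame["participant_id"]).to_numpy(dtype=float)
    y = frame[outcome].astype(float).to_numpy()
    cats = sorted(frame[explanatory].unique(), key=str)
    wsum = pd.Series(w, index=frame.index).groupby(frame[explanatory]).sum()
    wpos = pd.Series(w * y, index=frame.index).groupby(frame[explanatory]).sum()
    prevalence = (wpos / wsum).reindex(cats)

    # joint Wald test of the category dummies (reference = first category)
    dummies = np.column_stack(
        [np.ones(len(frame))]
        + [(frame[explanatory] == c).to_numpy(dtype=float) for c in cats[1:]]
    )
    beta, cov, *_ = irls_logistic(
        dummies, y, w / w.mean(), term_names=["const"] + [str(c) for c in cats[1:]]
    )
    k = len(cats) - 1
    if k == 0:
        raise EstimationError(f"{explanatory!r} has a single category")
    b = beta[1:]
    V = cov[1:, 1:]
    stat = float(b @ np.linalg.solve(V, b))
    p = float(stats.chi2.sf(stat, k))
    return AssociationTable(
        outcome=outcome,
        explanatory=explanatory,
        categories=cats,
        prevalence=prevalence,
        statistic=stat,
        df=k,
        p_value=p,
    )


def odds_ratio_report(fit: LogisticFit) -> pd.DataFrame:
    """OR table in the published layout: one row per covariate level, OR,
    CI bounds, p-value; reference rows print OR 1.00 with empty CI."""
    se = fit.standard_errors()
    p = fit.p_values()
    ors = fit.odds_ratios
    rows = []
    for term in fit.terms:
        if term == "const":
            continue
        shown, reference = fit.coding.get(term, (term, "reference"))
        lower = upper = np.nan
        if fit.ci_lower is not None and term in fit.ci_lower.index:
            lower, upper = float(fit.ci_lower[term]), float(fit.ci_upper[term])
        rows.append({
            "variable": term, "level": shown, "OR": float(ors[term]),
            "LL": lower, "UL": upper, "p_value": float(p[term]),
        })
        rows.append({
            "variable": term, "level": reference, "OR": 1.0,
            "LL": np.nan, "UL": np.nan, "p_value": np.nan,
        })
    return pd.DataFrame(rows)
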