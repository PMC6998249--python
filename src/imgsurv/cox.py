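"""Cox proportional-hazards baseline over feature tables.

The semiparametric Cox model relates covariates x to the hazard through
``h(t | x) = h0(t) exp(x' beta)``. This module maximizes the Breslow-ties
log partial likelihood by Newton's method with step-halving, and fits the
L1-penalized version by iteratively reweighted quadratic approximation with
cyclic coordinate descent and soft-thresholding (features are z-scored
internally; coefficients are reported on the original scale). A
cross-validated penalty path reproduces the LASSO-Cox feature-selection
workflow used to benchmark learned image features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "cox_fit",
    "cox_risk_score",
    "lasso_path_select",
    "LassoSelection",
    "CoxPH",
    "CoxPHResults",
]


@dataclass
class CoxFit:
    """A fitted Cox model: log hazard ratios and fit diagnostics."""

    coefficients: pd.Series
    converged: bool
    log_partial_likelihood: float
    selected_features: list[str] = field(default_factory=list)
    standard_errors: pd.Series | None = None
    l1_penalty: float = 0.0
    n_iter: int = 0
    separation_suspected: bool = False


# ---------------------------------------------------------------------------
# Partial likelihood machinery (Breslow ties)


def _prepare(features, records: Sequence[SurvivalRecord]):
    """Align a feature table with records; returns (X, times, events, names)."""
    records = list(records)
    if isinstance(features, pd.DataFrame):
        df = features
        if "subject_id" in df.columns:
            df = df.set_index(df["subject_id"].astype(str)).drop(
                columns=["subject_id"]
            )
            df = df.loc[[r.subject_id for r in records]]
        num = df.select_dtypes(include=[np.number])
        names = list(num.columns.astype(str))
        x = num.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        names = [f"x{i+1}" for i in range(x.shape[1])]
    if x.shape[0] != len(records):
        raise ValueError(
            f"{x.shape[0]} feature rows for {len(records)} survival records"
        )
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    return x, times, events, names


def _breslow_loglik_grad_hess(
    beta: np.ndarray, x: np.ndarray, times: np.ndarray, events: np.ndarray,
    want_hess: bool = True,
):
    """Log partial likelihood, gradient and (negative-definite) Hessian.

    Processes distinct times from latest to earliest, accumulating the
    risk-set sums S0, S1, S2; tied event times share one Breslow denominator.
    """
    n, p = x.shape
    order = np.argsort(-times, kind="stable")
    xs = x[order]
    ts = times[order]
    es = events[order]
    eta = xs @ beta
    eta = eta - eta.max()  # overflow guard; cancels in all ratios
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p)) if want_hess else None
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        block = slice(i, j)
        wb = w[block]
        s0 += wb.sum()
        s1 += wb @ xs[block]
        if want_hess:
            s2 += (xs[block] * wb[:, None]).T @ xs[block]
        ev = es[block] == 1
        d = int(ev.sum())
        if d > 0:
            xbar = s1 / s0
            ll += eta[block][ev].sum() - d * np.log(s0)
            grad += xs[block][ev].sum(axis=0) - d * xbar
            if want_hess:
                hess -= d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, hess


def _newton_cox(x, times, events, tol=1e-8, max_iter=100):
    n, p = x.shape
    beta = np.zeros(p)
    ll, grad, hess = _breslow_loglik_grad_hess(beta, x, times, events)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            if it > 1:
                # information degenerates as |beta| runs away: monotone
                # likelihood (perfect separation)
                separation = True
                break
            raise ValueError(
                "singular information matrix (constant or collinear feature "
                "columns?)"
            ) from err
        # step-halving keeps the partial likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _breslow_loglik_grad_hess(
                cand, x, times, events
            )
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 50:
            separation = True
            break
        if delta < tol:
            converged = True
            break
    return beta, ll, hess, converged, separation, it


# ---------------------------------------------------------------------------
# L1 path: quadratic approximation + cyclic coordinate descent


def _l1_cox(x, times, events, lam, beta0=None, outer_iter=30, tol=1e-7):
    """Minimize -loglik/n + lam * ||beta||_1 on (already standardized) x."""
    n, p = x.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    for _ in range(outer_iter):
        ll, grad, hess = _breslow_loglik_grad_hess(beta, x, times, events)
        big_g = -grad / n
        big_a = -hess / n
        diag = np.clip(np.diag(big_a).copy(), 1e-10, None)
        b = beta.copy()
        for _ in range(200):
            max_change = 0.0
            for k in range(p):
                gk = big_g[k] + big_a[k] @ (b - beta) - diag[k] * b[k]
                new = np.sign(-gk) * max(abs(gk) - lam, 0.0) / diag[k]
                change = abs(new - b[k])
                if change > 0:
                    max_change = max(max_change, change)
                    b[k] = new
            if max_change < tol:
                break
        if np.max(np.abs(b - beta)) < tol:
            beta = b
            break
        beta = b
    return beta


def _standardize(x):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe, sd_safe


def cox_fit(
    features,
    records: Sequence[SurvivalRecord],
    l1_penalty: float = 0.0,
) -> CoxFit:
    """Fit a Cox model; unpenalized via Newton, penalized via coordinate descent.

    ``l1_penalty`` is on the scale of the per-observation negative log partial
    likelihood (``-loglik/n + l1_penalty * ||beta||_1``) over z-scored
    features; coefficients come back on the original feature scale.
    """
    x, times, events, names = _prepare(features, records)
    if l1_penalty < 0:
        raise ValueError("l1_penalty must be nonnegative")
    if events.sum() == 0:
        raise ValueError("no events: partial likelihood is constant")
    if l1_penalty == 0:
        sd = x.std(axis=0)
        if np.any(sd == 0):
            bad = [names[k] for k in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant feature columns at penalty 0: {bad}")
        beta, ll, hess, converged, separation, it = _newton_cox(x, times, events)
        if not converged and not separation:
            warnings.warn("Newton did not converge within max iterations",
                          stacklevel=2)
        if separation:
            warnings.warn(
                "monotone partial likelihood (perfect separation?) — "
                "coefficients are unreliable", stacklevel=2,
            )
        se = np.sqrt(np.abs(np.diag(np.linalg.pinv(-hess))))
        return CoxFit(
            coefficients=pd.Series(beta, index=names),
            converged=converged,
            log_partial_likelihood=float(ll),
            selected_features=[nm for nm, b in zip(names, beta) if b != 0],
            standard_errors=pd.Series(se, index=names),
            n_iter=it,
            separation_suspected=separation,
        )
    xs, sd = _standardize(x)
    beta_std = _l1_cox(xs, times, events, l1_penalty)
    beta = beta_std / sd
    ll, _, _ = _breslow_loglik_grad_hess(beta, x, times, events, want_hess=False)
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        converged=True,
        log_partial_likelihood=float(ll),
        selected_features=[nm for nm, b in zip(names, beta) if b != 0],
        l1_penalty=l1_penalty,
    )


def cox_risk_score(fit: CoxFit, features) -> pd.Series:
    """Linear predictor ``x' beta`` per subject (higher = higher risk)."""
    if isinstance(features, pd.DataFrame):
        ids = (
            features["subject_id"].astype(str).tolist()
            if "subject_id" in features.columns
            else [str(i) for i in features.index]
        )
        num = features.drop(columns=["subject_id"], errors="ignore").select_dtypes(
            include=[np.number]
        )
        if list(num.columns.astype(str)) != list(fit.coefficients.index):
            raise ValueError(
                "feature columns do not match the fitted coefficients"
            )
        x = num.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        ids = [str(i) for i in range(x.shape[0])]
        if x.shape[1] != fit.coefficients.size:
            raise ValueError(
                f"{x.shape[1]} features vs {fit.coefficients.size} coefficients"
            )
    return pd.Series(x @ fit.coefficients.to_numpy(), index=ids)


# ---------------------------------------------------------------------------
# Cross-validated LASSO path


@dataclass
class LassoSelection:
    selected_features: list[str]
    chosen_lambda: float
    coefficients: pd.Series
    cv_loglik: pd.DataFrame  # columns: lambda, mean, se


def default_lambda_grid(features, records, n_points: int = 50) -> np.ndarray:
    """Log-spaced grid from the smallest all-zero penalty down two decades."""
    x, times, events, _ = _prepare(features, records)
    xs, _ = _standardize(x)
    _, grad, _ = _breslow_loglik_grad_hess(
        np.zeros(x.shape[1]), xs, times, events, want_hess=False
    )
    lam_max = np.max(np.abs(grad)) / x.shape[0]
    return np.geomspace(lam_max, lam_max / 100.0, n_points)


def lasso_path_select(
    features,
    records: Sequence[SurvivalRecord],
    lambdas: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    rule: Literal["1se", "min"] = "1se",
) -> LassoSelection:
    """Choose the L1 penalty by K-fold cross-validated partial likelihood.

    The fold contribution at each penalty is the Verweij–van Houwelingen
    cross-validated log partial likelihood ``l_all(beta_-k) - l_-k(beta_-k)``.
    ``rule="1se"`` picks the sparsest penalty within one standard error of the
    best mean (parsimonious default for small cohorts); ``"min"`` picks the
    best mean itself. The model is refit on all data at the chosen penalty and
    the nonzero-coefficient features are returned.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    x, times, events, names = _prepare(features, records)
    if lambdas is None:
        lambdas = default_lambda_grid(features, records)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    xs, sd = _standardize(x)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    rng.shuffle(fold_of)

    cvpl = np.zeros((n_folds, lambdas.size))
    for k in range(n_folds):
        tr = fold_of != k
        if events[tr].sum() == 0:
            continue
        beta = None
        for li, lam in enumerate(lambdas):  # warm starts down the path
            beta = _l1_cox(xs[tr], times[tr], events[tr], lam, beta0=beta)
            ll_all, _, _ = _breslow_loglik_grad_hess(
                beta, xs, times, events, want_hess=False
            )
            ll_tr, _, _ = _breslow_loglik_grad_hess(
                beta, xs[tr], times[tr], events[tr], want_hess=False
            )
            cvpl[k, li] = ll_all - ll_tr
    mean = cvpl.mean(axis=0)
    se = cvpl.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmax(mean))
    if rule == "min":
        chosen = best
    elif rule == "1se":
        threshold = mean[best] - se[best]
        candidates = np.flatnonzero(mean >= threshold)
        chosen = int(candidates[0])  # lambdas sorted descending: sparsest first
    else:
        raise ValueError(f"unknown rule {rule!r}")
    lam_star = float(lambdas[chosen])
    beta_std = _l1_cox(xs, times, events, lam_star)
    coef = pd.Series(beta_std / sd, index=names)
    selected = [nm for nm, b in coef.items() if b != 0]
    if not selected:
        warnings.warn("LASSO path selected no features", stacklevel=2)
    return LassoSelection(
        selected_features=selected,
        chosen_lambda=lam_star,
        coefficients=coef,
        cv_loglik=pd.DataFrame(
            {"lambda": lambdas, "mean": mean, "se": se}
        ),
    )


# ---------------------------------------------------------------------------
# Model / Results objects


class CoxPH:
    """Cox proportional-hazards model bound to a feature table and records."""

    def __init__(self, features, records: Sequence[SurvivalRecord]) -> None:
        self.features = features
        self.records = list(records)
        _prepare(features, self.records)  # validate alignment early

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        duration_col: str = "time_days",
        event_col: str = "event",
        id_col: str = "subject_id",
    ) -> "CoxPH":
        """Build from one table holding id, duration, event and features."""
        records = [
            SurvivalRecord(str(row[id_col]), float(row[duration_col]),
                           int(row[event_col]))
            for _, row in df.iterrows()
        ]
        feats = df.drop(columns=[duration_col, event_col])
        return cls(feats, records)

    def fit(self, l1_penalty: float = 0.0) -> "CoxPHResults":
        return CoxPHResults(self, cox_fit(self.features, self.records, l1_penalty))

    def fit_regularized_path(
        self,
        lambdas: np.ndarray | None = None,
        n_folds: int = 5,
        seed: int = 0,
        rule: Literal["1se", "min"] = "1se",
    ) -> LassoSelection:
        return lasso_path_select(
            self.features, self.records, lambdas, n_folds, seed, rule
        )


class CoxPHResults:
    """Estimates, uncertainties and a summary table for a fitted Cox model."""

    def __init__(self, model: CoxPH, fit: CoxFit) -> None:
        self.model = model
        self._fit = fit

    @property
    def params(self) -> pd.Series:
        return self._fit.coefficients

    @property
    def bse(self) -> pd.Series | None:
        return self._fit.standard_errors

    @property
    def llf(self) -> float:
        return self._fit.log_partial_likelihood

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def selected_features(self) -> list[str]:
        return self._fit.selected_features

    def risk_scores(self, features=None) -> pd.Series:
        feats = features if features is not None else self.model.features
        return cox_risk_score(self._fit, feats)

    def summary(self) -> pd.DataFrame:
        """coef, hazard ratio and (unpenalized fits) Wald inference."""
        out = pd.DataFrame({"coef": self.params, "exp(coef)": np.exp(self.params)})
        if self.bse is not None:
            z = self.params / self.bse
            out["se(coef)"] = self.bse
            out["z"] = z
            out["p"] = 2 * stats.norm.sf(np.abs(z))
        return out

    def report(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "coefficients": self.params.to_dict(),
            "selected": self.selected_features,
            "lambda": self._fit.l1_penalty,
            "loglik": self.llf,
            "converged": self.converged,
        }
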