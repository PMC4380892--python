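"""Logistic regression on individual scores: univariate screen and
backward-elimination multivariate model.

Individual scores enter as numeric 0/1/2 covariates (not dummy factors), so
each predictor carries a single per-unit odds ratio and the 0→2 contrast is
the square of that odds ratio.  Estimation is maximum likelihood by
Newton/IRLS with step-halving, which makes the log-likelihood non-decreasing
at every iteration; inference is Wald (normal) on the log-odds scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, NoModelError, NonIdentifiableError

_Z975 = float(stats.norm.ppf(0.975))

#: |log-odds| beyond which a score-scale (0..2) coefficient is treated as
#: evidence of complete or quasi-complete separation
_SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class LogisticFit:
    predictor_names: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]          # log-odds per unit score
    odds_ratios: tuple[float, ...]           # exp(coefficient)
    ci95: tuple[tuple[float, float], ...]    # per-predictor OR interval
    p_values: tuple[float, ...]              # Wald, per predictor
    standard_errors: tuple[float, ...]
    log_likelihood: float
    n: int
    converged: bool
    iterations: int

    def as_frame(self) -> pd.DataFrame:
        """Report table: predictor, OR, CI bounds, p (the Tables 3/4 shape)."""
        return pd.DataFrame({
            "predictor": self.predictor_names,
            "odds_ratio": self.odds_ratios,
            "ci95_low": [c[0] for c in self.ci95],
            "ci95_high": [c[1] for c in self.ci95],
            "p_value": self.p_values,
        })


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    predictor_names=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic fit (intercept added internally).

    Parameters
    ----------
    design : (n, p) array of numeric predictors (no intercept column).
    outcome : (n,) 0/1 array.
    tol : convergence tolerance on the max-norm of the score (gradient).
    max_iter : Newton/IRLS iteration budget.

    Raises
    ------
    NonIdentifiableError
        One outcome class absent, a zero-variance predictor, a rank-deficient
        design, or complete/quasi-complete separation (diverging coefficient).
    ConvergenceError
        Score norm still above ``tol`` after ``max_iter`` iterations.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(outcome).size == X.shape[1]:
        X = X.T
    y = np.asarray(outcome, dtype=float).ravel()
    n, p = X.shape
    names = tuple(predictor_names) if predictor_names is not None else tuple(
        f"x{i+1}" for i in range(p)
    )
    if len(names) != p:
        raise ValueError("predictor_names length does not match design width")
    if n != y.size:
        raise ValueError("design and outcome lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise NonIdentifiableError(
            f"outcome has a single class ({int(y[0])}); the model is not identifiable"
        )
    const = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0]
    if const:
        raise NonIdentifiableError(f"zero-variance predictor(s): {', '.join(const)}")

    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < p + 1:
        raise NonIdentifiableError(
            "design matrix is rank deficient (collinear predictors): "
            + ", ".join(names)
        )

    beta = np.zeros(p + 1)
    ll = _log_likelihood(Xd @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        fisher = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(fisher, grad)
        except np.linalg.LinAlgError as e:
            raise NonIdentifiableError(f"singular information matrix: {e}") from e
        # step-halving guarantees the log-likelihood never decreases
        scale = 1.0
        for _ in range(30):
            ll_new = _log_likelihood(Xd @ (beta + scale * step), y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        assert ll_new >= ll - 1e-12, "log-likelihood decreased during IRLS"
        ll = ll_new
        if np.max(np.abs(beta[1:])) > _SEPARATION_BOUND:
            worst = names[int(np.argmax(np.abs(beta[1:])))]
            raise NonIdentifiableError(
                f"apparent complete or quasi-complete separation on predictor "
                f"{worst!r} (|log-odds| > {_SEPARATION_BOUND:g})"
            )
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(score max-norm {np.max(np.abs(grad)):.3e}, tol {tol:g})"
        )

    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((Xd * w[:, None]).T @ Xd)
    se = np.sqrt(np.diag(cov))[1:]
    coef = beta[1:]
    or_ = np.exp(coef)
    ci = tuple(
        (float(np.exp(c - _Z975 * s)), float(np.exp(c + _Z975 * s)))
        for c, s in zip(coef, se)
    )
    pvals = tuple(float(2.0 * stats.norm.sf(abs(c / s))) for c, s in zip(coef, se))
    return LogisticFit(
        predictor_names=names,
        intercept=float(beta[0]),
        coefficients=tuple(float(c) for c in coef),
        odds_ratios=tuple(float(o) for o in or_),
        ci95=ci,
        p_values=pvals,
        standard_errors=tuple(float(s) for s in se),
        log_likelihood=ll,
        n=n,
        converged=converged,
        iterations=it,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Per-parameter univariate fits; failures are reported, not fatal."""

    fits: dict  # predictor name -> LogisticFit
    failures: dict  # predictor name -> error message

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [k for k, f in self.fits.items() if f.p_values[0] < alpha]

    def as_frame(self) -> pd.DataFrame:
        frames = [f.as_frame() for f in self.fits.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["predictor", "odds_ratio", "ci95_low", "ci95_high", "p_value"]
        )


def univariate_screen(scored: pd.DataFrame, predictors, outcome_col: str = "blastocyst") -> ScreenResult:
    """One single-predictor fit per individual score, in input order.

    Each fit uses the labeled records non-missing for that predictor
    (complete cases per parameter).  Errors in one fit are collected in
    ``failures`` and do not abort the screen.
    """
    fits: dict = {}
    failures: dict = {}
    for name in predictors:
        sub = scored[[name, outcome_col]].dropna()
        try:
            fits[name] = fit_logistic(
                sub[name].to_numpy()[:, None], sub[outcome_col].to_numpy(),
                predictor_names=(name,),
            )
        except Exception as e:  # noqa: BLE001 - reported per spec, not fatal
            failures[name] = f"{type(e).__name__}: {e}"
    return ScreenResult(fits, failures)


def multivariate_select(
    scored: pd.DataFrame,
    candidates,
    alpha: float = 0.05,
    outcome_col: str = "blastocyst",
):
    """Backward elimination at significance level ``alpha``.

    Fits all candidates jointly on their complete cases, repeatedly drops the
    predictor with the largest Wald p >= alpha and refits, until every
    retained predictor is significant.  Returns ``(fit, dropped)`` where
    ``dropped`` lists eliminated predictors in elimination order.

    Raises :class:`NoModelError` when elimination empties the candidate set.
    """
    retained = list(candidates)
    if not retained:
        raise NoModelError("no candidate predictors supplied")
    sub = scored[retained + [outcome_col]].dropna()
    dropped: list[str] = []
    while retained:
        fit = fit_logistic(
            sub[retained].to_numpy(), sub[outcome_col].to_numpy(),
            predictor_names=tuple(retained),
        )
        worst = int(np.argmax(fit.p_values))
        if fit.p_values[worst] < alpha:
            return fit, dropped
        dropped.append(retained.pop(worst))
    raise NoModelError(
        f"backward elimination removed every predictor (alpha={alpha}); "
        f"dropped in order: {', '.join(dropped)}"
    )
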