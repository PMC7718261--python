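"""Survival and categorical statistics: Kaplan-Meier, log-rank, Cox PH,
Fisher's exact test and Welch t-tests.

The survival estimators are implemented directly from their defining
formulas (product-limit estimator; Mantel-Cox statistic; Cox partial
likelihood maximised by Newton's method with Efron or Breslow tie handling)
so that every downstream analysis is self-contained and exactly replayable.
At equal times, events are taken to precede censorings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KmCurve",
    "CoxResult",
    "km_fit",
    "km_median",
    "format_median",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "fisher_exact_2x2",
    "welch_t",
]


@dataclass
class KmCurve:
    times: np.ndarray        # distinct event/censoring times, increasing
    survival: np.ndarray     # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    median: float | None     # smallest t with S(t) <= 0.5; None if never reached

    @property
    def max_time(self) -> float:
        return float(self.times[-1]) if self.times.size else float("nan")


@dataclass
class CoxResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pvalues: np.ndarray
    log_partial_likelihood: float
    ties: str
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.pvalues,
            },
            index=self.names,
        )


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("times and events length mismatch")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_fit(times, events) -> KmCurve:
    """Product-limit estimator S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n = t.size
    at_risk = np.empty(uniq.size)
    d = np.empty(uniq.size, dtype=int)
    c = np.empty(uniq.size, dtype=int)
    surv = np.empty(uniq.size)
    s = 1.0
    for j, tj in enumerate(uniq):
        here = t == tj
        at_risk[j] = n - np.searchsorted(t, tj, side="left")
        d[j] = int(e[here].sum())
        c[j] = int(here.sum() - d[j])
        if d[j] > 0:
            s *= 1.0 - d[j] / at_risk[j]
        surv[j] = s
    median = None
    crossed = np.nonzero(surv <= 0.5)[0]
    if crossed.size:
        median = float(uniq[crossed[0]])
    return KmCurve(uniq, surv, at_risk, d, c, median)


def km_median(curve: KmCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None when never reached."""
    return curve.median


def format_median(curve: KmCurve) -> str:
    """Median for reporting; curves that never cross 0.5 print as '> max-time'."""
    if curve.median is None:
        return f"> {curve.max_time:g}"
    return f"{curve.median:g}"


def logrank_test(groups: dict | list) -> tuple[float, float]:
    """Mantel-Cox log-rank test over >= 2 groups.

    ``groups`` maps group label -> (times, events) (or is a list of such
    pairs). Returns (chi2, p) with df = n_groups - 1.
    """
    if isinstance(groups, dict):
        items = list(groups.values())
    else:
        items = list(groups)
    if len(items) < 2:
        raise ValueError("log-rank test needs at least two groups")
    parsed = [_check_surv(t, e) for t, e in items]
    g = np.concatenate([np.full(t.size, i) for i, (t, _) in enumerate(parsed)])
    t = np.concatenate([t for t, _ in parsed])
    e = np.concatenate([e for _, e in parsed])
    if e.sum() == 0:
        raise ValueError("log-rank test needs at least one event")

    k = len(items)
    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for tj in event_times:
        at_risk_mask = t >= tj
        nj = at_risk_mask.sum()
        dj = int(((t == tj) & (e == 1)).sum())
        n_gj = np.array([(at_risk_mask & (g == i)).sum() for i in range(k)], dtype=float)
        d_gj = np.array(
            [int(((t == tj) & (e == 1) & (g == i)).sum()) for i in range(k)], dtype=float
        )
        observed += d_gj
        expected += dj * n_gj / nj
        if nj > 1:
            frac = n_gj / nj
            hyper = dj * (nj - dj) / (nj - 1)
            var += hyper * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[:-1]
    v = var[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


def _cox_loglik(beta, t, e, X, ties):
    """Log partial likelihood with gradient and Hessian (Efron or Breslow)."""
    order = np.argsort(-t, kind="stable")  # decreasing time for running sums
    t, e, X = t[order], e[order], X[order]
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        tj = t[i]
        j = i
        while j < n and t[j] == tj:
            s0 += w[j]
            s1 += w[j] * X[j]
            s2 += w[j] * np.outer(X[j], X[j])
            j += 1
        idx = [m for m in range(i, j) if e[m] == 1]
        d = len(idx)
        if d:
            xd = X[idx]
            wd = w[idx]
            ll += eta[idx].sum()
            if ties == "breslow" or d == 1:
                ll -= d * np.log(s0)
                mu = s1 / s0
                grad += xd.sum(axis=0) - d * mu
                hess -= d * (s2 / s0 - np.outer(mu, mu))
            else:  # efron
                d0 = wd.sum()
                d1 = (wd[:, None] * xd).sum(axis=0)
                d2 = (wd[:, None, None] * np.einsum("ij,ik->ijk", xd, xd)).sum(axis=0)
                grad += xd.sum(axis=0)
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll -= np.log(a0)
                    mu = a1 / a0
                    grad -= mu
                    hess -= a2 / a0 - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def cox_fit(
    times,
    events,
    covariates: pd.DataFrame | np.ndarray,
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional hazards fit by Newton iteration.

    Converges to gradient max-norm < 1e-8 (at most 100 iterations, with step
    halving); raises on non-convergence or monotone likelihood (a coefficient
    running to infinity), naming the covariate. Wald CIs: exp(beta +- 1.96 se).
    """
    t, e = _check_surv(times, events)
    if e.sum() == 0:
        raise ValueError("Cox fit needs at least one event")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != t.size:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.ndim == 1:
        X = X[:, None]
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        raise ValueError(f"constant covariate(s): {', '.join(const)}")
    # centering improves conditioning; partial likelihood is location-invariant
    Xc = X - X.mean(axis=0)

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_loglik(beta, t, e, Xc, ties)
    for _ in range(100):
        if np.max(np.abs(grad)) < 1e-8:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Cox fit") from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_loglik(new_beta, t, e, Xc, ties)
        halvings = 0
        # tolerate float-epsilon decreases near the optimum
        while new_ll < ll - 1e-9 * (1 + abs(ll)) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_loglik(new_beta, t, e, Xc, ties)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        big = np.abs(beta) > 20
        if big.any():
            raise RuntimeError(
                "monotone likelihood (coefficient diverging) for covariate(s): "
                + ", ".join(np.array(names)[big])
            )
    else:
        raise RuntimeError("Cox fit did not converge in 100 Newton iterations")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return CoxResult(
        names=names,
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci_lower=np.exp(beta - 1.959963984540054 * se),
        ci_upper=np.exp(beta + 1.959963984540054 * se),
        pvalues=p,
        log_partial_likelihood=float(ll),
        ties=ties,
        n=t.size,
        n_events=int(e.sum()),
    )


def cox_score_test(times, events, covariate, ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test of beta = 0 for a single covariate: U^2 / I.

    For a binary covariate with untied event times this equals the two-group
    log-rank chi-square exactly.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)[:, None]
    x = x - x.mean(axis=0)
    _, grad, hess = _cox_loglik(np.zeros(1), t, e, x, ties)
    chi2 = float(grad[0] ** 2 / -hess[0, 0])
    return chi2, float(stats.chi2.sf(chi2, 1))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for a non-negative integer 2x2 table.

    A zero margin makes every table with these margins equally (un)informative;
    p = 1 is returned with a warning.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any() or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
            raise ValueError("table must contain non-negative integers")
        tab = tab.astype(int)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    sided = {"two-sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    return float(stats.fisher_exact(tab, alternative=sided)[1])


def welch_t(a, b, tails: int = 2, alternative: str = "greater") -> tuple[float, float, float]:
    """Welch two-sample t-test with Satterthwaite df.

    ``tails = 2`` gives the two-sided p; ``tails = 1`` the one-sided p in the
    direction of ``alternative`` ('greater' tests mean(a) > mean(b)).
    Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 values per arm")
    alt = "two-sided" if tails == 2 else alternative
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alt)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    num = (va / a.size + vb / b.size) ** 2
    den = (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    df = num / den if den > 0 else float(a.size + b.size - 2)
    return float(res.statistic), float(df), float(res.pvalue)
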