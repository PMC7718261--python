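"""Progression gene signature (PGS) assembly by backward stepwise logistic regression.

Starting from the survival-gene pool, a logistic model of the binary
progression indicator on per-gene z-scored expression is pruned one covariate
at a time: the gene with the largest Wald p-value is removed while that
p-value is at or above the threshold (default 0.25, deliberately lenient so
weakly interacting variables stay in), refitting after every removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import ExpressionMatrix

__all__ = ["Signature", "backward_stepwise"]


@dataclass
class Signature:
    label: str
    genes: list[str]
    stepwise_p: dict[str, float]
    model_bic: float
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)
    p_threshold: float = 0.25

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "genes": list(self.genes),
            "stepwise_p": dict(self.stepwise_p),
            "model_bic": self.model_bic,
            "elimination_trace": [list(t) for t in self.elimination_trace],
            "p_threshold": self.p_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            label=d["label"],
            genes=list(d["genes"]),
            stepwise_p={k: float(v) for k, v in d["stepwise_p"].items()},
            model_bic=float(d["model_bic"]),
            elimination_trace=[(g, float(p)) for g, p in d["elimination_trace"]],
            p_threshold=float(d.get("p_threshold", 0.25)),
        )


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1e-4):
    """Newton fit of logistic regression with an L2 penalty on slopes.

    Stabilised fallback for (quasi-)separated data. Returns (beta, llf, pvalues
    for slope terms)."""
    n, k = X.shape
    Xc = np.column_stack([np.ones(n), X])
    pen = np.zeros(k + 1)
    pen[1:] = lam
    beta = np.zeros(k + 1)
    for _ in range(200):
        eta = np.clip(Xc @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = Xc.T @ (y - p) - pen * beta
        hess = (Xc * w[:, None]).T @ Xc + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(Xc @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    llf = float(np.sum(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)))
    w = p * (1 - p)
    hess = (Xc * w[:, None]).T @ Xc + np.diag(pen)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    return beta, llf, pvals[1:]


def _fit_wald(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Fit logistic regression; return (llf, per-slope Wald p). Falls back to a
    ridge-stabilised fit (lambda = 1e-4) under separation or non-convergence."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
            res = model.fit(disp=0, maxiter=200)
        pvals = np.asarray(res.pvalues)[1:]
        if (
            res.mle_retvals.get("converged", True)
            and np.all(np.isfinite(pvals))
            and np.all(np.isfinite(np.asarray(res.bse)))
            and np.max(np.abs(np.asarray(res.params))) < 50
        ):
            return float(res.llf), pvals
    except Exception:
        pass
    warnings.warn(
        "logistic fit unstable (separation?); using ridge-stabilised fallback",
        stacklevel=3,
    )
    _, llf, pvals = _ridge_logit(X, y)
    return llf, pvals


def _intercept_llf(y: np.ndarray) -> float:
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = y.size - n1
    return float(n1 * np.log(pbar) + n0 * np.log(1 - pbar))


def backward_stepwise(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    start_genes: list[str],
    p_threshold: float = 0.25,
    max_iter: int | None = None,
    label: str = "PGS",
) -> Signature:
    """Backward elimination on Wald p-values.

    ``matrix`` must be z-scored with samples matching ``labels`` (a 0/1 series
    indexed by sample id; missing labels are dropped before fitting). Removal
    ties break toward the lexicographically first gene. Returns the retained
    ordered gene list, final per-gene p-values, the final model's BIC
    (-2 logL + k ln n, k including the intercept) and the elimination trace.
    """
    if matrix.scale != "zscore":
        raise ValueError("backward_stepwise expects a z-scored matrix")
    start_genes = list(start_genes)
    missing = [g for g in start_genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"start genes absent from matrix: {', '.join(missing)}")

    labels = labels.dropna()
    common = [s for s in matrix.sample_ids if s in labels.index]
    y = labels.loc[common].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    n = y.size

    genes = sorted(start_genes)
    X_all = matrix.values.loc[genes, common].to_numpy().T  # samples x genes
    trace: list[tuple[str, float]] = []
    max_iter = max_iter if max_iter is not None else len(genes) + 1

    current = list(range(len(genes)))
    llf = _intercept_llf(y)
    pvals = np.array([])
    for _ in range(max_iter):
        if not current:
            break
        llf, pvals = _fit_wald(X_all[:, current], y)
        worst = float(np.max(pvals))
        if worst < p_threshold:
            break
        # tie-break: largest p, then lexicographically first gene symbol
        tied = [i for i, p in zip(current, pvals) if p == worst]
        drop = min(tied, key=lambda i: genes[i])
        trace.append((genes[drop], worst))
        current.remove(drop)
    if not current:
        llf = _intercept_llf(y)
        pvals = np.array([])

    k_params = len(current) + 1
    bic = -2.0 * llf + k_params * np.log(n)
    retained = [genes[i] for i in current]
    stepwise_p = {genes[i]: float(p) for i, p in zip(current, pvals)}
    return Signature(
        label=label,
        genes=retained,
        stepwise_p=stepwise_p,
        model_bic=float(bic),
        elimination_trace=trace,
        p_threshold=p_threshold,
    )
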