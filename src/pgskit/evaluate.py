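"""Evaluation battery: ROC/AUC, paired ROC comparison (DeLong), baseline
biomarkers, and the risk-group report (confusion matrix, survival contrasts,
treatment benefit, hypoxia).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .cohort import ClinicalTable, ExpressionMatrix, zscore_by_gene
from .survstats import fisher_exact_2x2, km_fit, format_median, logrank_test, welch_t

__all__ = [
    "RocCurve",
    "roc_auc",
    "compare_rocs",
    "baseline_biomarker_scores",
    "risk_group_report",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    auc: float
    n_pos: int
    n_neg: int


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected concordance probability (midranks)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve with AUC computed as the Mann-Whitney concordance statistic
    (identical to the trapezoidal area under the midrank convention)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        fpr=fpr,
        auc=_mann_whitney_auc(s, y),
        n_pos=int(y.sum()),
        n_neg=int(y.size - y.sum()),
    )


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-sample placement values (V10, V01) and AUC."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = x.size, y.size
    v10 = np.empty(m)
    for i, xi in enumerate(x):
        v10[i] = (np.sum(y < xi) + 0.5 * np.sum(y == xi)) / n
    v01 = np.empty(n)
    for j, yj in enumerate(y):
        v01[j] = (np.sum(x > yj) + 0.5 * np.sum(x == yj)) / m
    return v10, v01, float(v10.mean())


def compare_rocs(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong paired test for two correlated ROC curves on the same samples.

    Returns (z, two-sided p). Degenerate variance yields p = 1 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if a.size != b.size or a.size != y.size:
        raise ValueError("scores and labels must have equal length")
    va10, va01, auc_a = _delong_components(a, y)
    vb10, vb01, auc_b = _delong_components(b, y)
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]))  # 2x2
    s01 = np.cov(np.vstack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        if delta == 0:
            return 0.0, 1.0
        warnings.warn("degenerate DeLong variance; p = 1", stacklevel=2)
        return 0.0, 1.0
    z = delta / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def baseline_biomarker_scores(
    matrix: ExpressionMatrix,
    biomarker_genes: list[str],
    labels: pd.Series | None = None,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-gene baseline scores (z-scored expression) plus a combined
    baseline: the out-of-fold probability of a logistic model on all baseline
    genes together (requires ``labels``). Missing genes are skipped with a
    warning."""
    present = [g for g in biomarker_genes if g in matrix.values.index]
    missing = [g for g in biomarker_genes if g not in matrix.values.index]
    if missing:
        warnings.warn("baseline gene(s) missing, skipped: " + ", ".join(missing), stacklevel=2)
    if not present:
        raise ValueError("no baseline biomarker genes present in matrix")
    sub = matrix.subset_genes(present)
    zmat, _ = zscore_by_gene(sub)
    out = zmat.values.T.copy()  # samples x genes

    if labels is not None:
        labels = labels.dropna()
        common = [s for s in out.index if s in labels.index]
        X = out.loc[common].to_numpy()
        y = labels.loc[common].to_numpy(dtype=float)
        combined = pd.Series(np.nan, index=out.index, name="combined")
        if len(np.unique(y)) == 2:
            oof = np.empty(y.size)
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
            for tr, te in skf.split(X, y):
                lr = LogisticRegression(max_iter=1000)
                lr.fit(X[tr], y[tr])
                oof[te] = lr.predict_proba(X[te])[:, 1]
            combined.loc[common] = oof
        out["combined"] = combined
    return out


def _welch_or_flag(a, b, tails, alternative="greater"):
    if len(a) < 2 or len(b) < 2:
        return {"skipped": True, "reason": f"arm sizes {len(a)}/{len(b)} too small"}
    t, df, p = welch_t(a, b, tails=tails, alternative=alternative)
    return {
        "skipped": False, "t": t, "df": df, "p": p,
        "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
        "n_a": len(a), "n_b": len(b),
    }


def risk_group_report(scores: pd.DataFrame, clinical: ClinicalTable) -> dict:
    """Assemble the full risk-group assessment.

    ``scores`` is the frame from :func:`pgskit.risk.score_samples`. The report
    contains: the group x progression confusion matrix with Fisher's exact p;
    per-group KM curves with medians and the log-rank p; one-tailed Welch
    t-tests of treated-vs-untreated DFS within each risk group; the group x
    treatment-response Fisher's exact test; and a two-tailed Welch t-test of
    hypoxia scores between groups. Analyses whose arms are empty are skipped
    and flagged, never fabricated. Pure: identical inputs give an identical
    report.
    """
    common = [s for s in scores.index if s in clinical.data.index]
    sc = scores.loc[common]
    cl = clinical.data.loc[common]
    report: dict = {"n_samples": len(common), "flags": []}

    high = sc["group"] == "high"
    low = sc["group"] == "low"
    if not high.any() or not low.any():
        report["flags"].append("one risk group empty; group contrasts skipped")

    # ---- confusion matrix vs progression ----------------------------------
    if "progressed" in cl and cl["progressed"].notna().any() and high.any() and low.any():
        mask = cl["progressed"].notna()
        tab = np.array(
            [
                [int((high & mask & (cl["progressed"] == 1)).sum()),
                 int((high & mask & (cl["progressed"] == 0)).sum())],
                [int((low & mask & (cl["progressed"] == 1)).sum()),
                 int((low & mask & (cl["progressed"] == 0)).sum())],
            ]
        )
        report["confusion_matrix"] = tab.tolist()
        report["confusion_fisher_p"] = fisher_exact_2x2(tab)
    else:
        report["flags"].append("progression confusion matrix skipped")

    # ---- KM / log-rank by risk group --------------------------------------
    has_dfs = cl["dfs_months"].notna() if "dfs_months" in cl else pd.Series(False, index=cl.index)
    if high.any() and low.any() and has_dfs.any():
        km = {}
        groups = {}
        for name, mask in (("high", high), ("low", low)):
            sel = mask & has_dfs
            if sel.any():
                curve = km_fit(cl.loc[sel, "dfs_months"], cl.loc[sel, "dfs_event"].fillna(0))
                km[name] = {
                    "median": curve.median,
                    "median_label": format_median(curve),
                    "n": int(sel.sum()),
                }
                groups[name] = (
                    cl.loc[sel, "dfs_months"].to_numpy(),
                    cl.loc[sel, "dfs_event"].fillna(0).to_numpy(dtype=int),
                )
        report["km_by_group"] = km
        if len(groups) == 2:
            try:
                chi2, p = logrank_test(groups)
                report["logrank"] = {"chi2": chi2, "p": p}
            except ValueError as exc:
                report["flags"].append(f"log-rank skipped: {exc}")
    else:
        report["flags"].append("survival contrast skipped")

    # ---- treatment benefit (one-tailed Welch, treated > untreated DFS) ----
    if "treated" in cl and cl["treated"].notna().any():
        bench = {}
        for name, mask in (("high", high), ("low", low)):
            sel = mask & has_dfs & cl["treated"].notna()
            a = cl.loc[sel & (cl["treated"] == 1), "dfs_months"].to_numpy()
            b = cl.loc[sel & (cl["treated"] == 0), "dfs_months"].to_numpy()
            res = _welch_or_flag(a, b, tails=1, alternative="greater")
            if res["skipped"]:
                report["flags"].append(f"treatment benefit ({name} risk) skipped: {res['reason']}")
            bench[name] = res
        report["treatment_benefit"] = bench
    else:
        report["flags"].append("treatment benefit skipped: no treatment data")

    # ---- risk group x treatment response ----------------------------------
    if "response" in cl and cl["response"].notna().any() and high.any() and low.any():
        mask = cl["response"].notna()
        tab = np.array(
            [
                [int((high & mask & (cl["response"] == "resistant")).sum()),
                 int((high & mask & (cl["response"] == "responder")).sum())],
                [int((low & mask & (cl["response"] == "resistant")).sum()),
                 int((low & mask & (cl["response"] == "responder")).sum())],
            ]
        )
        report["response_table"] = tab.tolist()
        report["response_fisher_p"] = fisher_exact_2x2(tab)
    else:
        report["flags"].append("treatment response contrast skipped")

    # ---- hypoxia (two-tailed Welch) ---------------------------------------
    if "hypoxia_score" in cl and cl["hypoxia_score"].notna().any():
        a = cl.loc[high & cl["hypoxia_score"].notna(), "hypoxia_score"].to_numpy()
        b = cl.loc[low & cl["hypoxia_score"].notna(), "hypoxia_score"].to_numpy()
        res = _welch_or_flag(a, b, tails=2)
        if res["skipped"]:
            report["flags"].append(f"hypoxia contrast skipped: {res['reason']}")
        report["hypoxia"] = res
    else:
        report["flags"].append("hypoxia contrast skipped: no hypoxia scores")

    return report
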