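"""Survival-gene calling from shRNA depletion screens.

A gene is a "survival gene" when knocking it down depletes cells: its average
log2 fold change of shRNA abundance is negative. Significance is assessed per
shRNA with one-tailed one-sample t-tests of mean FC < 0 across cell lines,
combined per gene with Fisher's method (-2 sum ln p ~ chi2 with 2k df), and
adjusted across the candidate pool with Benjamini-Hochberg FDR. Following the
discovery design, the selection rule is the mean-FC < 0 cutoff itself; the
combined/adjusted p-values are confirmatory diagnostics (a strict mode that
additionally requires q below a threshold is available).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ShrnaScreen

__all__ = [
    "GeneEssentiality",
    "gene_mean_fc",
    "shrna_depletion_test",
    "fisher_combine",
    "bh_fdr",
    "call_survival_genes",
]


@dataclass
class GeneEssentiality:
    gene: str
    measured: bool
    mean_fc: float  # nan when not measured
    shrna_pvalues: tuple[float, ...]
    fisher_chi2: float
    fisher_df: int
    combined_p: float
    fdr_q: float
    is_survival_gene: bool


def gene_mean_fc(screen: ShrnaScreen, gene: str) -> float:
    """Two-stage average: mean over a gene's shRNAs within each cell line,
    then mean over cell lines."""
    sub = screen.data[screen.data["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not present in screen")
    per_line = sub.groupby("cell_line")["log2_fc"].mean()
    return float(per_line.mean())


def shrna_depletion_test(fcs_across_cell_lines: Sequence[float]) -> float | None:
    """One-tailed one-sample t-test of H0: mean FC = 0 vs H1: mean FC < 0.

    Returns None (shRNA skipped, with a warning) when fewer than two finite
    values are available or the values have zero variance.
    """
    vals = np.asarray(fcs_across_cell_lines, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or np.ptp(vals) == 0:
        warnings.warn(
            "shRNA skipped: need >= 2 finite measurements with nonzero variance",
            stacklevel=2,
        )
        return None
    res = stats.ttest_1samp(vals, 0.0, alternative="less")
    return float(res.pvalue)


def fisher_combine(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test: chi2 = -2 sum ln p on 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_survival_genes(
    screen: ShrnaScreen,
    candidate_genes: Sequence[str],
    strict_fdr: float | None = None,
) -> pd.DataFrame:
    """Score every candidate gene against the screen.

    Genes absent from the screen are marked ``measured = False`` and excluded
    from the survival-gene set (never imputed to 0). shRNAs measured in fewer
    than two cell lines contribute to the mean FC but not to the p-value
    combination. Returns one row per candidate with columns gene, measured,
    mean_fc, n_shrnas, fisher_chi2, fisher_df, combined_p, fdr_q,
    is_survival_gene.
    """
    candidate_genes = list(candidate_genes)
    if not candidate_genes:
        raise ValueError("candidate gene list is empty")

    by_gene = dict(tuple(screen.data.groupby("gene")))
    rows: list[dict] = []
    for gene in candidate_genes:
        sub = by_gene.get(gene)
        if sub is None or sub.empty:
            rows.append(
                dict(gene=gene, measured=False, mean_fc=np.nan, n_shrnas=0,
                     fisher_chi2=np.nan, fisher_df=0, combined_p=np.nan,
                     fdr_q=np.nan, is_survival_gene=False)
            )
            continue
        per_line = sub.groupby("cell_line")["log2_fc"].mean()
        mean_fc = float(per_line.mean())
        pvals = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _, shr in sub.groupby("shrna_id"):
                p = shrna_depletion_test(shr["log2_fc"].to_numpy())
                if p is not None:
                    pvals.append(p)
        if pvals:
            chi2, df, comb = fisher_combine(pvals)
        else:
            chi2, df, comb = np.nan, 0, np.nan
        rows.append(
            dict(gene=gene, measured=True, mean_fc=mean_fc, n_shrnas=len(pvals),
                 fisher_chi2=chi2, fisher_df=df, combined_p=comb, fdr_q=np.nan,
                 is_survival_gene=mean_fc < 0)
        )

    table = pd.DataFrame(rows).set_index("gene")
    has_p = table["combined_p"].notna()
    if has_p.any():
        table.loc[has_p, "fdr_q"] = bh_fdr(table.loc[has_p, "combined_p"].to_numpy())
    if strict_fdr is not None:
        table["is_survival_gene"] &= table["fdr_q"] < strict_fdr
    n_missing = int((~table["measured"]).sum())
    if n_missing:
        print(
            f"call_survival_genes: {n_missing} candidate gene(s) not in screen, excluded",
            file=sys.stderr,
        )
    return table
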