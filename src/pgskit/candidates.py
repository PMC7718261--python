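"""Primary candidate pool selection: ubiquitously expressed genes.

"Ubiquitous" is operationalised as a robust per-gene minimum: the 5th
percentile of (log-scale) expression across samples, which is high only when
the gene is highly expressed in essentially every sample. An initial
99th-percentile cutoff over that statistic yields the candidate pool; the
pool size can then be refined by minimising the BIC of the downstream
stepwise signature model over a grid of candidate sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, ExpressionMatrix, ShrnaScreen, zscore_by_gene
from .essentiality import call_survival_genes
from .signature import Signature, backward_stepwise

__all__ = [
    "CandidatePool",
    "ubiquity_rank",
    "select_top_percentile",
    "refine_pool_by_bic",
]

DEFAULT_CANDIDATE_SIZES = (200, 150, 100, 50)


@dataclass
class CandidatePool:
    genes: list[str]  # descending ubiquity, ties lexicographic
    ubiquity_statistic: pd.Series
    bic_trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def pool_size(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "ubiquity_statistic": {g: float(v) for g, v in self.ubiquity_statistic.items()},
            "bic_trace": [list(t) for t in self.bic_trace],
        }


def ubiquity_rank(matrix: ExpressionMatrix, statistic: str = "p5") -> pd.Series:
    """Per-gene ubiquity statistic on log-scale expression.

    ``statistic`` is ``"p5"`` (5th percentile across samples, the default) or
    ``"mean"``. Raw input is log2(x+1)-transformed first. The returned series
    is sorted descending with lexicographic tie-break on the gene symbol.
    """
    if matrix.shape[1] < 2:
        raise ValueError("ubiquity_rank needs at least 2 samples")
    logm = matrix.to_log()
    if statistic == "p5":
        stat = logm.values.quantile(0.05, axis=1)
    elif statistic == "mean":
        stat = logm.values.mean(axis=1)
    else:
        raise ValueError(f"unknown ubiquity statistic {statistic!r}")
    frame = stat.rename("ubiquity").rename_axis("gene").reset_index()
    frame = frame.sort_values(["ubiquity", "gene"], ascending=[False, True])
    return frame.set_index("gene")["ubiquity"]


def select_top_percentile(statistic: pd.Series, percentile: float) -> list[str]:
    """Genes at or above the given percentile of the ubiquity statistic.

    Returns ceil(n * (1 - percentile/100)) genes after deterministic tie
    handling (statistic descending, then gene symbol ascending).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    n = len(statistic)
    # (100 - percentile) first: 1 - 99/100 is not representable and would
    # push the ceiling up a gene (e.g. 21 instead of 20 for n = 2000)
    m = math.ceil(n * (100.0 - percentile) / 100.0 - 1e-9)
    m = max(m, 1)
    frame = statistic.rename("u").rename_axis("gene").reset_index()
    frame = frame.sort_values(["u", "gene"], ascending=[False, True])
    return frame["gene"].head(m).tolist()


def refine_pool_by_bic(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    screen: ShrnaScreen,
    candidate_sizes: tuple[int, ...] = DEFAULT_CANDIDATE_SIZES,
    p_threshold: float = 0.25,
    statistic: str = "p5",
) -> CandidatePool:
    """Choose the pool size whose downstream stepwise signature minimises BIC.

    For each size the full downstream path runs: essentiality filtering of the
    top-`size` ubiquitous genes, then backward stepwise assembly on the
    progression labels; the BIC of the final stepwise logistic model is
    recorded. Ties in BIC go to the smaller pool.
    """
    if not candidate_sizes:
        raise ValueError("candidate_sizes must be non-empty")
    stat = ubiquity_rank(matrix, statistic=statistic)
    n_genes = len(stat)
    for size in candidate_sizes:
        if size > n_genes:
            raise ValueError(f"candidate size {size} exceeds gene universe ({n_genes})")

    labels = clinical.data["progressed"]
    zmat, _ = zscore_by_gene(matrix)

    trace: list[tuple[int, float]] = []
    best: tuple[float, int] | None = None
    for size in sorted(set(candidate_sizes)):
        pool = stat.index[:size].tolist()
        ess = call_survival_genes(screen, pool)
        survival = ess.index[ess["is_survival_gene"]].tolist()
        if survival:
            sig: Signature = backward_stepwise(
                zmat, labels, survival, p_threshold=p_threshold
            )
            bic = sig.model_bic
        else:
            bic = math.inf
        trace.append((size, float(bic)))
        if best is None or bic < best[0] or (bic == best[0] and size < best[1]):
            best = (bic, size)

    best_size = best[1]
    genes = stat.index[:best_size].tolist()
    return CandidatePool(genes=genes, ubiquity_statistic=stat, bic_trace=trace)
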