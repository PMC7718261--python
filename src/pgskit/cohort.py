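"""Tabular containers and I/O for expression cohorts, clinical outcomes and shRNA screens.

All on-disk formats are plain UTF-8 text: expression as a genes x samples TSV
(first column gene symbols, header row sample ids), clinical as a TSV keyed by
``sample_id``, screens as CSV with one row per (shRNA, cell line) measurement.
Gene symbols are matched case-sensitively after trimming whitespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "ShrnaScreen",
    "CohortParseError",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_screen",
    "write_screen",
    "zscore_by_gene",
]

#: Columns read_clinical understands; anything else is kept as an opaque covariate.
CLINICAL_COLUMNS = (
    "progressed",
    "dfs_months",
    "dfs_event",
    "os_months",
    "os_event",
    "age",
    "gender",
    "stage",
    "smoking",
    "treated",
    "response",
    "hypoxia_score",
)


class CohortParseError(ValueError):
    """A file violated the artifact's tabular contracts."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit normalization state.

    ``scale`` is one of ``raw`` (non-negative RSEM-like values), ``log``
    (already log2-ish, e.g. microarray intensities or delta-Ct values) or
    ``zscore`` (per-gene standardized).
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str = "raw"
    constant_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log", "zscore"):
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise CohortParseError(f"duplicate gene ids: {', '.join(map(str, dups))}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise CohortParseError(f"duplicate sample ids: {', '.join(map(str, dups))}")
        self.values.index.name = "gene"
        self.values.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {', '.join(missing)}")
        return ExpressionMatrix(self.values.loc[genes].copy(), scale=self.scale)

    def to_log(self) -> "ExpressionMatrix":
        """Return the matrix on log scale (raw values become log2(x+1))."""
        if self.scale == "raw":
            return ExpressionMatrix(np.log2(self.values + 1.0), scale="log")
        return self


@dataclass
class ClinicalTable:
    """Per-sample outcomes and covariates, indexed by unique sample id.

    Missing values are NaN, never 0; event flags are 0/1; times non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise CohortParseError(f"duplicate sample ids: {', '.join(map(str, dups))}")
        for col in ("dfs_event", "os_event", "progressed", "treated"):
            if col in self.data:
                vals = self.data[col].dropna()
                if not vals.isin([0, 1]).all():
                    raise CohortParseError(f"column {col!r} must be 0/1")
        for col in ("dfs_months", "os_months"):
            if col in self.data:
                vals = self.data[col].dropna()
                if (vals < 0).any():
                    raise CohortParseError(f"column {col!r} has negative times")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class ShrnaScreen:
    """shRNA-level log2 fold changes of depletion across cell lines."""

    data: pd.DataFrame  # columns: shrna_id, gene, cell_line, log2_fc

    REQUIRED = ("shrna_id", "gene", "cell_line", "log2_fc")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise CohortParseError(f"screen missing columns: {', '.join(missing)}")
        genes_per_shrna = self.data.groupby("shrna_id")["gene"].nunique()
        bad = genes_per_shrna[genes_per_shrna > 1]
        if len(bad):
            raise CohortParseError(
                "shRNA mapped to multiple genes: " + ", ".join(map(str, bad.index))
            )
        if self.data.duplicated(["shrna_id", "cell_line"]).any():
            dup = self.data[self.data.duplicated(["shrna_id", "cell_line"])]
            pairs = {(r.shrna_id, r.cell_line) for r in dup.itertuples()}
            raise CohortParseError(f"duplicate (shrna_id, cell_line) pairs: {sorted(pairs)}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, scale: str = "raw") -> ExpressionMatrix:
    """Read a genes x samples TSV. Rejects duplicate ids, ragged rows and
    non-numeric cells, naming the offending gene/line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise CohortParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise CohortParseError(
            f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
        )
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV keyed by ``sample_id``; empty cells become missing."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise CohortParseError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    df.index = df.index.str.strip()
    for col in ("progressed", "dfs_months", "dfs_event", "os_months", "os_event",
                "age", "treated", "hypoxia_score"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_screen(path: str | Path) -> ShrnaScreen:
    df = pd.read_csv(path, dtype={"shrna_id": str, "gene": str, "cell_line": str})
    for col in ("gene", "shrna_id", "cell_line"):
        if col in df.columns:
            df[col] = df[col].str.strip()
    if "log2_fc" in df.columns:
        df["log2_fc"] = pd.to_numeric(df["log2_fc"], errors="raise")
    return ShrnaScreen(df)


def write_screen(screen: ShrnaScreen, path: str | Path) -> None:
    screen.data.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def zscore_by_gene(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Per-gene standardization (sample sd, n-1 denominator).

    Raw input is first log2(x+1)-transformed. Genes with zero variance map to
    all-zero rows and are flagged in ``constant_genes``. Returns the z-scored
    matrix and a (mean, sd) frame sufficient to replay the identical transform
    on new samples.
    """
    if matrix.values.size == 0:
        raise ValueError("cannot z-score an empty matrix")
    logm = matrix.to_log() if matrix.scale == "raw" else matrix
    vals = logm.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant gene row(s) mapped to zeros: "
            + ", ".join(map(str, constant[:5])),
            stacklevel=2,
        )
    safe_sd = sd.replace(0, np.nan)
    z = vals.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    z = z.fillna(0.0)
    norm = pd.DataFrame({"mean": mean, "sd": sd})
    return (
        ExpressionMatrix(z, scale="zscore", constant_genes=tuple(constant)),
        norm,
    )


def apply_gene_norm(matrix: ExpressionMatrix, norm: pd.DataFrame) -> ExpressionMatrix:
    """Apply previously fitted per-gene (mean, sd) to a new matrix."""
    logm = matrix.to_log() if matrix.scale == "raw" else matrix
    genes = [g for g in norm.index if g in logm.values.index]
    vals = logm.values.loc[genes]
    mean = norm.loc[genes, "mean"]
    sd = norm.loc[genes, "sd"].replace(0, np.nan)
    z = vals.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)
    return ExpressionMatrix(z, scale="zscore")
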