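"""Cohort application and orchestration: outcome recoding for validation
cohorts, stratified train/validation splitting, qPCR delta-Ct scoring, and the
end-to-end discovery pipeline with a reproducibility manifest.
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .candidates import (
    DEFAULT_CANDIDATE_SIZES,
    CandidatePool,
    refine_pool_by_bic,
    select_top_percentile,
    ubiquity_rank,
)
from .cohort import (
    ClinicalTable,
    ExpressionMatrix,
    ShrnaScreen,
    zscore_by_gene,
)
from .essentiality import call_survival_genes
from .evaluate import risk_group_report, roc_auc
from .risk import RiskModel, score_samples, train_risk_model
from .signature import Signature, backward_stepwise

__all__ = [
    "QpcrPanel",
    "recode_validation_outcomes",
    "stratified_split",
    "qpcr_to_expression",
    "PipelineResult",
    "run_pipeline",
]


@dataclass
class QpcrPanel:
    """Raw qPCR cycle thresholds: samples x genes, plus the reference gene."""

    ct: pd.DataFrame  # index = sample_id, columns = gene symbols (Ct values)
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} absent from panel")


def recode_validation_outcomes(clinical: ClinicalTable, mode: str) -> pd.Series:
    """Binary progression labels for validation cohorts.

    ``mode = "relapse"``: relapsed patients are progressed (uses a ``relapse``
    column when present, else the DFS event flag). ``mode = "death"``:
    deceased patients are progressed (uses the OS event flag). Samples with a
    missing outcome are excluded, with the count logged to stderr.
    """
    df = clinical.data
    if mode == "relapse":
        col = "relapse" if "relapse" in df.columns else "dfs_event"
    elif mode == "death":
        col = "os_event"
    else:
        raise ValueError("mode must be 'relapse' or 'death'")
    if col not in df.columns:
        raise ValueError(f"mode {mode!r} requires column {col!r}")
    raw = df[col]
    if raw.dtype == object:
        raw = raw.map({"yes": 1, "no": 0, "dead": 1, "alive": 0}).astype(float)
    labels = pd.to_numeric(raw, errors="coerce")
    n_missing = int(labels.isna().sum())
    if n_missing:
        print(
            f"recode_validation_outcomes: excluded {n_missing} sample(s) with missing outcome",
            file=sys.stderr,
        )
    out = labels.dropna().astype(int)
    out.name = "progressed"
    return out


def stratified_split(
    clinical: ClinicalTable,
    fraction: float,
    strata: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Seed-deterministic stratified train/validation split.

    Sampling is stratified on age quartile x gender by default. The training
    set has exactly round(n * fraction) samples overall, allocated to strata
    by largest remainder so each stratum deviates at most +-1 from its
    proportional share. Singleton strata go to training with a warning.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    df = clinical.data
    strata = strata or ["age", "gender"]
    keys = pd.DataFrame(index=df.index)
    for col in strata:
        if col not in df.columns:
            raise KeyError(f"stratification column {col!r} missing")
        vals = df[col]
        if pd.api.types.is_numeric_dtype(vals):
            keys[col] = pd.qcut(vals, 4, duplicates="drop").astype(str)
        else:
            keys[col] = vals.astype(str)
    stratum = keys.apply(lambda r: "|".join(r), axis=1)

    rng = np.random.default_rng(seed)
    groups = {k: list(idx) for k, idx in stratum.groupby(stratum).groups.items()}
    names = sorted(groups)
    singles = [k for k in names if len(groups[k]) == 1]
    if singles:
        warnings.warn(
            f"{len(singles)} singleton stratum(/a) assigned to training", stacklevel=2
        )
    multi = [k for k in names if len(groups[k]) > 1]
    n_total = len(df)
    target = round(n_total * fraction) - len(singles)
    target = max(0, min(target, sum(len(groups[k]) for k in multi)))

    shares = np.array([len(groups[k]) * fraction for k in multi])
    base = np.floor(shares).astype(int)
    base = np.minimum(base, [len(groups[k]) for k in multi])
    deficit = target - base.sum()
    remainders = shares - np.floor(shares)
    order = sorted(range(len(multi)), key=lambda i: (-remainders[i], names.index(multi[i])))
    alloc = base.copy()
    i = 0
    while deficit > 0 and i < len(order):
        j = order[i]
        if alloc[j] < len(groups[multi[j]]):
            alloc[j] += 1
            deficit -= 1
        i += 1
    while deficit < 0:
        j = order[-1]
        for j in reversed(order):
            if alloc[j] > 0:
                alloc[j] -= 1
                deficit += 1
                break

    train: list[str] = [groups[k][0] for k in singles]
    valid: list[str] = []
    for k, take in zip(multi, alloc):
        ids = sorted(groups[k])
        perm = rng.permutation(len(ids))
        chosen = [ids[i] for i in perm[:take]]
        train.extend(chosen)
        valid.extend(ids[i] for i in perm[take:])
    order_index = {s: i for i, s in enumerate(df.index)}
    train.sort(key=order_index.get)
    valid.sort(key=order_index.get)
    return train, valid


def qpcr_to_expression(panel: QpcrPanel) -> ExpressionMatrix:
    """Delta-Ct transform and within-panel z-scoring.

    dCt(gene, sample) = Ct(reference) - Ct(gene), which is proportional to
    log2 relative expression, then per-gene z-scored across the panel's
    samples. Samples missing the reference Ct are dropped with a warning; the
    result can be scored by :func:`pgskit.risk.score_samples` unchanged
    (cohort normalization already applied).
    """
    ct = panel.ct
    if ct.shape[0] < 2:
        raise ValueError("qPCR z-scoring needs at least 2 samples")
    ref = ct[panel.reference_gene]
    keep = ref.notna()
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} sample(s) missing reference Ct", stacklevel=2
        )
    ct = ct.loc[keep]
    genes = [g for g in ct.columns if g != panel.reference_gene]
    dct = ct[genes].rsub(ct[panel.reference_gene], axis=0)  # Ct(ref) - Ct(gene)
    matrix = ExpressionMatrix(dct.T, scale="log")
    zmat, _ = zscore_by_gene(matrix)
    return zmat


@dataclass
class PipelineResult:
    pool: CandidatePool
    essentiality: pd.DataFrame
    signature: Signature
    model: RiskModel
    scores: pd.DataFrame
    oof_probabilities: pd.Series
    report: dict
    manifest: dict


def run_pipeline(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    screen: ShrnaScreen,
    percentile: float = 99.0,
    bic_sizes: tuple[int, ...] | None = None,
    p_threshold: float = 0.25,
    seed: int = 0,
    label: str = "PGS",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full discovery pipeline.

    Candidate selection -> essentiality filtering -> stepwise signature
    assembly -> risk-model training -> scoring -> evaluation report, recording
    every stage (with parameters, seed and timings) in a manifest. Any stage
    failure aborts with the stage name. When ``out_dir`` is given, every
    intermediate artifact is written there as plain text.
    """
    manifest: dict = {
        "seed": seed,
        "parameters": {
            "percentile": percentile,
            "bic_sizes": list(bic_sizes) if bic_sizes else None,
            "p_threshold": p_threshold,
            "label": label,
        },
        "stages": [],
    }

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is None:
                    manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
                    print(f"[pgskit] {name}: {dt:.2f}s", file=sys.stderr)
                else:
                    manifest["stages"].append({"name": name, "failed": str(exc)})
                    raise RuntimeError(
                        f"pipeline stage {name!r} failed after "
                        f"{[s['name'] for s in manifest['stages'][:-1]]}: {exc}"
                    ) from exc
                return False

        return _Stage()

    with stage("candidate_selection"):
        if bic_sizes:
            pool = refine_pool_by_bic(
                expression, clinical, screen,
                candidate_sizes=tuple(bic_sizes), p_threshold=p_threshold,
            )
        else:
            stat = ubiquity_rank(expression)
            genes = select_top_percentile(stat, percentile)
            pool = CandidatePool(genes=genes, ubiquity_statistic=stat)

    with stage("essentiality_screen"):
        essentiality = call_survival_genes(screen, pool.genes)
        survival_genes = essentiality.index[essentiality["is_survival_gene"]].tolist()
        if not survival_genes:
            raise ValueError("no survival genes passed the mean-FC < 0 cutoff")

    with stage("signature_assembly"):
        zmat, _ = zscore_by_gene(expression)
        signature = backward_stepwise(
            zmat, clinical.data["progressed"], survival_genes,
            p_threshold=p_threshold, label=label,
        )
        if not signature.genes:
            raise ValueError("stepwise elimination removed every gene")

    with stage("risk_model"):
        model, oof = train_risk_model(
            expression, clinical.data["progressed"], signature, seed=seed
        )

    with stage("scoring"):
        scores = score_samples(model, expression)
        # honest evaluation on the training cohort: out-of-fold probabilities
        oof_scores = scores.copy()
        oof_scores.loc[oof.index, "probability"] = oof
        oof_scores["score"] = 100.0 * (oof_scores["probability"] - 0.5)
        oof_scores["group"] = np.where(oof_scores["score"] > 0, "high", "low")

    with stage("evaluation"):
        report = risk_group_report(oof_scores, clinical)
        labels = clinical.data["progressed"].dropna()
        common = [s for s in oof.index if s in labels.index]
        report["auc_oof"] = float(roc_auc(oof.loc[common], labels.loc[common]).auc)
        resub = scores.loc[common, "probability"]
        report["auc_resubstitution"] = float(roc_auc(resub, labels.loc[common]).auc)

    result = PipelineResult(
        pool=pool,
        essentiality=essentiality,
        signature=signature,
        model=model,
        scores=scores,
        oof_probabilities=oof,
        report=report,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "pool.json").write_text(json.dumps(result.pool.to_dict(), default=_json_default))
    result.essentiality.to_csv(out_dir / "essentiality.tsv", sep="\t", float_format="%.17g")
    (out_dir / "signature.json").write_text(json.dumps(result.signature.to_dict()))
    result.model.save(out_dir / "model.json")
    result.scores.to_csv(out_dir / "scores.tsv", sep="\t", float_format="%.17g")
    (out_dir / "report.json").write_text(json.dumps(result.report, default=_json_default))
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, default=_json_default))
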