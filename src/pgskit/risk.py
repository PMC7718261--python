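"""Risk scoring: iterated PCA / random-forest screening and a boosted
shallow-tanh-network classifier.

The pipeline linearises the z-scored signature-gene expression with a
full-rank PCA, screens the components with a 1000-tree random forest
(keeping components whose normalized importance exceeds 0.05), re-runs PCA on
the survivors and iterates until the forest retains every component. The
final components feed a gradient-boosted ensemble of tiny neural networks
(one hidden layer of 3 tanh units, linear output), 100 stages at learning
rate 0.1 on the log-loss gradient, with tenfold stratified cross-validation
supplying honest out-of-fold probabilities. Predicted progression
probabilities are transposed linearly to a -50..+50 risk score; scores > 0
mark the high-risk group (a score of exactly 0 is low-risk).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .cohort import ExpressionMatrix, apply_gene_norm, zscore_by_gene
from .signature import Signature

__all__ = [
    "PcaStep",
    "TanhNet",
    "BoostedNet",
    "RiskModel",
    "pca_fit",
    "rf_screen_pcs",
    "iterate_pca_rf",
    "fit_boosted_net",
    "train_risk_model",
    "score_samples",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaStep:
    mean: np.ndarray          # (d,)
    loadings: np.ndarray      # (n_pc, d); rows orthonormal
    explained_variance: np.ndarray
    selected: list[int] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.loadings.T


def pca_fit(X: np.ndarray) -> PcaStep:
    """Full-rank PCA via SVD: as many components as input variables.

    Sign convention: the largest-magnitude loading of each component is
    positive. Components beyond the data rank carry zero variance but are kept
    so downstream dimensions stay equal to the number of input variables.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=True)
    vt = vt[:d]
    ev = np.zeros(d)
    k = min(n - 1, d, s.size)
    ev[:k] = (s[:k] ** 2) / (n - 1)
    # deterministic sign: largest-|loading| entry positive
    for i in range(d):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    return PcaStep(mean=mean, loadings=vt, explained_variance=ev)


# ---------------------------------------------------------------------------
# random-forest screening
# ---------------------------------------------------------------------------

def rf_screen_pcs(
    pc_scores: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 1000,
    cutoff: float = 0.05,
    seed: int = 0,
    importance: str = "impurity",
) -> list[int]:
    """Keep components whose percent contribution exceeds ``cutoff``.

    Percent contribution is the forest's impurity-decrease importance
    normalized to sum to 1 (permutation importance available via
    ``importance="permutation"``). Never returns an empty selection: if no
    component clears the cutoff the single most important one is kept.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed), n_jobs=1
    )
    rf.fit(pc_scores, y)
    if importance == "impurity":
        imp = rf.feature_importances_
    elif importance == "permutation":
        from sklearn.inspection import permutation_importance

        r = permutation_importance(
            rf, pc_scores, y, n_repeats=10, random_state=int(seed)
        )
        imp = np.clip(r.importances_mean, 0, None)
    else:
        raise ValueError(f"unknown importance mode {importance!r}")
    total = imp.sum()
    contrib = imp / total if total > 0 else np.full(imp.size, 1.0 / imp.size)
    selected = [int(i) for i in np.nonzero(contrib > cutoff)[0]]
    if not selected:
        selected = [int(np.argmax(contrib))]
    return selected


def iterate_pca_rf(
    X: np.ndarray,
    labels: np.ndarray,
    max_rounds: int = 10,
    seed: int = 0,
    n_trees: int = 1000,
    cutoff: float = 0.05,
) -> tuple[list[PcaStep], np.ndarray]:
    """Alternate PCA and forest screening until the forest retains all PCs.

    Returns the recorded stack of PCA steps (with per-round selections, for
    exact replay at scoring time) and the final component scores.
    """
    current = np.asarray(X, dtype=float)
    stack: list[PcaStep] = []
    for round_idx in range(max_rounds):
        step = pca_fit(current)
        scores = step.transform(current)
        selected = rf_screen_pcs(
            scores, labels, n_trees=n_trees, cutoff=cutoff, seed=seed + round_idx
        )
        step.selected = selected
        stack.append(step)
        if len(selected) == scores.shape[1]:
            return stack, scores
        current = scores[:, selected]
    warnings.warn(f"PCA/RF iteration hit max_rounds = {max_rounds}", stacklevel=2)
    return stack, current


def replay_pca_stack(stack: list[PcaStep], X: np.ndarray) -> np.ndarray:
    current = np.asarray(X, dtype=float)
    for i, step in enumerate(stack):
        scores = step.transform(current)
        last = i == len(stack) - 1
        converged = len(step.selected) == scores.shape[1]
        if last and converged:
            return scores
        current = scores[:, step.selected]
    return current


# ---------------------------------------------------------------------------
# boosted shallow network
# ---------------------------------------------------------------------------

@dataclass
class TanhNet:
    """One hidden layer of tanh units with linear output: w2 . tanh(W1 x + b1) + b2."""

    W1: np.ndarray  # (hidden, d)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1.T + self.b1) @ self.w2 + self.b2


def _fit_tanh_net(
    X: np.ndarray,
    target: np.ndarray,
    hidden: int,
    rng: np.random.Generator,
    iters: int = 200,
    step: float = 0.05,
) -> TanhNet:
    """Least-squares fit of a tiny tanh network by full-batch Adam.

    The learner only needs to capture the pseudo-residual direction, so a
    short fixed-iteration schedule is enough and keeps fitting deterministic.
    """
    n, d = X.shape
    W1 = rng.normal(0.0, 0.5, (hidden, d))
    b1 = rng.normal(0.0, 0.1, hidden)
    w2 = rng.normal(0.0, 0.1, hidden)
    b2 = float(target.mean())
    params = [W1, b1, w2, np.array([b2])]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for it in range(1, iters + 1):
        H = np.tanh(X @ params[0].T + params[1])
        pred = H @ params[2] + params[3][0]
        err = pred - target  # d(MSE/2)/dpred
        g_w2 = H.T @ err / n
        g_b2 = np.array([err.mean()])
        dH = np.outer(err, params[2]) * (1.0 - H * H)
        g_W1 = dH.T @ X / n
        g_b1 = dH.mean(axis=0)
        grads = [g_W1, g_b1, g_w2, g_b2]
        for p, mp, vp, gp in zip(params, m, v, grads):
            mp *= beta1
            mp += (1 - beta1) * gp
            vp *= beta2
            vp += (1 - beta2) * gp * gp
            mhat = mp / (1 - beta1**it)
            vhat = vp / (1 - beta2**it)
            p -= step * mhat / (np.sqrt(vhat) + eps)
    return TanhNet(W1=params[0], b1=params[1], w2=params[2], b2=float(params[3][0]))


@dataclass
class BoostedNet:
    """Additive ensemble on the log-odds scale: F = intercept + lr * sum_m f_m."""

    intercept: float
    learners: list[TanhNet]
    learning_rate: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        F = np.full(X.shape[0], self.intercept)
        for net in self.learners:
            F += self.learning_rate * net.predict(X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.decision_function(X), -30, 30)))

    def staged_log_loss(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Training log-loss after each boosting stage (stage 0 = intercept)."""
        F = np.full(X.shape[0], self.intercept)
        out = []

        def loss(F):
            p = 1.0 / (1.0 + np.exp(-np.clip(F, -30, 30)))
            return float(-np.mean(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)))

        out.append(loss(F))
        for net in self.learners:
            F = F + self.learning_rate * net.predict(X)
            out.append(loss(F))
        return np.asarray(out)


def _boost(
    X: np.ndarray,
    y: np.ndarray,
    stages: int,
    hidden: int,
    lr: float,
    rng: np.random.Generator,
) -> BoostedNet:
    pbar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    intercept = float(np.log(pbar / (1 - pbar)))
    F = np.full(X.shape[0], intercept)
    learners: list[TanhNet] = []
    for _ in range(stages):
        p = 1.0 / (1.0 + np.exp(-np.clip(F, -30, 30)))
        residual = y - p  # negative gradient of log-loss wrt F
        net = _fit_tanh_net(X, residual, hidden, rng)
        F = F + lr * net.predict(X)
        learners.append(net)
    return BoostedNet(intercept=intercept, learners=learners, learning_rate=lr)


def fit_boosted_net(
    final_pcs: np.ndarray,
    labels: np.ndarray,
    stages: int = 100,
    hidden: int = 3,
    lr: float = 0.1,
    folds: int = 10,
    seed: int = 0,
) -> tuple[BoostedNet, np.ndarray]:
    """Gradient boosting of 3-tanh-node networks with tenfold stratified CV.

    Returns the deployed ensemble (refit on all samples) and per-sample
    out-of-fold probabilities for honest evaluation.
    """
    X = np.asarray(final_pcs, dtype=float)
    y = np.asarray(labels, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} samples per class for {folds}-fold stratified CV"
        )
    oof = np.empty(y.size)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        rng = np.random.default_rng((int(seed), fold_idx))
        model = _boost(X[tr], y[tr], stages, hidden, lr, rng)
        oof[te] = model.predict_proba(X[te])
    rng = np.random.default_rng((int(seed), folds))
    deployed = _boost(X, y, stages, hidden, lr, rng)
    return deployed, oof


# ---------------------------------------------------------------------------
# the assembled risk model
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    signature: Signature
    gene_norm: pd.DataFrame            # per-gene mean/sd from training
    pca_stack: list[PcaStep]
    ensemble: BoostedNet
    seed: int
    folds: int = 10
    training_auc_oof: float | None = None
    metadata: dict = field(default_factory=dict)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "signature": self.signature.to_dict(),
            "gene_norm": {
                g: [float(m), float(s)]
                for g, (m, s) in self.gene_norm[["mean", "sd"]].iterrows()
            },
            "pca_stack": [
                {
                    "mean": step.mean.tolist(),
                    "loadings": step.loadings.tolist(),
                    "explained_variance": step.explained_variance.tolist(),
                    "selected": list(step.selected),
                }
                for step in self.pca_stack
            ],
            "ensemble": {
                "intercept": self.ensemble.intercept,
                "learning_rate": self.ensemble.learning_rate,
                "learners": [
                    {
                        "W1": net.W1.tolist(),
                        "b1": net.b1.tolist(),
                        "w2": net.w2.tolist(),
                        "b2": net.b2,
                    }
                    for net in self.ensemble.learners
                ],
            },
            "seed": self.seed,
            "folds": self.folds,
            "training_auc_oof": self.training_auc_oof,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        gene_norm = pd.DataFrame(
            {g: {"mean": ms[0], "sd": ms[1]} for g, ms in d["gene_norm"].items()}
        ).T[["mean", "sd"]]
        stack = [
            PcaStep(
                mean=np.array(s["mean"]),
                loadings=np.array(s["loadings"]),
                explained_variance=np.array(s["explained_variance"]),
                selected=list(s["selected"]),
            )
            for s in d["pca_stack"]
        ]
        ens = BoostedNet(
            intercept=float(d["ensemble"]["intercept"]),
            learning_rate=float(d["ensemble"]["learning_rate"]),
            learners=[
                TanhNet(
                    W1=np.array(l["W1"]),
                    b1=np.array(l["b1"]),
                    w2=np.array(l["w2"]),
                    b2=float(l["b2"]),
                )
                for l in d["ensemble"]["learners"]
            ],
        )
        return cls(
            signature=Signature.from_dict(d["signature"]),
            gene_norm=gene_norm,
            pca_stack=stack,
            ensemble=ens,
            seed=int(d["seed"]),
            folds=int(d.get("folds", 10)),
            training_auc_oof=d.get("training_auc_oof"),
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_risk_model(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    signature: Signature,
    seed: int = 0,
    stages: int = 100,
    hidden: int = 3,
    lr: float = 0.1,
    folds: int = 10,
    n_trees: int = 1000,
    cutoff: float = 0.05,
    max_rounds: int = 10,
) -> tuple[RiskModel, pd.Series]:
    """Fit the full scoring pipeline on a training cohort.

    Returns the model and the out-of-fold probabilities (indexed by sample)
    from the tenfold CV of the boosting stage.
    """
    if not signature.genes:
        raise ValueError("signature has no genes")
    labels = labels.dropna()
    common = [s for s in matrix.sample_ids if s in labels.index]
    sub = matrix.subset_genes(signature.genes)
    sub = ExpressionMatrix(sub.values[common], scale=sub.scale)
    zmat, norm = zscore_by_gene(sub)
    X = zmat.values.to_numpy().T  # samples x genes
    y = labels.loc[common].to_numpy(dtype=float)

    stack, final_pcs = iterate_pca_rf(
        X, y, max_rounds=max_rounds, seed=seed, n_trees=n_trees, cutoff=cutoff
    )
    ensemble, oof = fit_boosted_net(
        final_pcs, y, stages=stages, hidden=hidden, lr=lr, folds=folds, seed=seed
    )
    from .evaluate import roc_auc  # local import to avoid a cycle

    auc = roc_auc(oof, y).auc
    model = RiskModel(
        signature=signature,
        gene_norm=norm,
        pca_stack=stack,
        ensemble=ensemble,
        seed=seed,
        folds=folds,
        training_auc_oof=float(auc),
        metadata={
            "stages": stages,
            "hidden": hidden,
            "learning_rate": lr,
            "n_trees": n_trees,
            "pc_cutoff": cutoff,
            "score_transposition": "score = 100 * (p - 0.5)",
            "deployed_model": "full-data refit",
        },
    )
    return model, pd.Series(oof, index=common, name="oof_probability")


def score_samples(
    model: RiskModel,
    matrix: ExpressionMatrix,
    normalization: str = "replay",
) -> pd.DataFrame:
    """Score a cohort with a trained model.

    ``normalization``: ``"replay"`` applies the training per-gene mean/sd
    (same-platform scoring); ``"cohort"`` re-z-scores within the new cohort
    (the cross-platform validation protocol). Missing signature genes are
    imputed at z = 0 with a warning, but more than 20% missing is an error.
    Returns a frame with probability, score in [-50, 50] and risk group
    (score > 0 is high risk; exactly 0 is low risk).
    """
    genes = model.signature.genes
    present = [g for g in genes if g in matrix.values.index]
    missing = [g for g in genes if g not in matrix.values.index]
    if len(missing) > 0.2 * len(genes):
        raise ValueError(
            f"{len(missing)}/{len(genes)} signature genes missing from matrix"
        )
    if missing:
        warnings.warn(
            "imputing z = 0 for missing signature gene(s): " + ", ".join(missing),
            stacklevel=2,
        )
    sub = ExpressionMatrix(matrix.values.loc[present], scale=matrix.scale)
    if normalization == "replay":
        zmat = apply_gene_norm(sub, model.gene_norm.loc[present])
    elif normalization == "cohort":
        if sub.scale == "zscore":
            zmat = sub
        else:
            zmat, _ = zscore_by_gene(sub)
    else:
        raise ValueError("normalization must be 'replay' or 'cohort'")
    z = pd.DataFrame(0.0, index=genes, columns=matrix.sample_ids)
    z.loc[present] = zmat.values.loc[present].to_numpy()
    X = z.to_numpy().T
    final = replay_pca_stack(model.pca_stack, X)
    prob = model.ensemble.predict_proba(final)
    score = 100.0 * (prob - 0.5)
    group = np.where(score > 0, "high", "low")
    return pd.DataFrame(
        {"probability": prob, "score": score, "group": group},
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
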