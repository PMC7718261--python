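"""Synthetic expression/clinical cohorts and shRNA screens.

A single latent per-patient risk factor z ~ N(0, 1) simultaneously drives
(i) the expression of a small planted gene set (loading_g * z on log2 scale),
(ii) the binary progression label through a logistic link, and (iii) DFS/OS
hazards through a log-linear proportional-hazards model. Planted genes also
receive a constant expression boost (so they dominate the ubiquity ranking)
and deplete in the simulated shRNA screen (negative mean log2 fold change).
This is the minimal structure under which genes that are highly expressed,
essential for cell survival and progression-associated coincide by
construction, which is what the discovery pipeline assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import ClinicalTable, ExpressionMatrix, ShrnaScreen

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_two_group_survival",
]


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of the cohort generator.

    Expression is simulated on log2 scale (shared baseline mean, i.i.d.
    Gaussian residual noise per gene and sample) and exported as 2**x so the
    raw matrix is non-negative like RSEM output. Survival is exponential with
    hazard baseline_hazard * exp(hazard_log_hr * z), censored by an
    independent exponential calibrated to the requested censoring fraction.
    """

    n_samples: int = 400
    n_genes: int = 2000
    n_planted: int = 20
    baseline_log_expression_mean: float = 5.0
    baseline_log_expression_sd: float = 1.0
    planted_expression_boost: float = 2.5
    progression_effect: float = 1.5  # log-odds of progression per unit latent risk
    latent_loading_mean: float = 0.6
    latent_loading_sd: float = 0.09
    n_cell_lines: int = 20
    shrnas_per_gene: int = 3
    essential_fc_mean: float = -1.0
    null_fc_mean: float = 0.0
    fc_sd: float = 0.3
    baseline_hazard: float = 0.02  # per month
    hazard_log_hr: float = 0.8
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, float) and not math.isfinite(value):
                raise ConfigurationError(f"{name} must be finite, got {value}")
        if self.n_samples < 1 or self.n_genes < 1:
            raise ConfigurationError("n_samples and n_genes must be positive")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ConfigurationError("need 0 <= n_planted <= n_genes")
        for name in ("baseline_log_expression_sd", "latent_loading_sd", "fc_sd",
                     "planted_expression_boost"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.fc_sd <= 0:
            raise ConfigurationError("fc_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigurationError("censor_rate must be in [0, 1]")
        if self.n_cell_lines < 1 or self.shrnas_per_gene < 1:
            raise ConfigurationError("n_cell_lines and shrnas_per_gene must be positive")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # raw (RSEM-like) scale
    clinical: ClinicalTable
    screen: ShrnaScreen
    planted_genes: frozenset[str]
    latent_risk: pd.Series
    config: SimulationConfig = field(repr=False, default=None)


def _censoring_rate_for(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+mu_i) = target."""
    if target <= 0:
        return 0.0
    if target >= 1:
        return math.inf

    def gap(c: float) -> float:
        return float(np.mean(c / (c + hazards)) - target)

    lo, hi = 1e-12, 1e12
    return brentq(gap, lo, hi, xtol=1e-12, rtol=1e-12)


def _survival_columns(
    rng: np.random.Generator,
    hazards: np.ndarray,
    censor_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    times = rng.exponential(1.0 / hazards)
    if censor_rate <= 0:
        return times, np.ones_like(times, dtype=int)
    c = _censoring_rate_for(hazards, censor_rate)
    censor = rng.exponential(1.0 / c, size=times.shape)
    event = (times <= censor).astype(int)
    return np.minimum(times, censor), event


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort (expression + clinical + screen) from ``config``.

    The same seed always yields a bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g, k = config.n_samples, config.n_genes, config.n_planted

    width = len(str(g))
    genes = [f"G{i:0{width}d}" for i in range(g)]
    samples = [f"S{i:04d}" for i in range(n)]
    planted = genes[:k]

    z = rng.standard_normal(n)
    loadings = rng.normal(config.latent_loading_mean, config.latent_loading_sd, k)

    log_expr = rng.normal(
        config.baseline_log_expression_mean,
        config.baseline_log_expression_sd,
        size=(g, n),
    )
    if k:
        log_expr[:k] += config.planted_expression_boost + np.outer(loadings, z)
    expression = ExpressionMatrix(
        pd.DataFrame(np.exp2(log_expr), index=genes, columns=samples), scale="raw"
    )

    prob = 1.0 / (1.0 + np.exp(-config.progression_effect * z))
    progressed = (rng.random(n) < prob).astype(int)

    hazards = config.baseline_hazard * np.exp(config.hazard_log_hr * z)
    dfs_months, dfs_event = _survival_columns(rng, hazards, config.censor_rate)
    os_months, os_event = _survival_columns(rng, 0.7 * hazards, config.censor_rate)

    age = rng.normal(65.0, 10.0, n)
    gender = rng.choice(["female", "male"], size=n)
    stage = rng.choice(["early", "late"], size=n)
    smoking = rng.choice(["never", "former", "current"], size=n)
    treated = rng.integers(0, 2, n)
    # treatment response tracks progression with 10% label noise
    flip = rng.random(n) < 0.10
    response = np.where(progressed.astype(bool) ^ flip, "resistant", "responder")
    hypoxia = 0.5 * z + rng.normal(0.0, 1.0, n)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "progressed": progressed,
                "dfs_months": dfs_months,
                "dfs_event": dfs_event,
                "os_months": os_months,
                "os_event": os_event,
                "age": age,
                "gender": gender,
                "stage": stage,
                "smoking": smoking,
                "treated": treated,
                "response": response,
                "hypoxia_score": hypoxia,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    cell_lines = [f"CL{i:02d}" for i in range(config.n_cell_lines)]
    records = []
    fc_means = np.where(
        np.arange(g) < k, config.essential_fc_mean, config.null_fc_mean
    )
    n_shr = config.shrnas_per_gene
    fc = rng.normal(
        fc_means[:, None, None],
        config.fc_sd,
        size=(g, n_shr, config.n_cell_lines),
    )
    for gi, gene in enumerate(genes):
        for si in range(n_shr):
            shrna = f"{gene}_sh{si}"
            for ci, cl in enumerate(cell_lines):
                records.append((shrna, gene, cl, fc[gi, si, ci]))
    screen = ShrnaScreen(
        pd.DataFrame(records, columns=["shrna_id", "gene", "cell_line", "log2_fc"])
    )

    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        screen=screen,
        planted_genes=frozenset(planted),
        latent_risk=pd.Series(z, index=samples, name="latent_risk"),
        config=config,
    )


def simulate_two_group_survival(
    n_per_group: int,
    hazard_ratio: float,
    baseline_hazard: float,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> ClinicalTable:
    """Exponential two-arm survival data (group 1 hazard = baseline * HR).

    Useful as an analytically tractable oracle input for KM / log-rank / Cox.
    """
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be positive")
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ConfigurationError("hazard_ratio and baseline_hazard must be > 0")
    if not 0 <= censor_rate <= 1:
        raise ConfigurationError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n_per_group)
    hazards = baseline_hazard * np.where(group == 1, hazard_ratio, 1.0)
    times, events = _survival_columns(rng, hazards, censor_rate)
    samples = [f"S{i:05d}" for i in range(2 * n_per_group)]
    return ClinicalTable(
        pd.DataFrame(
            {
                "dfs_months": times,
                "dfs_event": events,
                "group": group,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
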