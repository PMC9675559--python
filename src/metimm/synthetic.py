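"""Synthetic cohort and study-table generators.

These emulate the statistical structure the stratification analysis assumes:
block-correlated glycolytic and cholesterol gene modules riding on latent
per-sample module activities, a latent immune-inflammation axis that raises
the packaged 18-gene T-cell-inflamed signature in planted immuno-hot
samples, proportional-hazards (exponential) survival tied to planted group
labels, and study-level log hazard ratios with optional between-study
heterogeneity.  Every generator is a pure function of its config, seed
included: repeated calls are bit-identical.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import datasets
from .io import ExpressionMatrix, StudyEffect

__all__ = [
    "CohortConfig",
    "MetaSimConfig",
    "generate_expression_cohort",
    "generate_survival_times",
    "generate_meta_studies",
]

SUBTYPES = ("quiescent", "glycolytic", "cholesterol")

#: latent module / immune activity jitter (SD) shared by all module genes of
#: a sample; this is what makes module genes co-expressed rather than merely
#: mean-shifted.  Kept at half the default gene-level noise so planted
#: subtype labels stay recoverable at the stated effect sizes.
LATENT_SD = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic expression cohort.

    ``module_effect_size`` is the separation (high minus low) between planted
    subtypes in module-activity units; ``immune_effect_size`` is the hot/cold
    separation on the latent inflammation axis.  Defaults describe a cohort
    with clearly separated but noisy subtypes: effect 3 against unit noise,
    200 unstructured genes, and an EGFR-mutant admixture matching the
    77-in-881 prevalence of the cohort this generator emulates.
    """

    n_samples: int
    n_glycolytic_genes: int = 16
    n_cholesterol_genes: int = 13
    n_noise_genes: int = 200
    module_effect_size: float = 3.0
    immune_effect_size: float = 2.0
    noise_sd: float = 1.0
    egfr_mutant_fraction: float = 77 / 881
    include_signature_genes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 (three planted subtypes)")
        for name in ("n_glycolytic_genes", "n_cholesterol_genes", "n_noise_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.module_effect_size < 0 or self.immune_effect_size < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.egfr_mutant_fraction <= 1.0):
            raise ValueError("egfr_mutant_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MetaSimConfig:
    """Simulation frame for study-level log-hazard-ratio tables."""

    k_studies: int
    true_log_hr: float = 0.0
    tau2: float = 0.0
    n_range: tuple[int, int] = (100, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        lo, hi = self.n_range
        if not (1 <= lo <= hi):
            raise ValueError("n_range must satisfy 1 <= lo <= hi")


def _planted_gene_roles(config: CohortConfig) -> list[tuple[str, str]]:
    """Ordered (gene, role) pairs; first occurrence of a symbol wins."""
    candidates = datasets.load_metabolic_candidates()
    gly_pool = candidates["GLYCOLYSIS_CANDIDATES"].genes
    chol_pool = candidates["CHOLESTEROL_CANDIDATES"].genes
    if config.n_glycolytic_genes > len(gly_pool):
        raise ValueError(
            f"n_glycolytic_genes exceeds candidate pool size {len(gly_pool)}"
        )
    if config.n_cholesterol_genes > len(chol_pool):
        raise ValueError(
            f"n_cholesterol_genes exceeds candidate pool size {len(chol_pool)}"
        )
    roles: dict[str, str] = {}

    def add(gene: str, role: str) -> None:
        roles.setdefault(gene, role)

    for g in gly_pool[: config.n_glycolytic_genes]:
        add(g, "gly_module")
    for g in chol_pool[: config.n_cholesterol_genes]:
        add(g, "chol_module")
    for g in gly_pool[config.n_glycolytic_genes:]:
        add(g, "noise")
    for g in chol_pool[config.n_cholesterol_genes:]:
        add(g, "noise")
    for g in datasets.load_tcell_inflamed_signature().genes:
        add(g, "immune")
    if config.include_signature_genes:
        stromal, immune = datasets.load_estimate_signatures()
        for g in stromal.genes + immune.genes:
            add(g, "noise")
        for sig in datasets.load_immune_signatures().values():
            for g in sig.genes:
                add(g, "noise")
        driver, suppressor = datasets.load_ferroptosis_signatures()
        for g in driver.genes + suppressor.genes:
            add(g, "noise")
    for i in range(config.n_noise_genes):
        add(f"NOISE{i + 1:04d}", "noise")
    return list(roles.items())


def generate_expression_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (expression, clinical, truth) for one synthetic cohort.

    Samples are evenly assigned (sizes differ by at most one) to the three
    planted metabolic subtypes; each module gene carries the sample's latent
    module activity plus Gaussian noise; planted-hot samples are raised on
    the 18-gene T-cell-inflamed panel; EGFR-mutant flags are independent of
    subtype.  The returned clinical table carries null survival columns
    (all groups at the same hazard) drawn from a derived sub-seed; use
    :func:`generate_survival_times` to plant survival effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    subtype = np.array([SUBTYPES[i % 3] for i in range(n)])
    subtype = subtype[rng.permutation(n)]
    n_hot = math.ceil(n / 2)
    phenotype = np.array(["cold"] * n, dtype=object)
    phenotype[rng.permutation(n)[:n_hot]] = "hot"

    half = config.module_effect_size / 2.0
    imm_half = config.immune_effect_size / 2.0
    gly_act = np.where(subtype == "glycolytic", half, -half) + rng.normal(0, LATENT_SD, n)
    chol_act = np.where(subtype == "cholesterol", half, -half) + rng.normal(0, LATENT_SD, n)
    imm_act = np.where(phenotype == "hot", imm_half, -imm_half) + rng.normal(0, LATENT_SD, n)

    gene_roles = _planted_gene_roles(config)
    gene_ids = [g for g, _ in gene_roles]
    baseline = rng.normal(6.0, 1.0, len(gene_ids))
    activity = {
        "gly_module": gly_act,
        "chol_module": chol_act,
        "immune": imm_act,
        "noise": np.zeros(n),
    }
    values = np.empty((len(gene_ids), n))
    noise = rng.normal(0.0, config.noise_sd, size=values.shape)
    for row, (gene, role) in enumerate(gene_roles):
        values[row] = baseline[row] + activity[role] + noise[row]
    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    egfr = np.where(
        rng.random(n) < config.egfr_mutant_fraction, "mutant", "wild-type"
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": subtype,
            "phenotype": phenotype,
            "gly_activity": gly_act,
            "chol_activity": chol_act,
            "immune_activity": imm_act,
        }
    ).set_index("sample_id", drop=False)

    surv_seed = int(rng.integers(0, 2**31 - 1))
    survival = generate_survival_times(
        pd.Series("all", index=sample_ids),
        {"all": 0.0},
        baseline_rate=0.02,
        censor_prob=0.3,
        seed=surv_seed,
    )
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "egfr_status": egfr,
            "os_time": survival["os_time"].to_numpy(),
            "os_event": survival["os_event"].to_numpy(),
        }
    ).set_index("sample_id", drop=False)
    return expr, clinical, truth


def generate_survival_times(
    groups: pd.Series | Mapping[str, str],
    group_log_hr: Mapping[str, float],
    baseline_rate: float,
    censor_prob: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential event times under proportional hazards with censoring.

    Event times are exponential with rate ``baseline_rate * exp(log_hr)`` of
    the sample's group; with probability ``censor_prob`` a sample is censored
    at a Uniform(0, event time) instant instead.  Returns a DataFrame indexed
    by sample with ``os_time`` and ``os_event`` columns.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if not (0.0 <= censor_prob <= 1.0):
        raise ValueError("censor_prob must lie in [0, 1]")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    missing = sorted(set(groups.unique()) - set(group_log_hr))
    if missing:
        raise KeyError(f"groups without a specified log hazard: {missing}")
    rng = np.random.default_rng(seed)
    n = len(groups)
    rates = baseline_rate * np.exp(
        np.array([group_log_hr[g] for g in groups], dtype=float)
    )
    event_times = rng.exponential(1.0 / rates)
    censored = rng.random(n) < censor_prob
    censor_at = rng.uniform(0.0, event_times)
    times = np.where(censored, censor_at, event_times)
    return pd.DataFrame(
        {
            "sample_id": groups.index,
            "os_time": times,
            "os_event": (~censored).astype(int),
        }
    ).set_index("sample_id", drop=False)


def generate_meta_studies(config: MetaSimConfig) -> list[StudyEffect]:
    """Simulate k studies around a true pooled log hazard ratio.

    Per-study truth is ``true_log_hr + Normal(0, tau2)``; the observed
    log HR adds sampling noise at the study's standard error, where
    ``se_i = 2 / sqrt(n_i)`` — a stated, decreasing function of the study
    size drawn uniformly from ``n_range``.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_studies
    lo, hi = config.n_range
    n = rng.integers(lo, hi + 1, size=k)
    se = 2.0 / np.sqrt(n)
    theta = config.true_log_hr + rng.normal(0.0, math.sqrt(config.tau2), size=k)
    observed = theta + rng.normal(0.0, 1.0, size=k) * se
    return [
        StudyEffect(f"SIM{i + 1:02d}", float(observed[i]), float(se[i]), int(n[i]))
        for i in range(k)
    ]
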