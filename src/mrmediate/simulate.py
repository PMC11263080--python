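"""Synthetic GWAS summary statistics with known causal truth.

The generator emulates the two-sample MR setting directly on the summary
level: true per-variant instrument effects γ_j are drawn once, each GWAS
observes them (or their causal images) with the sampling error implied by its
sample size and the variant's allele frequency, se = (2·maf(1−maf)·N)^{−1/2}
— the standard error of a per-allele regression coefficient for a
standardized trait.  Pleiotropy (balanced or directional) and an
exposure→mediator→outcome mediation structure with known proportion are
configurable, as is block LD for exercising clumping.

Sample sizes are *effective* sample sizes: for a case/control GWAS the
per-SNP standard error behaves like that of a continuous trait with
n_eff = 4/(1/n_cases + 1/n_controls).  The defaults mirror the study design
this package targets: an autoimmune-disease exposure GWAS (~8k cases against
~400k controls, n_eff ≈ 32,000), a small dedicated immune-phenotype mediator
cohort (3,757) and a disease-endpoint outcome GWAS (~6.3k cases against
~222k controls, n_eff ≈ 24,500).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, SumStatTable

#: within-block spacing (bp) keeps correlated variants inside the clumping
#: window; blocks are separated by more than the default 10,000 kb window.
BLOCK_SPACING_BP = 1_000_000
BETWEEN_BLOCK_GAP_BP = 20_000_000


@dataclass
class Pleiotropy:
    """Direct variant→outcome effects for the invalid instruments.

    ``kind`` is ``"none"``, ``"balanced"`` (mean-zero) or ``"directional"``.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced":
            self.mean = 0.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic exposure–(mediator)–outcome system."""

    n_snps: int = 100
    n_exposure: int = 32_000
    n_mediator: int = 3_757
    n_outcome: int = 24_500
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.1
    delta_sd: float = 0.5
    theta: float = 0.1
    a_true: float = 0.2
    b_true: float = 0.3
    c_prime: float = 0.04
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    prop_invalid: float = 0.0
    n_mediator_snps: int = 100
    ld_blocks: Sequence[tuple[int, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prop_invalid <= 1:
            raise ValueError("prop_invalid must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for n in (self.n_snps, self.n_exposure, self.n_mediator, self.n_outcome):
            if n < 1:
                raise ValueError("counts and sample sizes must be ≥ 1")
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise ValueError("ld_blocks sizes exceed n_snps")


@dataclass
class SimTruth:
    """The generating parameters behind one simulated system."""

    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray
    theta: float
    a: Optional[float] = None
    b: Optional[float] = None
    c_prime: Optional[float] = None
    proportion: Optional[float] = None
    delta: Optional[np.ndarray] = None  # mediator-specific instrument effects


def _positions(n_snps: int, ld_blocks: Sequence[tuple[int, float]]) -> np.ndarray:
    """Positions on one chromosome: correlated blocks packed inside the
    clumping window, independent variants separated beyond it."""
    pos = np.empty(n_snps, dtype=int)
    cursor = 1
    i = 0
    for size, _ in ld_blocks:
        for j in range(size):
            pos[i] = cursor + j * BLOCK_SPACING_BP
            i += 1
        cursor += size * BLOCK_SPACING_BP + BETWEEN_BLOCK_GAP_BP
    while i < n_snps:
        pos[i] = cursor
        cursor += BETWEEN_BLOCK_GAP_BP
        i += 1
    return pos


def _table(trait_id, trait_type, ids, pos, maf, beta, se, n) -> SumStatTable:
    pval = 2 * stats.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, 1e-300, 1.0)
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(n),
        }
    )
    return SumStatTable(trait_id=trait_id, trait_type=trait_type, records=df)


def _se_for(maf: np.ndarray, n: int) -> np.ndarray:
    return (2 * maf * (1 - maf) * n) ** -0.5


def simulate_sumstats(cfg: SimConfig) -> tuple[SumStatTable, SumStatTable, SimTruth]:
    """Exposure and outcome summary statistics under a known total effect θ.

    β_x,j ~ N(γ_j, se_x,j²) and β_y,j ~ N(θ·γ_j + α_j, se_y,j²), with α_j
    the pleiotropic effect of the configured invalid fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    ids = [f"rs{i + 1}" for i in range(k)]
    pos = _positions(k, cfg.ld_blocks)
    maf = rng.uniform(*cfg.maf_range, size=k)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=k)

    n_invalid = int(round(cfg.prop_invalid * k))
    valid = np.ones(k, dtype=bool)
    alpha = np.zeros(k)
    if n_invalid and cfg.pleiotropy.kind != "none":
        invalid_idx = rng.choice(k, size=n_invalid, replace=False)
        valid[invalid_idx] = False
        alpha[invalid_idx] = rng.normal(cfg.pleiotropy.mean, cfg.pleiotropy.sd, size=n_invalid)

    se_x = _se_for(maf, cfg.n_exposure)
    se_y = _se_for(maf, cfg.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.theta * gamma + alpha, se_y)

    exposure = _table("sim_exposure", "binary", ids, pos, maf, beta_x, se_x, cfg.n_exposure)
    outcome = _table("sim_outcome", "binary", ids, pos, maf, beta_y, se_y, cfg.n_outcome)
    truth = SimTruth(gamma=gamma, alpha=alpha, valid=valid, theta=cfg.theta)
    return exposure, outcome, truth


def simulate_mediation_system(
    cfg: SimConfig,
) -> tuple[SumStatTable, SumStatTable, SumStatTable, SimTruth]:
    """Exposure, mediator and outcome tables under X → M → Y mediation.

    The exposure's instruments carry the total effect a·b + c′ to the
    outcome and a to the mediator; ``n_mediator_snps`` mediator-specific
    instruments δ_j ~ N(0, delta_sd²) affect the mediator directly and the
    outcome through b — these identify b in the MVMR step.  ``delta_sd``
    defaults to 0.5: immune-cell phenotypes are strongly heritable with large
    per-allele effects, which is how a 3,757-sample GWAS yields genome-wide
    significant instruments at all.
    """
    rng = np.random.default_rng(cfg.seed)
    k_x, k_m = cfg.n_snps, cfg.n_mediator_snps
    k = k_x + k_m
    ids = [f"rs{i + 1}" for i in range(k)]
    pos = _positions(k, cfg.ld_blocks)
    maf = rng.uniform(*cfg.maf_range, size=k)

    gamma = np.zeros(k)
    gamma[:k_x] = rng.normal(0.0, cfg.gamma_sd, size=k_x)
    delta = np.zeros(k)
    delta[k_x:] = rng.normal(0.0, cfg.delta_sd, size=k_m)

    n_invalid = int(round(cfg.prop_invalid * k_x))
    valid = np.ones(k, dtype=bool)
    alpha = np.zeros(k)
    if n_invalid and cfg.pleiotropy.kind != "none":
        invalid_idx = rng.choice(k_x, size=n_invalid, replace=False)
        valid[invalid_idx] = False
        alpha[invalid_idx] = rng.normal(cfg.pleiotropy.mean, cfg.pleiotropy.sd, size=n_invalid)

    theta_total = cfg.c_prime + cfg.a_true * cfg.b_true
    mu_x = gamma
    mu_m = cfg.a_true * gamma + delta
    mu_y = theta_total * gamma + cfg.b_true * delta + alpha

    se_x = _se_for(maf, cfg.n_exposure)
    se_m = _se_for(maf, cfg.n_mediator)
    se_y = _se_for(maf, cfg.n_outcome)
    beta_x = rng.normal(mu_x, se_x)
    beta_m = rng.normal(mu_m, se_m)
    beta_y = rng.normal(mu_y, se_y)

    exposure = _table("sim_exposure", "binary", ids, pos, maf, beta_x, se_x, cfg.n_exposure)
    mediator = _table("sim_mediator", "continuous", ids, pos, maf, beta_m, se_m, cfg.n_mediator)
    outcome = _table("sim_outcome", "binary", ids, pos, maf, beta_y, se_y, cfg.n_outcome)
    proportion = (
        cfg.a_true * cfg.b_true / theta_total if theta_total != 0 else None
    )
    truth = SimTruth(
        gamma=gamma,
        alpha=alpha,
        valid=valid,
        theta=theta_total,
        a=cfg.a_true,
        b=cfg.b_true,
        c_prime=cfg.c_prime,
        proportion=proportion,
        delta=delta,
    )
    return exposure, mediator, outcome, truth


def simulate_ld_blocks(cfg: SimConfig) -> LDMatrix:
    """Block-diagonal r² matrix matching the variant grid of the generator."""
    k = cfg.n_snps
    ids = [f"rs{i + 1}" for i in range(k)]
    pos = _positions(k, cfg.ld_blocks)
    r2 = np.eye(k)
    i = 0
    for size, block_r2 in cfg.ld_blocks:
        block = np.full((size, size), float(block_r2))
        np.fill_diagonal(block, 1.0)
        r2[i : i + size, i : i + size] = block
        i += size
    return LDMatrix(
        variant_ids=ids,
        r2=r2,
        chrom={v: "1" for v in ids},
        pos={v: int(p) for v, p in zip(ids, pos)},
    )
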