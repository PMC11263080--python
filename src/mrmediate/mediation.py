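"""Two-step MR mediator screening and Delta-method mediation proportions.

For an exposure X with a significant total effect c on outcome Y, a candidate
mediator M is screened in two steps: (1) the effect a of X on M by
univariable IVW; (2) the direct effect b of M on Y by multivariable IVW
adjusting for X.  The indirect effect is a·b and the proportion mediated is
a·b/c; both standard errors propagate by the first-order Delta method with
coefficient covariances set to zero (the mediator GWAS cohort does not
overlap the exposure or outcome cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import instruments as instr
from .harmonize import harmonize_pair
from .mvmr import harmonize_multi, mv_ivw
from .sumstats import SumStatTable
from .uvmr import Z95, ivw

logger = logging.getLogger("mrmediate.mediation")


@dataclass
class ScreenCriteria:
    """Gates a candidate mediator must pass before its proportion is reported."""

    alpha_mediator: float = 0.05
    require_no_reverse: bool = True
    require_sign_consistency: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_mediator < 1:
            raise ValueError("alpha_mediator must be in (0, 1)")


@dataclass
class MediationResult:
    """The (a, b, c) coefficient triplet for one exposure–mediator–outcome path."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: Optional[float] = None
    se_a: Optional[float] = None
    p_a: Optional[float] = None
    b: Optional[float] = None
    se_b: Optional[float] = None
    p_b: Optional[float] = None
    c: Optional[float] = None
    se_c: Optional[float] = None
    p_c: Optional[float] = None
    indirect: Optional[float] = None
    se_indirect: Optional[float] = None
    proportion: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    screen_flags: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.screen_flags) and all(self.screen_flags.values())


def indirect_effect_delta(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Product-of-coefficients indirect effect a·b with first-order Delta SE.

    se = sqrt(a²·se_b² + b²·se_a²), assuming zero covariance between a and b.
    The formula is symmetric in (a, se_a) ↔ (b, se_b).
    """
    indirect = a * b
    se = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    return float(indirect), se


def mediation_proportion(
    indirect: float, se_indirect: float, c: float, se_c: float
) -> tuple[float, float, float]:
    """Proportion mediated indirect/c with a ratio Delta-method 95% CI.

    var(ind/c) ≈ se_ind²/c² + ind²·se_c²/c⁴ with zero covariance; returns the
    proportion as a fraction (multiply by 100 for the percentage).
    """
    if c == 0:
        raise ValueError("total effect c must be non-zero")
    prop = indirect / c
    var = se_indirect**2 / c**2 + indirect**2 * se_c**2 / c**4
    half = Z95 * float(np.sqrt(var))
    return float(prop), float(prop - half), float(prop + half)


def _reverse_instruments(iset, other: SumStatTable):
    """Drop reverse-test instruments more strongly associated with ``other``.

    When a forward effect truly exists, the downstream trait's hit list
    inherits the upstream trait's instruments, and a naive reverse MR flags
    bidirectionality by construction.  A variant more strongly associated
    with the putative *effect* trait than with the instrument trait most
    plausibly acts on that trait first, so it is removed before the reverse
    test.  The comparison uses association z-scores with a 2-SD buffer: a shared
    variant is kept only when its instrument-trait association exceeds its
    target-trait association by at least two standard deviations, so sampling
    noise on genuinely downstream hits rarely leaks instruments through.
    """
    other_z = dict(
        zip(other.records["variant_id"], np.abs(other.records["beta"] / other.records["se"]))
    )
    own_z = dict(
        zip(iset.records["variant_id"], np.abs(iset.records["beta"] / iset.records["se"]))
    )
    drop = {v for v in own_z if v in other_z and own_z[v] < other_z[v] + 2.0}
    keep = ~iset.records["variant_id"].isin(drop)
    return iset._with(iset.records.loc[keep], "reverse:dropped_ambiguous_origin")


def screen_mediators(
    exposure: SumStatTable,
    outcome: SumStatTable,
    mediator_tables: Sequence[SumStatTable],
    criteria: ScreenCriteria | None = None,
    *,
    ld=None,
    blacklist=(),
    p_threshold: float = instr.GENOME_WIDE_P,
    r2_threshold: float = instr.DEFAULT_R2,
    window_kb: int = instr.DEFAULT_WINDOW_KB,
    min_f: float = instr.DEFAULT_MIN_F,
    palindrome_policy: str = "infer_by_eaf",
    ivw_mode: str = "multiplicative_random",
    adjusted_b: bool = True,
) -> list[MediationResult]:
    """Two-step MR screen of candidate mediators for one exposure–outcome pair.

    Per mediator the gates are: (1) p_a < alpha (exposure affects mediator);
    (2) no reverse signal — mediator→exposure and outcome→mediator both
    non-significant, when their instruments exist; (3) p_b < alpha for the
    mediator's outcome effect adjusted for the exposure (MV-IVW; set
    ``adjusted_b=False`` for the unadjusted univariable b); (4) the product
    a·b agrees in sign with the total effect c.  Every candidate receives a
    :class:`MediationResult` with audit flags; only survivors of all gates
    carry indirect effects and proportions.
    """
    criteria = criteria or ScreenCriteria()
    sel = dict(
        ld=ld,
        blacklist=blacklist,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
        min_f=min_f,
    )
    exp_iset = instr.select_instruments(exposure, **sel)
    if exp_iset.n_variants < 2:
        raise ValueError(f"exposure {exposure.trait_id} has <2 instruments; cannot screen mediators")

    h_total = harmonize_pair(exp_iset, outcome, palindrome_policy)
    total = ivw(h_total, ivw_mode)
    c, se_c, p_c = total.beta, total.se, total.pval

    out_iset = instr.select_instruments(outcome, **sel)

    results: list[MediationResult] = []
    for med in mediator_tables:
        res = MediationResult(
            exposure_id=exposure.trait_id,
            mediator_id=med.trait_id,
            outcome_id=outcome.trait_id,
            c=c,
            se_c=se_c,
            p_c=p_c,
        )
        results.append(res)

        # step 1: a — exposure → mediator
        try:
            h_a = harmonize_pair(exp_iset, med, palindrome_policy)
            est_a = ivw(h_a, ivw_mode)
        except ValueError as exc:
            logger.info("%s: cannot estimate a (%s); skipped", med.trait_id, exc)
            res.screen_flags["a_estimable"] = False
            continue
        res.screen_flags["a_estimable"] = True
        res.a, res.se_a, res.p_a = est_a.beta, est_a.se, est_a.pval
        res.screen_flags["a_significant"] = res.p_a < criteria.alpha_mediator
        if not res.screen_flags["a_significant"]:
            continue

        # step 2: reverse checks — mediator → exposure and outcome → mediator,
        # each on instruments not shared with the forward direction
        med_iset = instr.select_instruments(med, **sel)
        if criteria.require_no_reverse:
            no_reverse = True
            med_rev = _reverse_instruments(med_iset, exposure)
            if med_rev.n_variants >= 2:
                try:
                    rev = ivw(harmonize_pair(med_rev, exposure, palindrome_policy), ivw_mode)
                    no_reverse &= rev.pval >= criteria.alpha_mediator
                except ValueError:
                    pass
            out_rev = _reverse_instruments(out_iset, med)
            if out_rev.n_variants >= 2:
                try:
                    rev = ivw(harmonize_pair(out_rev, med, palindrome_policy), ivw_mode)
                    no_reverse &= rev.pval >= criteria.alpha_mediator
                except ValueError:
                    pass
            res.screen_flags["no_reverse"] = bool(no_reverse)
            if not no_reverse:
                continue

        # step 3: b — mediator → outcome, adjusted for the exposure
        try:
            if adjusted_b:
                d = harmonize_multi(
                    [med_iset, exp_iset], [med, exposure], outcome,
                    palindrome_policy=palindrome_policy,
                )
                est_b = mv_ivw(d).for_exposure(med.trait_id)
                res.b, res.se_b, res.p_b = est_b["beta"], est_b["se"], est_b["pval"]
            else:
                est_b = ivw(harmonize_pair(med_iset, outcome, palindrome_policy), ivw_mode)
                res.b, res.se_b, res.p_b = est_b.beta, est_b.se, est_b.pval
        except ValueError as exc:
            logger.info("%s: cannot estimate b (%s); skipped", med.trait_id, exc)
            res.screen_flags["b_estimable"] = False
            continue
        res.screen_flags["b_estimable"] = True
        res.screen_flags["b_significant"] = res.p_b < criteria.alpha_mediator
        if not res.screen_flags["b_significant"]:
            continue

        # step 4: the indirect effect must not oppose the total effect
        if criteria.require_sign_consistency:
            res.screen_flags["sign_consistent"] = bool(np.sign(res.a * res.b) == np.sign(c))
            if not res.screen_flags["sign_consistent"]:
                continue

        res.indirect, res.se_indirect = indirect_effect_delta(res.a, res.se_a, res.b, res.se_b)
        res.proportion, res.ci_low, res.ci_high = mediation_proportion(
            res.indirect, res.se_indirect, c, se_c
        )
    return results
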