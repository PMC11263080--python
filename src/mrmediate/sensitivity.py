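"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Cochran's Q measures heterogeneity of per-variant Wald ratios around the IVW
estimate; the MR-Egger intercept tests directional pleiotropy; MR-PRESSO is a
simulation-based residual-sum-of-squares test with per-variant outlier
detection and a distortion test; leave-one-out quantifies the influence of
single instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet
from .uvmr import MREstimate, _ivw_core, egger, ivw

logger = logging.getLogger("mrmediate.sensitivity")


@dataclass
class HeterogeneityReport:
    q: float
    df: int
    p_q: float
    i2: float


@dataclass
class PressoReport:
    rss_obs: float
    global_p: float
    outlier_indices: list[str]
    outlier_p: dict[str, float]
    distortion_p: Optional[float]
    estimate_before: MREstimate
    estimate_after: Optional[MREstimate]
    n_sim: int
    seed: int


def cochran_q(h: HarmonizedSet) -> HeterogeneityReport:
    """Cochran's Q on the Wald-ratio scale with first-order weights, plus I².

    With w_j = (se_y/β_x)⁻² this is algebraically identical to the residual
    weighted sum of squares of the origin regression.
    """
    if h.k < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    _, _, q = _ivw_core(h.beta_x, h.beta_y, h.se_y)
    df = h.k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityReport(q=q, df=df, p_q=p, i2=i2)


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept, its SE and two-sided p (directional-pleiotropy test)."""
    fit = egger(h)
    return fit.intercept, fit.intercept_se, fit.intercept_p


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for every j, via sum updates."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PressoReport:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is RSS_obs = Σ_j w_j (β_y,j − θ̂_(−j) β_x,j)² with
    θ̂_(−j) the leave-one-out IVW estimate and w_j = se_y,j⁻².  The null
    distribution draws β*_x,j ~ N(β_x,j, se_x,j²) and
    β*_y,j ~ N(θ̂_(−j) β_x,j, se_y,j²) and recomputes the statistic the same
    way.  Empirical p-values use (1 + #{≥ obs})/(n_sim + 1), so they can never
    be exactly zero.  Outliers (per-variant residual tests, Bonferroni-scaled
    by k) are only reported when the global test rejects at ``alpha``;
    downstream estimators should then be re-run on the outlier-free set.
    """
    if h.k < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    k = h.k
    w = sy**-2.0

    theta_loo = _loo_thetas(bx, by, w)
    resid2_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(resid2_obs))

    # simulated null: (n_sim, k) draws, LOO estimates recomputed per draw
    bxs = rng.normal(bx, sx, size=(n_sim, k))
    bys = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    s1 = np.sum(w * bxs * bys, axis=1, keepdims=True)
    s2 = np.sum(w * bxs**2, axis=1, keepdims=True)
    theta_loo_sim = (s1 - w * bxs * bys) / (s2 - w * bxs**2)
    resid2_sim = w * (bys - theta_loo_sim * bxs) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_p_raw = (1 + np.sum(resid2_sim >= resid2_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_p = {v: float(min(1.0, p * k)) for v, p in zip(h.variant_ids, outlier_p_raw)}

    outliers: list[str] = []
    if global_p < alpha:
        outliers = [v for v in h.variant_ids if outlier_p[v] < alpha]

    estimate_before = ivw(h)
    estimate_after = None
    distortion_p = None
    if outliers and (k - len(outliers)) >= 2:
        h_clean = h.drop_variants(outliers)
        estimate_after = ivw(h_clean)
        # distortion: observed shift vs shifts from removing |outliers| random SNPs
        n_out = len(outliers)
        obs_shift = estimate_after.beta - estimate_before.beta
        shifts = np.empty(n_sim)
        ids = np.arange(k)
        for i in range(n_sim):
            drop = rng.choice(ids, size=n_out, replace=False)
            keep = np.setdiff1d(ids, drop)
            th, _, _ = _ivw_core(bx[keep], by[keep], sy[keep])
            shifts[i] = th - estimate_before.beta
        distortion_p = float((1 + np.sum(np.abs(shifts) >= abs(obs_shift))) / (n_sim + 1))
    elif outliers:
        logger.warning("all but <2 instruments flagged as outliers; no corrected estimate")

    return PressoReport(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_indices=outliers,
        outlier_p=outlier_p,
        distortion_p=distortion_p,
        estimate_before=estimate_before,
        estimate_after=estimate_after,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(h: HarmonizedSet, ivw_mode: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated k times, omitting one instrument each time.

    A row is flagged when omitting that variant changes the sign of the
    estimate or its significance at 0.05 relative to the full-set IVW.
    """
    if h.k < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    full = ivw(h, ivw_mode)
    rows = []
    for v in h.variant_ids:
        sub = h.drop_variants([v])
        est = ivw(sub, ivw_mode)
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or ((est.pval < 0.05) != (full.pval < 0.05))
        rows.append(
            {
                "left_out": v,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)
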