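"""Univariable two-sample MR estimators.

All estimators consume a :class:`~mrmediate.harmonize.HarmonizedSet` of
instrument-level effect pairs.  The inverse-variance-weighted (IVW) estimate
is the weighted regression of outcome effects on exposure effects through the
origin (equivalently the precision-weighted mean of Wald ratios); MR-Egger
adds an intercept capturing directional pleiotropy; the weighted median is
consistent when instruments carrying more than half the weight are valid.

p-values use the normal reference throughout, the convention for two-sample
summary-data MR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet

logger = logging.getLogger("mrmediate.uvmr")

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One estimator's causal effect on the log-odds scale plus the OR scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int, **kw) -> "MREstimate":
        ci_low, ci_high = beta - Z95 * se, beta + Z95 * se
        pval = float(np.clip(2 * stats.norm.sf(abs(beta) / se), np.nextafter(0, 1), 1.0))
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(ci_low),
            ci_high=float(ci_high),
            pval=pval,
            n_snps=int(n_snps),
            odds_ratio=float(np.exp(beta)),
            or_ci_low=float(np.exp(ci_low)),
            or_ci_high=float(np.exp(ci_high)),
            **kw,
        )


def wald_ratios(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant ratio estimates θ_j = β_y/β_x with first-order SE σ_j = se_y/|β_x|."""
    keep = h.beta_x != 0
    if not keep.any():
        raise ValueError("all exposure effects are zero; no Wald ratios defined")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%d variants with beta_x = 0 dropped from Wald ratios", n_dropped)
    bx, by, sy = h.beta_x[keep], h.beta_y[keep], h.se_y[keep]
    return pd.DataFrame(
        {
            "variant_id": np.asarray(h.variant_ids)[keep],
            "theta": by / bx,
            "sigma": sy / np.abs(bx),
        }
    )


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Closed-form IVW: returns (theta_hat, fixed_se, Q)."""
    w = sy**-2
    s2 = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by) / s2)
    se_fixed = s2**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, q


def ivw(h: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (weighted regression through the origin).

    ``mode="fixed"`` uses the fixed-effect SE; ``"multiplicative_random"``
    (default) inflates it by sqrt(max(1, Q/(k−1))) so heterogeneity widens the
    interval but can never shrink it below the fixed-effect one.
    """
    if h.k < 2:
        raise ValueError("IVW requires at least 2 instruments; use wald_ratios for k=1")
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    theta, se_fixed, q = _ivw_core(h.beta_x, h.beta_y, h.se_y)
    se = se_fixed
    if mode == "multiplicative_random":
        se = se_fixed * float(np.sqrt(max(1.0, q / (h.k - 1))))
    return MREstimate.from_beta_se(f"ivw_{mode.split('_')[-1]}" if mode == "multiplicative_random" else "ivw_fixed", theta, se, h.k)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression with intercept, instruments oriented β_x > 0.

    The slope is the pleiotropy-adjusted causal estimate and the intercept the
    average directional pleiotropy.  SEs carry a multiplicative overdispersion
    factor sqrt(max(1, RSS_w/(k−2))).
    """
    if h.k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(h.beta_x)
    flip[flip == 0] = 1.0
    bx, by, sy = h.beta_x * flip, h.beta_y * flip, h.se_y
    w = sy**-2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (h.k - 2))
    cov = phi * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_int = float(np.clip(2 * stats.norm.sf(abs(intercept) / se_int), np.nextafter(0, 1), 1.0))
    return MREstimate.from_beta_se(
        "egger",
        slope,
        se_slope,
        h.k,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=p_int,
    )


def weighted_median_estimate(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    With weights standardized to s_j, the cumulative quantile position of the
    j-th ordered ratio is p_j = Σ_{i≤j} s_i − s_j/2; the estimate interpolates
    (p_j, θ_j) linearly at 0.5 (clamped to the extreme ratios outside [p_1, p_k]).
    """
    theta = np.asarray(theta, float)
    w = np.asarray(w, float)
    # secondary key on weight makes ties deterministic and order-independent
    order = np.lexsort((w, theta))
    th, ww = theta[order], w[order]
    s = ww / ww.sum()
    p = np.cumsum(s) - s / 2
    return float(np.interp(0.5, p, th))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Valid when instruments carrying > 50% of the inverse-variance weight are
    valid; the SE resamples (β_x, β_y) from their reported normal errors.
    """
    if h.k < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    ratios = wald_ratios(h)
    w = ratios["sigma"].to_numpy() ** -2.0
    est = weighted_median_estimate(ratios["theta"].to_numpy(), w)

    rng = np.random.default_rng(seed)
    bx, sx = h.beta_x, h.se_x
    by, sy = h.beta_y, h.se_y
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        th = bys[ok] / bxs[ok]
        sg = sy[ok] / np.abs(bxs[ok])
        boots[i] = weighted_median_estimate(th, sg**-2.0)
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se("weighted_median", est, se, h.k)


def estimate_all(h: HarmonizedSet, ivw_mode: str = "multiplicative_random", n_boot: int = 1000, seed: int = 0) -> list[MREstimate]:
    """The standard estimator battery: IVW plus Egger and weighted median when k allows."""
    out = [ivw(h, ivw_mode)]
    if h.k >= 3:
        out.append(egger(h))
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
    return out
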