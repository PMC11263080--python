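"""Multivariable Mendelian randomization (MVMR).

Regressing outcome effects jointly on several exposures' genetic effects
yields each exposure's *direct* effect, conditional on the others — the
ingredient needed to estimate a mediator's effect on the outcome adjusted for
the upstream exposure.  Robust variants (Egger intercept, weighted median /
LAD, and lasso-based invalid-instrument selection) guard against pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .harmonize import DEFAULT_MAF_LIMIT, align_alleles
from .instruments import InstrumentSet
from .sumstats import SumStatTable
from .uvmr import Z95

logger = logging.getLogger("mrmediate.mvmr")

CONDITION_LIMIT = 1e8


@dataclass
class MVMRDataset:
    """Instrument-level effects for m exposures and one outcome, one orientation."""

    outcome_id: str
    exposure_ids: list[str]
    variant_ids: list[str]
    beta_x: np.ndarray  # (k, m)
    se_x: np.ndarray  # (k, m)
    beta_y: np.ndarray  # (k,)
    se_y: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        self.beta_y = np.asarray(self.beta_y, float)
        self.se_y = np.asarray(self.se_y, float)
        k, m = self.beta_x.shape
        if m != len(self.exposure_ids):
            raise ValueError("beta_x column count must match exposure_ids")
        if k <= m:
            raise ValueError(f"need more instruments (k={k}) than exposures (m={m})")

    @property
    def k(self) -> int:
        return self.beta_x.shape[0]

    @property
    def m(self) -> int:
        return self.beta_x.shape[1]

    def subset(self, idx: np.ndarray) -> "MVMRDataset":
        return MVMRDataset(
            outcome_id=self.outcome_id,
            exposure_ids=list(self.exposure_ids),
            variant_ids=[self.variant_ids[i] for i in np.atleast_1d(idx)],
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
        )


@dataclass
class MVMREstimate:
    """Per-exposure direct effects from one multivariable estimator."""

    method: str
    exposure_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pval: np.ndarray
    n_snps: int
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    selected_valid_set: Optional[list[str]] = None

    @classmethod
    def from_beta_se(cls, method, exposure_ids, beta, se, n_snps, **kw) -> "MVMREstimate":
        beta = np.asarray(beta, float)
        se = np.asarray(se, float)
        pval = np.clip(2 * stats.norm.sf(np.abs(beta) / se), np.nextafter(0, 1), 1.0)
        return cls(
            method=method,
            exposure_ids=list(exposure_ids),
            beta=beta,
            se=se,
            ci_low=beta - Z95 * se,
            ci_high=beta + Z95 * se,
            pval=pval,
            n_snps=int(n_snps),
            **kw,
        )

    def for_exposure(self, exposure_id: str) -> dict:
        j = self.exposure_ids.index(exposure_id)
        return {
            "beta": float(self.beta[j]),
            "se": float(self.se[j]),
            "ci_low": float(self.ci_low[j]),
            "ci_high": float(self.ci_high[j]),
            "pval": float(self.pval[j]),
        }


def harmonize_multi(
    instrument_sets: Sequence[InstrumentSet],
    exposure_tables: Sequence[SumStatTable],
    outcome: SumStatTable,
    palindrome_policy: str = "infer_by_eaf",
    maf_limit: float = DEFAULT_MAF_LIMIT,
) -> MVMRDataset:
    """Build the joint instrument × exposure effect matrix for MVMR.

    The instrument set is the union of the per-exposure instruments; every
    exposure table and the outcome must report each retained variant, aligned
    to the orientation of the first exposure table that carries it.  Variants
    missing from any table, or unharmonizable, are dropped with a logged count.
    """
    exposure_ids = [t.trait_id for t in exposure_tables]
    union: list[str] = []
    seen: set[str] = set()
    for iset in instrument_sets:
        for v in iset.variant_ids:
            if v not in seen:
                union.append(v)
                seen.add(v)

    indexed = [t.records.set_index("variant_id") for t in exposure_tables]
    out_idx = outcome.records.set_index("variant_id")

    rows_bx, rows_sx, rows_by, rows_sy, kept_ids = [], [], [], [], []
    n_missing = n_dropped = 0
    for v in union:
        tables_with_v = [t for t in indexed if v in t.index]
        if len(tables_with_v) < len(indexed) or v not in out_idx.index:
            n_missing += 1
            continue
        ref = tables_with_v[0].loc[v]
        ref_ea, ref_oa = ref["effect_allele"], ref["other_allele"]
        ref_eaf = ref["eaf"] if pd.notna(ref["eaf"]) else None
        bx, sx = [], []
        ok = True
        for t in indexed:
            r = t.loc[v]
            sign, _ = align_alleles(
                ref_ea, ref_oa, r["effect_allele"], r["other_allele"],
                ref_eaf, r["eaf"] if pd.notna(r["eaf"]) else None,
                palindrome_policy, maf_limit,
            )
            if sign == 0:
                ok = False
                break
            bx.append(sign * float(r["beta"]))
            sx.append(float(r["se"]))
        if ok:
            r = out_idx.loc[v]
            sign, _ = align_alleles(
                ref_ea, ref_oa, r["effect_allele"], r["other_allele"],
                ref_eaf, r["eaf"] if pd.notna(r["eaf"]) else None,
                palindrome_policy, maf_limit,
            )
            ok = sign != 0
            if ok:
                rows_by.append(sign * float(r["beta"]))
                rows_sy.append(float(r["se"]))
        if not ok:
            n_dropped += 1
            continue
        rows_bx.append(bx)
        rows_sx.append(sx)
        kept_ids.append(v)

    if n_missing or n_dropped:
        logger.info(
            "MVMR alignment: %d variants missing from a table, %d unharmonizable, %d kept",
            n_missing, n_dropped, len(kept_ids),
        )
    if len(kept_ids) <= len(exposure_ids):
        raise ValueError(
            f"only {len(kept_ids)} aligned instruments for {len(exposure_ids)} exposures"
        )
    return MVMRDataset(
        outcome_id=outcome.trait_id,
        exposure_ids=exposure_ids,
        variant_ids=kept_ids,
        beta_x=np.array(rows_bx, float),
        se_x=np.array(rows_sx, float),
        beta_y=np.array(rows_by, float),
        se_y=np.array(rows_sy, float),
    )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int, exposure_ids=None):
    """Weighted LS with multiplicative overdispersion sqrt(max(1, RSS_w/df))."""
    Xw = X * np.sqrt(w)[:, None]
    cond = np.linalg.cond(Xw)
    if cond > CONDITION_LIMIT:
        raise ValueError(
            f"exposure effect columns are collinear (condition number {cond:.2e})"
            + (f": {exposure_ids}" if exposure_ids else "")
        )
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / df_resid) if df_resid > 0 else 1.0
    cov = phi * np.linalg.inv(xtwx)
    return coef, np.sqrt(np.diag(cov)), rss_w


def mv_ivw(d: MVMRDataset) -> MVMREstimate:
    """Multivariable IVW: WLS of β_y on the exposure-effect columns, no intercept."""
    w = d.se_y**-2.0
    coef, se, _ = _wls(d.beta_x, d.beta_y, w, d.k - d.m, d.exposure_ids)
    return MVMREstimate.from_beta_se("mv_ivw", d.exposure_ids, coef, se, d.k)


def mv_egger(d: MVMRDataset) -> MVMREstimate:
    """MVMR-Egger: adds an intercept, rows oriented so the first exposure's β > 0."""
    if d.k <= d.m + 1:
        raise ValueError(f"MVMR-Egger needs k > m+1 (k={d.k}, m={d.m})")
    flip = np.sign(d.beta_x[:, 0])
    flip[flip == 0] = 1.0
    bx = d.beta_x * flip[:, None]
    by = d.beta_y * flip
    w = d.se_y**-2.0
    X = np.column_stack([np.ones(d.k), bx])
    coef, se, _ = _wls(X, by, w, d.k - d.m - 1, d.exposure_ids)
    p_int = float(np.clip(2 * stats.norm.sf(abs(coef[0]) / se[0]), np.nextafter(0, 1), 1.0))
    return MVMREstimate.from_beta_se(
        "mv_egger",
        d.exposure_ids,
        coef[1:],
        se[1:],
        d.k,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=p_int,
    )


def _weighted_lad(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Exact weighted least-absolute-deviations fit through the origin (LP).

    minimize Σ_j w_j |y_j − X_j b| via the standard split u−v formulation,
    solved with the HiGHS simplex for determinism.
    """
    k, m = X.shape
    # variables: b (m, free), u (k, ≥0), v (k, ≥0); X b + u − v = y
    c = np.concatenate([np.zeros(m), w, w])
    A_eq = np.hstack([X, np.eye(k), -np.eye(k)])
    bounds = [(None, None)] * m + [(0, None)] * (2 * k)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"weighted LAD regression failed to converge: {res.message}")
    return res.x[:m]


def mv_median(d: MVMRDataset, n_boot: int = 1000, seed: int = 0) -> MVMREstimate:
    """MVMR-median: weighted L1 (median) regression through the origin.

    Robust to a minority of outlying instruments; SEs come from a seeded
    parametric bootstrap resampling (β_x, β_y) from their reported errors.
    """
    if d.k <= d.m + 2:
        raise ValueError(f"MVMR-median needs k > m+2 (k={d.k}, m={d.m})")
    w = d.se_y**-2.0
    coef = _weighted_lad(d.beta_x, d.beta_y, w)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, d.m))
    for i in range(n_boot):
        bxs = rng.normal(d.beta_x, d.se_x)
        bys = rng.normal(d.beta_y, d.se_y)
        boots[i] = _weighted_lad(bxs, bys, w)
    se = np.std(boots, axis=0, ddof=1)
    return MVMREstimate.from_beta_se("mv_median", d.exposure_ids, coef, se, d.k)


def _lasso_path_fit(bx, by, w, lam, sy, n_iter=500, tol=1e-10):
    """Alternating minimizer of the per-variant-intercept lasso objective.

    The soft-threshold acts on the residual in units of the variant's
    standard error, so λ is a dimensionless z-score-like cutoff: an
    instrument receives a nonzero pleiotropy intercept only when its
    standardized residual exceeds λ.
    """
    k, m = bx.shape
    alpha = np.zeros(k)
    coef = np.zeros(m)
    for _ in range(n_iter):
        xtwx = bx.T @ (w[:, None] * bx)
        coef_new = np.linalg.solve(xtwx, bx.T @ (w * (by - alpha)))
        r = by - bx @ coef_new
        thresh = lam * sy
        alpha_new = np.sign(r) * np.maximum(0.0, np.abs(r) - thresh)
        if np.max(np.abs(coef_new - coef)) < tol and np.max(np.abs(alpha_new - alpha)) < tol:
            coef, alpha = coef_new, alpha_new
            break
        coef, alpha = coef_new, alpha_new
    return coef, alpha


def mv_lasso(
    d: MVMRDataset,
    lambda_grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> MVMREstimate:
    """MVMR-Lasso: per-variant pleiotropy intercepts with an L1 penalty.

    Each instrument gets a free intercept shrunk by λ; instruments whose
    intercept is driven to zero form the valid set.  λ is chosen by the
    heterogeneity stopping rule: scanning from the largest λ downward, the
    first (i.e. least-exclusionary) λ whose valid-set heterogeneity Q falls
    below the χ²₀.₉₅ critical value is selected.  The reported estimate is
    MV-IVW restricted to that valid set.
    """
    if d.k <= d.m + 1:
        raise ValueError(f"MVMR-Lasso needs k > m+1 (k={d.k}, m={d.m})")
    if lambda_grid is None:
        lambda_grid = np.geomspace(1e-3, 10.0, 50)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    w = d.se_y**-2.0

    chosen = None
    for lam in lambda_grid:
        _, alpha = _lasso_path_fit(d.beta_x, d.beta_y, w, lam, d.se_y)
        valid = np.flatnonzero(np.abs(alpha) < 1e-12)
        if len(valid) <= d.m:
            continue
        sub = d.subset(valid)
        coef, _, rss_w = _wls(sub.beta_x, sub.beta_y, sub.se_y**-2.0, sub.k - sub.m)
        df = sub.k - sub.m
        if rss_w < stats.chi2.ppf(0.95, df):
            chosen = (lam, valid)
            break
    if chosen is None:
        raise ValueError("no λ in the grid yields a valid set larger than m that passes the heterogeneity rule")
    lam, valid = chosen
    sub = d.subset(valid)
    est = mv_ivw(sub)
    return MVMREstimate.from_beta_se(
        "mv_lasso",
        d.exposure_ids,
        est.beta,
        est.se,
        sub.k,
        selected_valid_set=[d.variant_ids[i] for i in valid],
    )
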