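"""Orchestration of the full MR mediation workflow.

The study design this package implements runs, per exposure: instrument
selection → harmonization → MR-PRESSO outlier gate (with one restart after
removing outliers) → the IVW / Egger / weighted-median battery plus the
heterogeneity and pleiotropy diagnostics; classifies exposures against a
Bonferroni-adjusted primary threshold; checks the reverse direction; and
screens a battery of candidate mediators by two-step MR, reporting
Delta-method mediation proportions ranked in descending order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import instruments as instr
from .harmonize import harmonize_pair
from .mediation import ScreenCriteria, screen_mediators
from .sensitivity import cochran_q, leave_one_out, mr_presso
from .sumstats import SumStatTable, read_blacklist, read_ld_matrix, read_sumstats
from .uvmr import estimate_all, ivw

logger = logging.getLogger("mrmediate.pipeline")

NOT_ESTIMABLE = "not_estimable"


@dataclass
class PipelineConfig:
    """All thresholds and estimator settings for one study run."""

    # instrument selection
    p_instrument: float = instr.GENOME_WIDE_P
    p_instrument_reverse: float = instr.GENOME_WIDE_P
    r2_threshold: float = instr.DEFAULT_R2
    window_kb: int = instr.DEFAULT_WINDOW_KB
    min_f: float = instr.DEFAULT_MIN_F
    # significance
    alpha: float = 0.05
    alpha_mediator: float = 0.05
    mediator_correction: str = "nominal"  # nominal | bonferroni
    # estimators
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    n_sim: int = 1000
    palindrome_policy: str = "infer_by_eaf"
    maf_limit: float = 0.42
    seed: int = 0
    # optional input paths (the library API also accepts in-memory tables)
    exposure_paths: dict = field(default_factory=dict)
    mediator_paths: dict = field(default_factory=dict)
    outcome_path: Optional[str] = None
    ld_path: Optional[str] = None
    ld_sidecar_path: Optional[str] = None
    blacklist_path: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("p_instrument", "p_instrument_reverse", "alpha", "alpha_mediator"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.window_kb < 0 or self.min_f < 0:
            raise ValueError("window_kb and min_f must be non-negative")
        if self.ivw_mode not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown ivw_mode {self.ivw_mode!r}")
        if self.mediator_correction not in ("nominal", "bonferroni"):
            raise ValueError(f"unknown mediator_correction {self.mediator_correction!r}")
        if self.seed is None:
            raise ValueError("seed must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class StudyReport:
    """All result tables of one run, reproducible from the echoed config."""

    uvmr_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    reverse_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    sensitivity_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    mediation_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("uvmr_table", "reverse_table", "sensitivity_table", "mediation_table"):
            df = getattr(self, name)
            if len(df):
                df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, na_rep="NA", float_format="%.10g")
        (outdir / "config.json").write_text(json.dumps(self.config, indent=2, default=str))
        (outdir / "run.log").write_text("\n".join(str(x) for x in self.log) + "\n")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """The family-wise threshold alpha/n_tests, unrounded.

    Reports may display it rounded (e.g. 0.05/14 shown as 0.003); comparisons
    always use the exact value.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    return alpha / n_tests


def _classify(p_ivw: float, alpha_primary: float, alpha: float) -> str:
    if p_ivw < alpha_primary:
        return "significant"
    if p_ivw < alpha:
        return "suggestive"
    return "null"


def _analyze_pair(
    exposure: SumStatTable,
    outcome: SumStatTable,
    cfg: PipelineConfig,
    ld,
    blacklist,
    p_threshold: float,
) -> tuple[list[dict], Optional[dict], list[str]]:
    """Instrument → harmonize → PRESSO gate → estimator battery for one pair.

    Returns (uvmr rows, sensitivity row or None, log lines).
    """
    log: list[str] = []
    iset = instr.select_instruments(
        exposure,
        ld=ld,
        blacklist=blacklist,
        p_threshold=p_threshold,
        r2_threshold=cfg.r2_threshold,
        window_kb=cfg.window_kb,
        min_f=cfg.min_f,
    )
    log.append(f"{exposure.trait_id}: {iset.n_variants} instruments after selection")
    base = {"exposure": exposure.trait_id, "outcome": outcome.trait_id}
    if iset.n_variants < 2:
        return [dict(base, method=NOT_ESTIMABLE, n_snps=iset.n_variants)], None, log

    h = harmonize_pair(iset, outcome, cfg.palindrome_policy, cfg.maf_limit)
    log.append(f"{exposure.trait_id}: {h.k} instruments after harmonization")
    if h.k < 2:
        return [dict(base, method=NOT_ESTIMABLE, n_snps=h.k)], None, log

    presso = None
    if h.k >= 4:
        presso = mr_presso(h, n_sim=cfg.n_sim, alpha=cfg.alpha, seed=cfg.seed)
        if presso.outlier_indices and h.k - len(presso.outlier_indices) >= 2:
            log.append(
                f"{exposure.trait_id}: MR-PRESSO outliers {presso.outlier_indices}; analysis restarted without them"
            )
            h = h.drop_variants(presso.outlier_indices)

    rows = []
    for est in estimate_all(h, cfg.ivw_mode, n_boot=cfg.n_boot, seed=cfg.seed):
        rows.append(
            dict(
                base,
                method=est.method,
                n_snps=est.n_snps,
                beta=est.beta,
                se=est.se,
                odds_ratio=est.odds_ratio,
                or_ci_low=est.or_ci_low,
                or_ci_high=est.or_ci_high,
                pval=est.pval,
            )
        )

    sens = dict(base, n_snps=h.k)
    het = cochran_q(h)
    sens.update(q=het.q, i2=het.i2, p_q=het.p_q)
    if h.k >= 3:
        from .uvmr import egger as _egger

        fit = _egger(h)
        sens.update(egger_intercept=fit.intercept, egger_intercept_p=fit.intercept_p)
        loo = leave_one_out(h, cfg.ivw_mode)
        sens.update(loo_flagged=int(loo["flagged"].sum()))
    if presso is not None:
        sens.update(presso_global_p=presso.global_p, presso_n_outliers=len(presso.outlier_indices))
    return rows, sens, log


def run_uvmr_screen(
    exposures: Sequence[SumStatTable],
    outcome: SumStatTable,
    cfg: PipelineConfig,
    ld=None,
    blacklist=(),
) -> StudyReport:
    """Univariable screen of every exposure against the outcome.

    Each exposure is classified ``significant`` (IVW p below the Bonferroni
    threshold alpha/n_exposures), ``suggestive`` (below alpha) or ``null``.
    """
    if not exposures:
        raise ValueError("at least one exposure table is required")
    alpha_primary = bonferroni_threshold(cfg.alpha, len(exposures))
    report = StudyReport(config=asdict(cfg))
    report.log.append(f"primary significance threshold {alpha_primary:.6g} ({cfg.alpha}/{len(exposures)})")

    uvmr_rows, sens_rows = [], []
    for exposure in exposures:
        rows, sens, log = _analyze_pair(exposure, outcome, cfg, ld, blacklist, cfg.p_instrument)
        report.log.extend(log)
        for r in rows:
            if r["method"].startswith("ivw"):
                r["classification"] = _classify(r["pval"], alpha_primary, cfg.alpha)
            elif r["method"] == NOT_ESTIMABLE:
                r["classification"] = NOT_ESTIMABLE
        uvmr_rows.extend(rows)
        if sens is not None:
            sens_rows.append(sens)
    report.uvmr_table = pd.DataFrame(uvmr_rows)
    report.sensitivity_table = pd.DataFrame(sens_rows)
    return report


def run_bidirectional(
    exposures: Sequence[SumStatTable],
    outcome: SumStatTable,
    cfg: PipelineConfig,
    ld=None,
    blacklist=(),
) -> StudyReport:
    """Reverse MR: the outcome's instruments against each original exposure."""
    report = StudyReport(config=asdict(cfg))
    rows = []
    for exposure in exposures:
        r, _, log = _analyze_pair(exposure=outcome, outcome=exposure, cfg=cfg, ld=ld, blacklist=blacklist, p_threshold=cfg.p_instrument_reverse)
        report.log.extend(log)
        rows.extend(r)
    report.reverse_table = pd.DataFrame(rows)
    return report


def run_mediation_pipeline(
    exposures: Sequence[SumStatTable],
    outcome: SumStatTable,
    mediators: Sequence[SumStatTable],
    cfg: PipelineConfig,
    ld=None,
    blacklist=(),
) -> StudyReport:
    """The full workflow: UVMR screen → reverse check → two-step mediator scan.

    Mediators are screened for every exposure classified significant; the
    mediation table is ranked by descending mediation proportion.
    """
    report = run_uvmr_screen(exposures, outcome, cfg, ld, blacklist)
    reverse = run_bidirectional(exposures, outcome, cfg, ld, blacklist)
    report.reverse_table = reverse.reverse_table
    report.log.extend(reverse.log)

    uvmr = report.uvmr_table
    significant_ids = set(
        uvmr.loc[
            uvmr["method"].str.startswith("ivw") & (uvmr.get("classification") == "significant"),
            "exposure",
        ]
    )
    report.log.append(f"significant exposures: {sorted(significant_ids) or 'none'}")

    alpha_med = cfg.alpha_mediator
    if cfg.mediator_correction == "bonferroni" and mediators:
        alpha_med = cfg.alpha_mediator / len(mediators)
    criteria = ScreenCriteria(alpha_mediator=alpha_med)

    med_rows = []
    for exposure in exposures:
        if exposure.trait_id not in significant_ids:
            continue
        results = screen_mediators(
            exposure,
            outcome,
            mediators,
            criteria,
            ld=ld,
            blacklist=blacklist,
            p_threshold=cfg.p_instrument,
            r2_threshold=cfg.r2_threshold,
            window_kb=cfg.window_kb,
            min_f=cfg.min_f,
            palindrome_policy=cfg.palindrome_policy,
            ivw_mode=cfg.ivw_mode,
        )
        for res in results:
            med_rows.append(
                {
                    "exposure": res.exposure_id,
                    "mediator": res.mediator_id,
                    "outcome": res.outcome_id,
                    "a": res.a,
                    "se_a": res.se_a,
                    "p_a": res.p_a,
                    "b": res.b,
                    "se_b": res.se_b,
                    "p_b": res.p_b,
                    "c": res.c,
                    "se_c": res.se_c,
                    "indirect": res.indirect,
                    "proportion_pct": None if res.proportion is None else 100 * res.proportion,
                    "ci_low_pct": None if res.ci_low is None else 100 * res.ci_low,
                    "ci_high_pct": None if res.ci_high is None else 100 * res.ci_high,
                    "gates_passed": ";".join(g for g, ok in res.screen_flags.items() if ok),
                    "passed_all": res.passed,
                }
            )
    med = pd.DataFrame(med_rows)
    if len(med):
        med = med.sort_values(
            "proportion_pct", ascending=False, na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    report.mediation_table = med
    return report


def load_inputs(cfg: PipelineConfig):
    """Read all tables named in the config (paths → in-memory objects)."""
    exposures = [
        read_sumstats(p, trait_id=tid, trait_type="binary") for tid, p in cfg.exposure_paths.items()
    ]
    mediators = [
        read_sumstats(p, trait_id=tid, trait_type="continuous")
        for tid, p in cfg.mediator_paths.items()
    ]
    outcome = (
        read_sumstats(cfg.outcome_path, trait_id="outcome", trait_type="binary")
        if cfg.outcome_path
        else None
    )
    ld = read_ld_matrix(cfg.ld_path, cfg.ld_sidecar_path) if cfg.ld_path else None
    blacklist = read_blacklist(cfg.blacklist_path) if cfg.blacklist_path else ()
    return exposures, mediators, outcome, ld, blacklist
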