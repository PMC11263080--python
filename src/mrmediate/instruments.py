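"""Genetic-instrument selection: significance filter, blacklist, LD clumping, F.

The pipeline applies the filters in a fixed order — genome-wide significance,
confounder blacklist, greedy LD clumping, instrument-strength (F) filter —
because blacklist removal before clumping can promote a different index SNP
per LD region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .sumstats import BlacklistEntry, LDMatrix, SumStatTable

logger = logging.getLogger("mrmediate.instruments")

GENOME_WIDE_P = 5e-8
DEFAULT_R2 = 0.001
DEFAULT_WINDOW_KB = 10_000
DEFAULT_MIN_F = 10.0


@dataclass
class InstrumentSet:
    """A trait's selected instruments with per-variant filter provenance."""

    trait_id: str
    records: pd.DataFrame
    f_stats: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records["variant_id"])

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def _with(self, records: pd.DataFrame, note: str) -> "InstrumentSet":
        prov = {v: list(p) for v, p in self.provenance.items()}
        for v in records["variant_id"]:
            prov.setdefault(v, []).append(note)
        return InstrumentSet(
            trait_id=self.trait_id,
            records=records.reset_index(drop=True),
            f_stats={v: f for v, f in self.f_stats.items() if v in set(records["variant_id"])},
            provenance=prov,
        )


def select_genome_wide(table: SumStatTable, p_threshold: float = GENOME_WIDE_P) -> InstrumentSet:
    """Keep variants with pval strictly below the genome-wide threshold."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    keep = table.records.loc[table.records["pval"] < p_threshold].reset_index(drop=True)
    if len(keep) == 0:
        logger.warning("%s: no variants pass p < %g", table.trait_id, p_threshold)
    prov = {v: [f"pval<{p_threshold:g}"] for v in keep["variant_id"]}
    return InstrumentSet(trait_id=table.trait_id, records=keep, provenance=prov)


def greedy_clump(
    iset: InstrumentSet,
    ld: LDMatrix | None,
    r2_threshold: float = DEFAULT_R2,
    window_kb: int = DEFAULT_WINDOW_KB,
) -> InstrumentSet:
    """Greedy LD clumping: the most significant SNP in each region is kept.

    Variants are visited in ascending p order (ties broken by variant_id);
    each visited variant is kept and every not-yet-kept variant on the same
    chromosome with r² ≥ ``r2_threshold`` and |Δpos| ≤ ``window_kb`` kb is
    removed.  Variants absent from ``ld`` are treated as independent and kept
    with a warning (the reference panel does not cover them).
    """
    df = iset.records
    if len(df) <= 1:
        return iset._with(df, "clump:index")
    order = df.sort_values(["pval", "variant_id"], kind="mergesort")
    pos = dict(zip(df["variant_id"], df["pos"]))
    chrom = dict(zip(df["variant_id"], df["chrom"]))
    window_bp = window_kb * 1000

    missing = [v for v in df["variant_id"] if ld is None or v not in ld]
    if missing and ld is not None:
        logger.warning(
            "%s: %d instruments absent from LD matrix, retained as independent",
            iset.trait_id,
            len(missing),
        )
    missing_set = set(missing)

    kept: list[str] = []
    removed: set[str] = set()
    for v in order["variant_id"]:
        if v in removed:
            continue
        kept.append(v)
        if v in missing_set:
            continue
        for u in order["variant_id"]:
            if u == v or u in removed or u in kept or u in missing_set:
                continue
            if chrom[u] != chrom[v]:
                continue
            if abs(pos[u] - pos[v]) > window_bp:
                continue
            if ld.r2_between(v, u) >= r2_threshold:
                removed.add(u)

    kept_set = set(kept)
    out = df.loc[df["variant_id"].isin(kept_set)].reset_index(drop=True)
    return iset._with(out, f"clump:r2<{r2_threshold:g},window<={window_kb}kb")


def apply_blacklist(iset: InstrumentSet, blacklist: Iterable[BlacklistEntry]) -> InstrumentSet:
    """Remove instruments listed as associated with confounders or the outcome."""
    reasons = {b.variant_id: b.associated_trait for b in blacklist}
    present = set(iset.records["variant_id"])
    absent = [v for v in reasons if v not in present]
    if absent:
        logger.warning("%s: %d blacklist variants not among instruments", iset.trait_id, len(absent))
    hits = present & set(reasons)
    out = iset.records.loc[~iset.records["variant_id"].isin(hits)]
    result = iset._with(out, "blacklist:pass")
    for v in hits:
        result.provenance.setdefault(v, []).append(f"blacklist:removed({reasons[v]})")
    return result


def compute_f_statistics(
    iset: InstrumentSet,
    min_f: float = DEFAULT_MIN_F,
    method: str = "t2",
) -> InstrumentSet:
    """Per-variant instrument strength; variants with F ≤ ``min_f`` are removed.

    ``method="t2"`` uses the squared-t approximation F = (β/se)².  The
    alternative ``"r2"`` uses F = R²(n−2)/(1−R²) with R² = 2·maf(1−maf)·β²,
    available only when eaf and n are present; the two agree closely for the
    small per-SNP R² typical of GWAS instruments.
    """
    df = iset.records
    if method == "t2":
        f = (df["beta"] / df["se"]) ** 2
    elif method == "r2":
        if df["eaf"].isna().any():
            raise ValueError("method='r2' requires eaf for every instrument")
        maf = np.minimum(df["eaf"], 1 - df["eaf"])
        r2 = 2 * maf * (1 - maf) * df["beta"] ** 2
        f = r2 * (df["n"] - 2) / (1 - r2)
    else:
        raise ValueError(f"unknown F method {method!r}")
    f = pd.Series(np.asarray(f, dtype=float), index=df.index)
    keep = f > min_f  # boundary F = min_f is excluded
    out = df.loc[keep]
    result = iset._with(out, f"F>{min_f:g}")
    result.f_stats = dict(zip(out["variant_id"], f.loc[keep]))
    return result


def select_instruments(
    table: SumStatTable,
    ld: LDMatrix | None = None,
    blacklist: Iterable[BlacklistEntry] = (),
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_R2,
    window_kb: int = DEFAULT_WINDOW_KB,
    min_f: float = DEFAULT_MIN_F,
) -> InstrumentSet:
    """Full selection chain in the fixed order significance → blacklist → clump → F."""
    iset = select_genome_wide(table, p_threshold)
    iset = apply_blacklist(iset, blacklist)
    iset = greedy_clump(iset, ld, r2_threshold, window_kb)
    return compute_f_statistics(iset, min_f)
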