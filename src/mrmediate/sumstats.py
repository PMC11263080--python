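"""Readers, writers and validation for GWAS summary-statistic tables.

The canonical table layout is one row per variant with columns
``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
``beta`` is on the log-odds scale for binary traits and in standardized units
for continuous traits; ``eaf`` is the effect-allele frequency and may be
missing (serialized as ``NA``).  Auxiliary inputs — a dense LD (r²) matrix
with a chrom/pos sidecar, and a confounder blacklist — use plain TSV as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrmediate.sumstats")

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

VALID_ALLELES = frozenset("ACGT")

#: p-values of exactly zero (underflowed exports) are clamped to this value.
PVAL_FLOOR = 1e-300


@dataclass
class SumStatTable:
    """Per-variant GWAS association records for one trait.

    ``records`` is a DataFrame with the canonical columns; ``variant_id`` is
    unique within a table.  ``trait_type`` distinguishes the log-odds scale
    (binary) from standardized units (continuous).
    """

    trait_id: str
    trait_type: str  # "binary" | "continuous"
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary/continuous, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing canonical columns: {missing}")
        if self.records["variant_id"].duplicated().any():
            dup = self.records.loc[self.records["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant_id in table {self.trait_id}: {list(dup[:5])}")

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def subset(self, variant_ids: Sequence[str]) -> pd.DataFrame:
        """Rows for the given variants, in the given order (missing → absent)."""
        idx = self.records.set_index("variant_id")
        present = [v for v in variant_ids if v in idx.index]
        return idx.loc[present].reset_index()


@dataclass
class LDMatrix:
    """Dense matrix of squared correlations (r²) between variants."""

    variant_ids: list[str]
    r2: np.ndarray
    chrom: dict[str, str] = field(default_factory=dict)
    pos: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {self.r2.shape}")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("r2 values must lie in [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric (tolerance 1e-8)")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


@dataclass(frozen=True)
class BlacklistEntry:
    """A variant excluded because of association with a confounder or the outcome."""

    variant_id: str
    associated_trait: str


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    trait_id: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
) -> SumStatTable:
    """Load a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    column_map
        Mapping from canonical column names to the file's column names, for
        non-canonical dialects (e.g. ``{"variant_id": "SNP", "beta": "b"}``).
        Unmapped canonical names are looked up verbatim.

    Rows violating the record invariants (se > 0, pval in (0, 1], alleles in
    {A,C,G,T} and distinct, pos ≥ 1, n ≥ 1, eaf missing or in [0,1]) are
    dropped with a logged count.  p-values of exactly 0 are clamped to 1e-300.
    A missing mandatory column or zero surviving rows is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", "NaN", ""], keep_default_na=False)

    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src not in raw.columns:
            raise ValueError(f"mandatory column {canonical!r} (file column {src!r}) not found in {path}")
        rename[src] = canonical
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()

    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval", "n", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    n_clamped = int((df["pval"] == 0).sum())
    if n_clamped:
        logger.warning("%s: %d p-values of exactly 0 clamped to %g", trait_id, n_clamped, PVAL_FLOOR)
        df.loc[df["pval"] == 0, "pval"] = PVAL_FLOOR

    ok = (
        df["variant_id"].notna()
        & df["pos"].notna()
        & (df["pos"] >= 1)
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["beta"].notna()
        & df["se"].notna()
        & (df["se"] > 0)
        & df["pval"].notna()
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & df["n"].notna()
        & (df["n"] >= 1)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows of %d", trait_id, n_dropped, len(df))
    df = df.loc[ok].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"{path}: zero valid rows after validation")

    dup = df["variant_id"].duplicated()
    if dup.any():
        logger.warning("%s: %d duplicate variant ids, keeping first occurrence", trait_id, int(dup.sum()))
        df = df.loc[~dup].reset_index(drop=True)

    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(float)
    return SumStatTable(trait_id=trait_id, trait_type=trait_type, records=df)


def write_sumstats(table: SumStatTable, path: str | Path) -> None:
    """Write a table in the canonical tab-delimited dialect (missing eaf → NA)."""
    if table.n_variants == 0:
        raise ValueError("refusing to write a table with zero records")
    out = table.records[CANONICAL_COLUMNS].copy()
    # 12 significant digits keeps the write→read round trip lossless in practice
    for col in ("eaf", "beta", "se", "pval", "n"):
        out[col] = out[col].map(lambda x: "NA" if pd.isna(x) else f"{x:.12g}")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_matrix(path: str | Path, sidecar: str | Path | None = None) -> LDMatrix:
    """Load a dense r² matrix (TSV, variant-ID header row and column).

    ``sidecar`` is an optional TSV with columns ``variant_id, chrom, pos``;
    without it the matrix is usable but window-aware clumping falls back to
    positions supplied by the instrument set.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"LD matrix must be square, got {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError("LD matrix row and column variant IDs disagree")
    ids = [str(v) for v in df.index]
    chrom: dict[str, str] = {}
    pos: dict[str, int] = {}
    if sidecar is not None:
        side = pd.read_csv(sidecar, sep="\t", dtype={"variant_id": str, "chrom": str})
        for col in ("variant_id", "chrom", "pos"):
            if col not in side.columns:
                raise ValueError(f"LD sidecar missing column {col!r}")
        chrom = dict(zip(side["variant_id"], side["chrom"]))
        pos = {v: int(p) for v, p in zip(side["variant_id"], side["pos"])}
    return LDMatrix(variant_ids=ids, r2=df.to_numpy(dtype=float), chrom=chrom, pos=pos)


def write_ld_matrix(ld: LDMatrix, path: str | Path, sidecar: str | Path | None = None) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")
    if sidecar is not None:
        pd.DataFrame(
            {
                "variant_id": ld.variant_ids,
                "chrom": [ld.chrom.get(v, "NA") for v in ld.variant_ids],
                "pos": [ld.pos.get(v, 0) for v in ld.variant_ids],
            }
        ).to_csv(sidecar, sep="\t", index=False)


def read_blacklist(path: str | Path) -> list[BlacklistEntry]:
    """Load a 2-column TSV (variant_id, associated_trait) of excluded variants."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variant_id", "associated_trait"):
        if col not in df.columns:
            raise ValueError(f"blacklist missing column {col!r}")
    return [
        BlacklistEntry(variant_id=v, associated_trait=t)
        for v, t in zip(df["variant_id"], df["associated_trait"])
    ]
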