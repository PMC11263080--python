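"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires every (β_exposure, β_outcome) pair to refer to the
same effect allele.  For each shared variant the outcome record is aligned
to the exposure's orientation, handling swapped alleles (sign flip), strand
flips (complementary alleles) and palindromic A/T and G/C variants, whose
strand cannot be resolved from alleles alone and is either inferred from
allele frequency or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import InstrumentSet
from .sumstats import SumStatTable

logger = logging.getLogger("mrmediate.harmonize")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_MAF_LIMIT = 0.42

KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"


@dataclass
class HarmonizedSet:
    """Instrument-level aligned effect pairs ready for estimation.

    ``data`` has one row per *retained* variant (columns variant_id, beta_x,
    se_x, beta_y, se_y, eaf_x, eaf_y); ``action_log`` covers every shared
    variant, retained or dropped.
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    action_log: dict[str, str]

    @property
    def k(self) -> int:
        return len(self.data)

    @property
    def beta_x(self) -> np.ndarray:
        return self.data["beta_x"].to_numpy(dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return self.data["se_x"].to_numpy(dtype=float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.data["beta_y"].to_numpy(dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return self.data["se_y"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data["variant_id"])

    def drop_variants(self, variant_ids) -> "HarmonizedSet":
        """A copy with the given variants removed (used after outlier detection)."""
        drop = set(variant_ids)
        data = self.data.loc[~self.data["variant_id"].isin(drop)].reset_index(drop=True)
        log = dict(self.action_log)
        for v in drop:
            log[v] = "removed_outlier"
        return HarmonizedSet(self.exposure_id, self.outcome_id, data, log)


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def align_alleles(
    ref_ea: str,
    ref_oa: str,
    ea: str,
    oa: str,
    eaf_ref: float | None,
    eaf: float | None,
    palindrome_policy: str = "infer_by_eaf",
    maf_limit: float = DEFAULT_MAF_LIMIT,
) -> tuple[int, str]:
    """Orient one record's alleles onto a reference orientation.

    Returns ``(sign, action)`` where ``sign`` is +1 (keep), −1 (negate beta and
    complement eaf) or 0 (drop), and ``action`` is the audit label.
    """
    if is_palindromic(ref_ea, ref_oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return 0, DROPPED_INCOMPATIBLE
        if palindrome_policy == "drop_all":
            return 0, DROPPED_PALINDROMIC
        if palindrome_policy != "infer_by_eaf":
            raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
        if eaf_ref is None or eaf is None or np.isnan(eaf_ref) or np.isnan(eaf):
            return 0, DROPPED_PALINDROMIC  # frequency unavailable, cannot infer strand
        sign = 1 if ea == ref_ea else -1
        eaf_aligned = eaf if sign == 1 else 1 - eaf
        same_side = (eaf_ref - 0.5) * (eaf_aligned - 0.5) > 0
        informative = min(eaf_ref, 1 - eaf_ref) < maf_limit and min(eaf_aligned, 1 - eaf_aligned) < maf_limit
        if same_side and informative:
            return sign, KEPT if sign == 1 else FLIPPED
        return 0, DROPPED_PALINDROMIC

    if (ea, oa) == (ref_ea, ref_oa):
        return 1, KEPT
    if (ea, oa) == (ref_oa, ref_ea):
        return -1, FLIPPED
    # strand flip: the record's alleles are the complements of the reference's
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return 1, KEPT
    if (cea, coa) == (ref_oa, ref_ea):
        return -1, FLIPPED
    return 0, DROPPED_INCOMPATIBLE


def harmonize_pair(
    exposure: InstrumentSet,
    outcome: SumStatTable,
    palindrome_policy: str = "infer_by_eaf",
    maf_limit: float = DEFAULT_MAF_LIMIT,
) -> HarmonizedSet:
    """Align outcome records to the exposure instruments' effect alleles.

    ``palindrome_policy`` is ``"drop_all"`` or ``"infer_by_eaf"`` (keep a
    palindromic variant only when both allele frequencies fall on the same
    side of 0.5 and are informative, i.e. MAF < ``maf_limit``).
    """
    exp = exposure.records.set_index("variant_id")
    out = outcome.records.set_index("variant_id")
    shared = [v for v in exp.index if v in out.index]
    if not shared:
        raise ValueError(
            f"no shared instruments between {exposure.trait_id} and {outcome.trait_id}"
        )

    rows = []
    action_log: dict[str, str] = {}
    for v in shared:
        e = exp.loc[v]
        o = out.loc[v]
        sign, action = align_alleles(
            e["effect_allele"],
            e["other_allele"],
            o["effect_allele"],
            o["other_allele"],
            e["eaf"] if pd.notna(e["eaf"]) else None,
            o["eaf"] if pd.notna(o["eaf"]) else None,
            palindrome_policy,
            maf_limit,
        )
        action_log[v] = action
        if sign == 0:
            continue
        eaf_y = o["eaf"]
        if sign == -1 and pd.notna(eaf_y):
            eaf_y = 1 - eaf_y
        rows.append(
            {
                "variant_id": v,
                "beta_x": float(e["beta"]),
                "se_x": float(e["se"]),
                "beta_y": sign * float(o["beta"]),
                "se_y": float(o["se"]),
                "eaf_x": float(e["eaf"]) if pd.notna(e["eaf"]) else np.nan,
                "eaf_y": float(eaf_y) if pd.notna(eaf_y) else np.nan,
            }
        )

    n_dropped = sum(a.startswith("dropped") for a in action_log.values())
    if n_dropped:
        logger.info(
            "%s vs %s: %d of %d shared variants dropped during harmonization",
            exposure.trait_id,
            outcome.trait_id,
            n_dropped,
            len(shared),
        )
    data = pd.DataFrame(rows, columns=["variant_id", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"])
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        data=data,
        action_log=action_log,
    )


def write_harmonized(h: HarmonizedSet, path) -> None:
    """Serialize the harmonized set (retained and dropped variants) for audit."""
    data = h.data.set_index("variant_id")
    rows = []
    for v, action in h.action_log.items():
        row = {"variant_id": v, "action": action}
        if v in data.index:
            row.update(data.loc[v].to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
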