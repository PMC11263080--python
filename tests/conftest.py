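import numpy as np
import pandas as pd
import pytest

from mrmediate.harmonize import HarmonizedSet
from mrmediate.sumstats import SumStatTable


def make_hset(beta_x, beta_y, se_y, se_x=None, ids=None, exposure="X", outcome="Y"):
    """Build a HarmonizedSet directly from effect arrays."""
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    se_x = np.full_like(beta_x, 1e-3) if se_x is None else np.asarray(se_x, float)
    k = len(beta_x)
    ids = ids or [f"rs{i + 1}" for i in range(k)]
    data = pd.DataFrame(
        {
            "variant_id": ids,
            "beta_x": beta_x,
            "se_x": se_x,
            "beta_y": beta_y,
            "se_y": se_y,
            "eaf_x": np.nan,
            "eaf_y": np.nan,
        }
    )
    return HarmonizedSet(exposure, outcome, data, {v: "kept" for v in ids})


def make_table(
    trait_id,
    variant_ids,
    beta,
    se,
    pval=None,
    pos=None,
    chrom=None,
    effect_allele=None,
    other_allele=None,
    eaf=None,
    n=10000,
    trait_type="binary",
):
    """Build a SumStatTable from arrays with sensible defaults."""
    from scipy import stats

    k = len(variant_ids)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pval is None:
        pval = np.clip(2 * stats.norm.sf(np.abs(beta) / se), 1e-300, 1.0)
    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom if chrom is not None else ["1"] * k,
            "pos": pos if pos is not None else (np.arange(k) + 1) * 1000,
            "effect_allele": effect_allele if effect_allele is not None else ["A"] * k,
            "other_allele": other_allele if other_allele is not None else ["G"] * k,
            "eaf": eaf if eaf is not None else [0.3] * k,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(n),
        }
    )
    return SumStatTable(trait_id=trait_id, trait_type=trait_type, records=df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
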