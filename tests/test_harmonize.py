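"""Allele harmonization: flips, strand flips, palindromes, audit conservation."""

import numpy as np
import pytest

from mrmediate.harmonize import (
    DROPPED_INCOMPATIBLE,
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
    harmonize_pair,
)
from mrmediate.instruments import select_genome_wide
from mrmediate.uvmr import ivw

from conftest import make_table


def _iset(table, p=1e-5):
    return select_genome_wide(table, p)


def test_swapped_orientation_negates_outcome_beta():
    exp = make_table("X", ["rs1"], [0.1], [0.01], pval=[1e-10], effect_allele=["A"], other_allele=["G"])
    out = make_table("Y", ["rs1"], [0.05], [0.01], effect_allele=["G"], other_allele=["A"], eaf=[0.7])
    h = harmonize_pair(_iset(exp), out)
    assert h.action_log["rs1"] == FLIPPED
    assert h.beta_y[0] == pytest.approx(-0.05)
    assert h.data.loc[0, "eaf_y"] == pytest.approx(0.3)


def test_strand_flip_aligned_without_sign_change():
    exp = make_table("X", ["rs1"], [0.1], [0.01], pval=[1e-10], effect_allele=["A"], other_allele=["G"])
    out = make_table("Y", ["rs1"], [0.05], [0.01], effect_allele=["T"], other_allele=["C"])
    h = harmonize_pair(_iset(exp), out)
    assert h.action_log["rs1"] == KEPT
    assert h.beta_y[0] == pytest.approx(0.05)


def test_strand_flip_with_swap_negates():
    exp = make_table("X", ["rs1"], [0.1], [0.01], pval=[1e-10], effect_allele=["A"], other_allele=["G"])
    out = make_table("Y", ["rs1"], [0.05], [0.01], effect_allele=["C"], other_allele=["T"])
    h = harmonize_pair(_iset(exp), out)
    assert h.action_log["rs1"] == FLIPPED
    assert h.beta_y[0] == pytest.approx(-0.05)


@pytest.mark.parametrize(
    "eaf_x,eaf_y,expect_kept",
    [
        (0.50, 0.50, False),  # ambiguous frequency exactly at 0.5
        (0.20, 0.25, True),  # same side, informative
        (0.20, 0.80, False),  # opposite sides
        (0.45, 0.44, False),  # same side but MAF ≥ limit: uninformative
    ],
)
def test_palindromic_inference_by_eaf(eaf_x, eaf_y, expect_kept):
    exp = make_table("X", ["rs1"], [0.1], [0.01], pval=[1e-10], effect_allele=["A"], other_allele=["T"], eaf=[eaf_x])
    out = make_table("Y", ["rs1"], [0.05], [0.01], effect_allele=["A"], other_allele=["T"], eaf=[eaf_y])
    h = harmonize_pair(_iset(exp), out, palindrome_policy="infer_by_eaf", maf_limit=0.42)
    if expect_kept:
        assert h.action_log["rs1"] == KEPT and h.k == 1
    else:
        assert h.action_log["rs1"] == DROPPED_PALINDROMIC and h.k == 0


def test_palindromic_drop_all_policy_and_missing_eaf():
    exp = make_table("X", ["rs1"], [0.1], [0.01], pval=[1e-10], effect_allele=["G"], other_allele=["C"], eaf=[0.2])
    out = make_table("Y", ["rs1"], [0.05], [0.01], effect_allele=["G"], other_allele=["C"], eaf=[0.2])
    assert harmonize_pair(_iset(exp), out, palindrome_policy="drop_all").k == 0
    out_noeaf = make_table("Y", ["rs1"], [0.05], [0.01], effect_allele=["G"], other_allele=["C"], eaf=[np.nan])
    assert harmonize_pair(_iset(exp), out_noeaf, palindrome_policy="infer_by_eaf").k == 0


def test_irreconcilable_alleles_dropped():
    exp = make_table("X", ["rs1"], [0.1], [0.01], pval=[1e-10], effect_allele=["A"], other_allele=["G"])
    out = make_table("Y", ["rs1"], [0.05], [0.01], effect_allele=["A"], other_allele=["C"])
    h = harmonize_pair(_iset(exp), out)
    assert h.action_log["rs1"] == DROPPED_INCOMPATIBLE and h.k == 0


def test_empty_intersection_is_hard_error():
    exp = make_table("X", ["rs1"], [0.1], [0.01], pval=[1e-10])
    out = make_table("Y", ["rs2"], [0.05], [0.01])
    with pytest.raises(ValueError, match="no shared instruments"):
        harmonize_pair(_iset(exp), out)


def test_self_harmonization_is_involution(rng):
    """Harmonizing a table against itself returns beta_y = beta_x for kept variants."""
    k = 20
    ids = [f"rs{i}" for i in range(k)]
    alleles = rng.choice([("A", "G"), ("C", "T"), ("A", "C"), ("A", "T")], size=k)
    t = make_table(
        "X", ids, rng.normal(0, 0.1, k), np.full(k, 0.01), pval=np.full(k, 1e-10),
        effect_allele=[a for a, _ in alleles], other_allele=[b for _, b in alleles],
        eaf=rng.uniform(0.05, 0.45, k),
    )
    h = harmonize_pair(_iset(t), t)
    assert h.k > 0
    np.testing.assert_allclose(h.beta_y, h.beta_x)


def test_action_log_conserves_intersection(rng):
    k = 30
    ids = [f"rs{i}" for i in range(k)]
    alleles = rng.choice([("A", "G"), ("A", "T"), ("G", "C"), ("C", "T")], size=k)
    exp = make_table(
        "X", ids, rng.normal(0, 0.1, k), np.full(k, 0.01), pval=np.full(k, 1e-10),
        effect_allele=[a for a, _ in alleles], other_allele=[b for _, b in alleles],
        eaf=rng.uniform(0.05, 0.6, k),
    )
    swap = rng.random(k) < 0.5
    out = make_table(
        "Y", ids, rng.normal(0, 0.05, k), np.full(k, 0.01),
        effect_allele=[(b if s else a) for (a, b), s in zip(alleles, swap)],
        other_allele=[(a if s else b) for (a, b), s in zip(alleles, swap)],
        eaf=rng.uniform(0.05, 0.6, k),
    )
    h = harmonize_pair(_iset(exp), out)
    assert len(h.action_log) == k
    n_kept = sum(a in (KEPT, FLIPPED) for a in h.action_log.values())
    n_dropped = sum(a.startswith("dropped") for a in h.action_log.values())
    assert n_kept + n_dropped == k
    assert h.k == n_kept


def test_serialized_audit_table_covers_all_shared_variants(tmp_path, rng):
    import pandas as pd

    from mrmediate.harmonize import write_harmonized

    exp = make_table("X", ["rs1", "rs2"], [0.1, 0.2], [0.01, 0.01], pval=[1e-10, 1e-9],
                     effect_allele=["A", "A"], other_allele=["G", "T"], eaf=[0.3, 0.5])
    out = make_table("Y", ["rs1", "rs2"], [0.05, 0.02], [0.01, 0.01],
                     effect_allele=["A", "A"], other_allele=["G", "T"], eaf=[0.3, 0.5])
    h = harmonize_pair(_iset(exp), out)
    path = tmp_path / "harmonized.tsv"
    write_harmonized(h, path)
    audit = pd.read_csv(path, sep="\t")
    assert set(audit["variant_id"]) == {"rs1", "rs2"}
    assert set(audit["action"]) == {"kept", "dropped_palindromic"}


def test_sign_invariance_of_downstream_estimate(rng):
    """Negating exposure betas and swapping its allele columns leaves IVW unchanged."""
    k = 10
    ids = [f"rs{i}" for i in range(k)]
    bx = rng.normal(0, 0.1, k)
    by = 0.3 * bx + rng.normal(0, 0.01, k)
    exp = make_table("X", ids, bx, np.full(k, 0.01), pval=np.full(k, 1e-10),
                     effect_allele=["A"] * k, other_allele=["G"] * k, eaf=[0.3] * k)
    out = make_table("Y", ids, by, np.full(k, 0.01), effect_allele=["A"] * k,
                     other_allele=["G"] * k, eaf=[0.3] * k)
    est = ivw(harmonize_pair(_iset(exp), out))
    exp_flipped = make_table("X", ids, -bx, np.full(k, 0.01), pval=np.full(k, 1e-10),
                             effect_allele=["G"] * k, other_allele=["A"] * k, eaf=[0.7] * k)
    est_flipped = ivw(harmonize_pair(_iset(exp_flipped), out))
    assert est_flipped.beta == pytest.approx(est.beta, abs=1e-12)
    assert est_flipped.se == pytest.approx(est.se, abs=1e-12)
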