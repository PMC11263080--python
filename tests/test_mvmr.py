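"""Multivariable MR: alignment, IVW/Egger oracles, robust median and lasso."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate.instruments import select_genome_wide
from mrmediate.mvmr import (
    MVMRDataset,
    harmonize_multi,
    mv_egger,
    mv_ivw,
    mv_lasso,
    mv_median,
)
from mrmediate.uvmr import ivw

from conftest import make_hset, make_table


def _dataset(bx, by, sy, sx=None, exposure_ids=None):
    bx = np.atleast_2d(np.asarray(bx, float))
    k, m = bx.shape
    return MVMRDataset(
        outcome_id="Y",
        exposure_ids=exposure_ids or [f"X{j + 1}" for j in range(m)],
        variant_ids=[f"rs{i + 1}" for i in range(k)],
        beta_x=bx,
        se_x=np.full((k, m), 1e-3) if sx is None else np.asarray(sx, float),
        beta_y=np.asarray(by, float),
        se_y=np.asarray(sy, float),
    )


EXACT_BX = np.array([[0.1, 0.2], [0.2, 0.1], [0.1, 0.0], [0.3, 0.15], [0.05, 0.25], [0.2, 0.3]])
EXACT_BY = 0.3 * EXACT_BX[:, 0] + 0.1 * EXACT_BX[:, 1]


class TestHarmonizeMulti:
    def _tables(self, rng, k=8):
        ids = [f"rs{i}" for i in range(k)]
        t1 = make_table("X1", ids, rng.normal(0, 0.1, k), np.full(k, 0.01), pval=np.full(k, 1e-10))
        t2 = make_table("X2", ids, rng.normal(0, 0.1, k), np.full(k, 0.01), pval=np.full(k, 1e-10))
        ty = make_table("Y", ids, rng.normal(0, 0.05, k), np.full(k, 0.01))
        return t1, t2, ty

    def test_union_of_shared_variants(self, rng):
        t1, t2, ty = self._tables(rng)
        i1, i2 = select_genome_wide(t1, 1e-5), select_genome_wide(t2, 1e-5)
        d = harmonize_multi([i1, i2], [t1, t2], ty)
        assert d.k == 8 and d.m == 2

    def test_variant_absent_from_outcome_dropped(self, rng):
        t1, t2, ty = self._tables(rng)
        ty.records = ty.records.iloc[1:].reset_index(drop=True)
        d = harmonize_multi([select_genome_wide(t1, 1e-5), select_genome_wide(t2, 1e-5)], [t1, t2], ty)
        assert d.k == 7
        assert "rs0" not in d.variant_ids

    def test_three_exposure_hand_built_matrix(self, rng):
        k = 5
        ids = [f"rs{i}" for i in range(k)]
        betas = [rng.normal(0, 0.1, k) for _ in range(3)]
        tables = [
            make_table(f"X{j + 1}", ids, betas[j], np.full(k, 0.01), pval=np.full(k, 1e-10))
            for j in range(3)
        ]
        ty = make_table("Y", ids, rng.normal(0, 0.05, k), np.full(k, 0.01))
        isets = [select_genome_wide(t, 1e-5) for t in tables]
        d = harmonize_multi(isets, tables, ty)
        np.testing.assert_allclose(d.beta_x, np.column_stack(betas))
        np.testing.assert_allclose(d.beta_y, ty.records["beta"])

    def test_flipped_outcome_alleles_align(self, rng):
        k = 4
        ids = [f"rs{i}" for i in range(k)]
        t1 = make_table("X1", ids, rng.normal(0, 0.1, k), np.full(k, 0.01), pval=np.full(k, 1e-10))
        t2 = make_table("X2", ids, rng.normal(0, 0.1, k), np.full(k, 0.01), pval=np.full(k, 1e-10))
        by = rng.normal(0, 0.05, k)
        ty = make_table("Y", ids, -by, np.full(k, 0.01), effect_allele=["G"] * k, other_allele=["A"] * k)
        d = harmonize_multi([select_genome_wide(t1, 1e-5), select_genome_wide(t2, 1e-5)], [t1, t2], ty)
        np.testing.assert_allclose(d.beta_y, by)

    def test_too_few_instruments_fatal(self, rng):
        t1, t2, ty = self._tables(rng, k=2)
        with pytest.raises(ValueError):
            harmonize_multi([select_genome_wide(t1, 1e-5), select_genome_wide(t2, 1e-5)], [t1, t2], ty)


class TestMvIVW:
    def test_exact_fit(self):
        bx = np.array([[0.1, 0.2], [0.2, 0.1], [0.1, 0.0]])
        by = 0.3 * bx[:, 0] + 0.1 * bx[:, 1]
        est = mv_ivw(_dataset(bx, by, np.full(3, 0.01)))
        np.testing.assert_allclose(est.beta, [0.3, 0.1], atol=1e-12)

    def test_m1_reduces_to_univariable_ivw(self, rng):
        bx = rng.normal(0.2, 0.05, 8)
        by = rng.normal(0.1 * bx, 0.02)
        sy = rng.uniform(0.01, 0.03, 8)
        est_mv = mv_ivw(_dataset(bx[:, None], by, sy))
        est_uv = ivw(make_hset(bx, by, sy))
        assert est_mv.beta[0] == pytest.approx(est_uv.beta, abs=1e-14)
        assert est_mv.se[0] == pytest.approx(est_uv.se, abs=1e-14)

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            k, m = int(rng.integers(5, 30)), int(rng.integers(2, 4))
            bx = rng.normal(0, 0.2, (k, m))
            by = rng.normal(bx @ rng.normal(0, 0.3, m), 0.05)
            sy = rng.uniform(0.01, 0.1, k)
            est = mv_ivw(_dataset(bx, by, sy))
            fit = sm.WLS(by, bx, weights=sy**-2.0).fit()
            np.testing.assert_allclose(est.beta, fit.params, atol=1e-10)

    def test_exposure_permutation_permutes_coefficients(self, rng):
        bx = rng.normal(0, 0.2, (10, 3))
        by = rng.normal(bx @ [0.3, 0.1, -0.2], 0.02)
        sy = rng.uniform(0.01, 0.03, 10)
        base = mv_ivw(_dataset(bx, by, sy, exposure_ids=["A", "B", "C"]))
        perm = mv_ivw(_dataset(bx[:, [2, 0, 1]], by, sy, exposure_ids=["C", "A", "B"]))
        for name in ("A", "B", "C"):
            assert perm.for_exposure(name)["beta"] == pytest.approx(base.for_exposure(name)["beta"])

    def test_collinear_exposures_fatal(self):
        bx = np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6], [0.15, 0.3]])
        with pytest.raises(ValueError, match="collinear"):
            mv_ivw(_dataset(bx, np.ones(4), np.full(4, 0.01)))


class TestMvEgger:
    def test_exact_fit_with_constant_offset(self):
        by = EXACT_BY + 0.01
        est = mv_egger(_dataset(EXACT_BX, by, np.full(6, 0.01)))
        assert est.intercept == pytest.approx(0.01, abs=1e-10)
        np.testing.assert_allclose(est.beta, [0.3, 0.1], atol=1e-10)

    def test_row_sign_flip_invariance(self, rng):
        bx = np.abs(rng.normal(0.2, 0.05, (8, 2))) + 0.01
        by = rng.normal(bx @ [0.3, 0.1] + 0.02, 0.01)
        sy = np.full(8, 0.01)
        base = mv_egger(_dataset(bx, by, sy))
        flip = np.ones(8)
        flip[[1, 4]] = -1
        flipped = mv_egger(_dataset(bx * flip[:, None], by * flip, sy))
        np.testing.assert_allclose(flipped.beta, base.beta, atol=1e-12)
        assert flipped.intercept == pytest.approx(base.intercept, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        bx = np.abs(rng.normal(0.2, 0.08, (12, 2))) + 0.01
        by = rng.normal(bx @ [0.3, 0.1], 0.03)
        sy = rng.uniform(0.01, 0.05, 12)
        est = mv_egger(_dataset(bx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        np.testing.assert_allclose(est.beta, fit.params[1:], atol=1e-10)


class TestMvMedian:
    def test_exact_fit(self):
        est = mv_median(_dataset(EXACT_BX, EXACT_BY, np.full(6, 0.01)), n_boot=20, seed=0)
        np.testing.assert_allclose(est.beta, [0.3, 0.1], atol=1e-8)

    def test_robust_to_minority_corruption(self):
        by = EXACT_BY.copy()
        by[2] += 0.5  # single corrupted instrument
        est = mv_median(_dataset(EXACT_BX, by, np.full(6, 0.01)), n_boot=20, seed=0)
        np.testing.assert_allclose(est.beta, [0.3, 0.1], atol=1e-8)

    def test_matches_grid_search_oracle(self, rng):
        bx = rng.normal(0, 0.2, (6, 2))
        by = rng.normal(bx @ [0.3, 0.1], 0.02)
        sy = rng.uniform(0.01, 0.03, 6)
        est = mv_median(_dataset(bx, by, sy), n_boot=20, seed=0)
        w = sy**-2.0

        def grid_min(lo1, hi1, lo2, hi2, n):
            best, best_obj = None, np.inf
            for b1 in np.linspace(lo1, hi1, n):
                for b2 in np.linspace(lo2, hi2, n):
                    obj = np.sum(w * np.abs(by - bx @ [b1, b2]))
                    if obj < best_obj:
                        best, best_obj = (b1, b2), obj
            return best

        coarse = grid_min(-0.5, 0.9, -0.5, 0.9, 141)
        best = grid_min(coarse[0] - 0.02, coarse[0] + 0.02, coarse[1] - 0.02, coarse[1] + 0.02, 161)
        np.testing.assert_allclose(est.beta, best, atol=1e-3)


class TestMvLasso:
    def test_clean_data_equals_mv_ivw(self, rng):
        bx = rng.normal(0, 0.2, (10, 2))
        by = rng.normal(bx @ [0.3, 0.1], 0.005)
        sy = np.full(10, 0.005)
        d = _dataset(bx, by, sy)
        est = mv_lasso(d)
        full = mv_ivw(d)
        assert len(est.selected_valid_set) == 10
        np.testing.assert_allclose(est.beta, full.beta, atol=1e-12)

    def test_injected_intercept_excluded_from_valid_set(self, rng):
        bx = rng.normal(0, 0.2, (12, 2))
        by = rng.normal(bx @ [0.3, 0.1], 0.005)
        by[3] += 0.2  # strong pleiotropic intercept on one variant
        d = _dataset(bx, by, np.full(12, 0.005))
        est = mv_lasso(d)
        assert "rs4" not in est.selected_valid_set

    def test_infinite_penalty_limit_is_full_mv_ivw(self, rng):
        bx = rng.normal(0, 0.2, (10, 2))
        by = rng.normal(bx @ [0.3, 0.1], 0.005)
        d = _dataset(bx, by, np.full(10, 0.005))
        est = mv_lasso(d, lambda_grid=np.array([1e9]))
        full = mv_ivw(d)
        np.testing.assert_allclose(est.beta, full.beta, atol=1e-12)
        assert est.n_snps == 10


def test_parameter_recovery_simulation(rng):
    """True direct effects (0.3, 0.1) with k=100 are recovered on average."""
    ests = []
    for _ in range(30):
        bx = rng.normal(0, 0.15, (100, 2))
        sy = np.full(100, 0.01)
        by = rng.normal(bx @ [0.3, 0.1], sy)
        ests.append(mv_ivw(_dataset(bx, by, sy)).beta)
    mean = np.mean(ests, axis=0)
    np.testing.assert_allclose(mean, [0.3, 0.1], atol=0.01)
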