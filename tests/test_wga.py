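"""Kinship, REML, GLS association, genotype residualization and genomic
control, each against independent small-instance oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hitchcomb.datatypes import GenotypeTable, Pedigree, make_variant_frame
from hitchcomb.wga import (
    KinshipMatrix,
    VarianceComponents,
    _adaptive_perm,
    adaptive_permutation_p,
    estimate_kinship,
    family_design,
    fit_mix,
    fit_mixstrat,
    fit_variance_components,
    gls_scan,
    inflation_factor,
    qq_table,
    residualize_genotypes,
)


def make_gt(codes, ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    variants = make_variant_frame(
        [f"k{j}" for j in range(m)], "1", np.arange(1, m + 1) * 10
    )
    return GenotypeTable(codes, variants, ids or [f"i{x}" for x in range(n)])


class TestKinship:
    def test_duplicate_individuals_share_everything(self, rng):
        p = rng.uniform(0.1, 0.9, 1000)
        g = (rng.random((1, 1000)) < p).astype(np.int8) + (
            rng.random((1, 1000)) < p
        ).astype(np.int8)
        codes = np.vstack([g, g, (rng.random((1, 1000)) < p).astype(np.int8)
                           + (rng.random((1, 1000)) < p).astype(np.int8)])
        km = estimate_kinship(make_gt(codes))
        assert km.values[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_unrelated_pairs_average_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 5000)
        codes = (
            (rng.random((30, 5000)) < p).astype(np.int8)
            + (rng.random((30, 5000)) < p).astype(np.int8)
        )
        km = estimate_kinship(make_gt(codes))
        off = km.values[~np.eye(30, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_fully_heterozygous_individual_has_f_minus_one(self):
        # everyone heterozygous at p = 0.5: O_hom = 0, E_hom = L/2 -> F = -1
        codes = np.ones((4, 200), dtype=np.int8)
        km = estimate_kinship(make_gt(codes), min_snps=100)
        assert np.allclose(np.diag(km.values), 0.0, atol=1e-9)

    def test_monomorphic_only_input_raises(self):
        codes = np.zeros((4, 200), dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            estimate_kinship(make_gt(codes))

    def test_ridge_repair_reaches_floor(self):
        km = KinshipMatrix(np.ones((3, 3)), ["a", "b", "c"])
        from hitchcomb.wga import repair_positive_definite

        out = repair_positive_definite(km)
        assert np.linalg.eigvalsh(out.values)[0] >= 1e-6 - 1e-12
        assert out.ridge > 0


class TestVarianceComponents:
    def _halfsib_G(self, n_fam, fam_size):
        n = n_fam * fam_size
        G = np.zeros((n, n))
        for f in range(n_fam):
            sl = slice(f * fam_size, (f + 1) * fam_size)
            G[sl, sl] = 0.25
        np.fill_diagonal(G, 1.0)
        return G

    def test_recovers_heritability_on_halfsib_design(self):
        rng = np.random.default_rng(17)
        G = self._halfsib_G(100, 5)
        L = np.linalg.cholesky(G + 1e-9 * np.eye(500))
        y = L @ rng.normal(size=500) + rng.normal(size=500)  # h2 = 0.5
        vc = fit_variance_components(y, G)
        assert 0.35 < vc.heritability < 0.65

    def test_pure_noise_gives_near_zero_ratio(self):
        G = self._halfsib_G(60, 5)
        hits = 0
        for seed in range(10):
            y = np.random.default_rng(seed).normal(size=300)
            vc = fit_variance_components(y, G)
            hits += vc.heritability < 0.1
        assert hits >= 9

    def test_identity_G_is_flagged_flat(self):
        y = np.random.default_rng(0).normal(size=100)
        vc = fit_variance_components(y, np.eye(100))
        assert vc.ratio_flat
        assert vc.sigma2_a == 0.0


class TestGls:
    def _ols_oracle(self, y, x):
        """Hand-rolled normal equations with residual-variance scaling."""
        X = np.column_stack([np.ones_like(x), x])
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - 2)
        var = s2 * np.linalg.inv(XtX)[1, 1]
        return beta[1], var

    def test_zero_polygenic_variance_equals_ols(self, rng):
        y = rng.normal(size=40)
        x = rng.integers(0, 3, 40).astype(float)
        vc = VarianceComponents(0.0, 1.3, 0.0)
        rec = fit_mix(y, x, np.eye(40), vc)
        b_ref, v_ref = self._ols_oracle(y, x)
        assert rec.beta == pytest.approx(b_ref, abs=1e-10)
        assert rec.var_beta == pytest.approx(v_ref, abs=1e-10)

    def test_perfect_fit_has_zero_variance(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = 2.0 + 0.5 * x
        rec = fit_mix(y, x, np.eye(6), VarianceComponents(0.0, 1.0, 0.0))
        assert rec.beta == pytest.approx(0.5)
        assert rec.var_beta == pytest.approx(0.0, abs=1e-20)

    def test_matches_direct_inversion_oracle(self, rng):
        """GLS against an explicit whitening oracle on random instances."""
        for _ in range(25):
            n = int(rng.integers(10, 50))
            A = rng.normal(size=(n, n))
            G = A @ A.T / n + np.eye(n)
            vc = VarianceComponents(
                float(rng.uniform(0.1, 2)), float(rng.uniform(0.1, 2)), 0.0
            )
            y = rng.normal(size=n)
            x = rng.integers(0, 3, n).astype(float)
            if np.ptp(x) == 0:
                continue
            rec = fit_mix(y, x, G, vc)
            V = vc.sigma2_a * G + vc.sigma2_e * np.eye(n)
            L = np.linalg.cholesky(V)
            yw = np.linalg.solve(L, y)
            Xw = np.linalg.solve(L, np.column_stack([np.ones(n), x]))
            beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
            resid = yw - Xw @ beta
            r_hat = resid @ resid / (n - 2)
            var = r_hat * np.linalg.inv(Xw.T @ Xw)[1, 1]
            assert rec.beta == pytest.approx(beta[1], abs=1e-8)
            assert rec.var_beta == pytest.approx(var, abs=1e-8)

    def test_constant_genotype_is_flagged(self):
        rec = fit_mix(
            np.random.default_rng(0).normal(size=20),
            np.ones(20),
            np.eye(20),
            VarianceComponents(0.0, 1.0, 0.0),
        )
        assert rec.flags == "monomorphic"


class TestResidualize:
    def test_single_family_residual_is_centering(self):
        codes = np.array([0, 1, 2, 1, 0], dtype=float)
        out = residualize_genotypes(
            codes, sire_labels=["s"] * 5, mgs_labels=["m"] * 5, min_family=1
        )
        np.testing.assert_allclose(out, codes - codes.mean(), atol=1e-12)

    def test_residuals_orthogonal_to_family_indicators(self, rng):
        sire = rng.integers(0, 6, 60)
        mgs = rng.integers(0, 8, 60)
        codes = rng.integers(0, 3, 60).astype(float)
        out = residualize_genotypes(
            codes, sire_labels=sire, mgs_labels=mgs, min_family=1
        )
        for f in range(6):
            assert abs(out[sire == f].sum()) < 1e-8
        for f in range(8):
            assert abs(out[mgs == f].sum()) < 1e-8

    def test_two_by_two_families_match_normal_equations(self):
        sire = np.array([0, 0, 0, 1, 1, 1])
        mgs = np.array([0, 1, 0, 1, 0, 1])
        codes = np.array([0, 1, 2, 2, 1, 0], dtype=float)
        D = np.column_stack(
            [np.ones(6)]
            + [(sire == f).astype(float) for f in (0, 1)]
            + [(mgs == f).astype(float) for f in (0, 1)]
        )
        coef, *_ = np.linalg.lstsq(D, codes, rcond=None)
        expected = codes - D @ coef
        out = residualize_genotypes(
            codes, sire_labels=sire, mgs_labels=mgs, min_family=1
        )
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_small_families_are_pooled(self):
        sire = np.array([0] * 6 + [1, 2, 3])  # three singletons pooled
        mgs = np.zeros(9, dtype=int)
        U, sire_p, _ = family_design(sire, mgs, min_family=5)
        assert len(np.unique(sire_p[6:])) == 1
        assert len(np.unique(sire_p)) == 2

    def test_family_constant_codes_residualize_to_zero(self):
        ped = Pedigree(
            pd.DataFrame(
                {
                    "id": [f"i{k}" for k in range(6)],
                    "sire": ["a"] * 3 + ["b"] * 3,
                    "mgs": ["x"] * 3 + ["y"] * 3,
                }
            )
        )
        codes = np.array([2, 2, 2, 0, 0, 0], dtype=float)
        rec = fit_mixstrat(
            np.random.default_rng(0).normal(size=6), codes, ped,
            np.eye(6), VarianceComponents(0.0, 1.0, 0.0),
            min_family=1, ids=[f"i{k}" for k in range(6)],
        )
        assert rec.flags == "monomorphic"
        assert rec.model == "MIXStrat"


class TestAdaptivePermutation:
    def test_stub_stream_controls_escalation(self):
        # exceedances >= 10 at the first stage: stop at n = 100
        calls = []

        def draw_many(k):
            calls.append(k)
            return np.ones(k)  # everything exceeds

        p, n = _adaptive_perm(0.5, draw_many, schedule=(100, 1000))
        assert n == 100 and calls == [100]
        assert p == pytest.approx(101 / 101)

        # no exceedances: escalate through the whole schedule
        calls.clear()

        def draw_none(k):
            calls.append(k)
            return np.zeros(k)

        p, n = _adaptive_perm(0.5, draw_none, schedule=(100, 1000))
        assert n == 1000 and calls == [100, 900]
        assert p == pytest.approx(1 / 1001)

    def test_zero_statistic_yields_p_one_without_escalation(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        x = rng.integers(0, 3, 30).astype(float)
        p, n = adaptive_permutation_p(
            y, x, np.eye(30), VarianceComponents(0.0, 1.0, 0.0),
            observed_t2=0.0, schedule=(200, 2000), seed=1,
        )
        assert n == 200
        assert p > 0.9

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=60)
        vc = VarianceComponents(0.0, 1.0, 0.0)
        ps = []
        for _ in range(60):
            x = rng.integers(0, 3, 60).astype(float)
            rec = fit_mix(y, x, np.eye(60), vc)
            p, _ = adaptive_permutation_p(
                y, x, np.eye(60), vc, rec.t2, schedule=(199,), seed=int(rng.integers(2**31)),
            )
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGenomicControl:
    def test_median_at_chi2_median_gives_unity(self):
        t2 = np.array([0.1, 0.2, 0.456, 0.8, 1.5] * 4)
        assert inflation_factor(t2) == pytest.approx(1.0)

    def test_chi2_draws_give_lambda_near_one(self):
        t2 = np.random.default_rng(2).chisquare(1, 100_000)
        assert 0.97 < inflation_factor(t2) < 1.03

    def test_doubling_statistics_doubles_lambda(self):
        t2 = np.random.default_rng(3).chisquare(1, 1000)
        assert inflation_factor(2 * t2) == pytest.approx(2 * inflation_factor(t2))

    def test_qq_table_uniform_expected_quantiles(self):
        q = qq_table([0.5, 0.1, 0.9])
        np.testing.assert_allclose(
            q["expected"], -np.log10(np.array([1, 3, 5]) / 6)
        )
        assert (np.diff(q["observed"]) <= 0).all()
        assert len(q) == 3
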