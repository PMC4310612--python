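"""Spearman mapping, permutation schemes, Storey q-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tissueqtl import association as assoc
from tissueqtl import simulate as sim


class TestSpearman:
    def test_monotone_is_one(self):
        rho, _ = assoc.spearman([0, 1, 2], [1.1, 2.2, 3.0])
        assert rho == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        rho, _ = assoc.spearman([0, 1, 2], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, p = assoc.spearman(x, y)
        # independent oracle: enumerate all 8! permutations of y outright
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)

        def pear(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        count = 0
        total = 0
        for perm in itertools.permutations(range(8)):
            total += 1
            if abs(pear(xr, yr[list(perm)])) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_zero_variance_undefined(self):
        rho, p = assoc.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_missing_pairs_dropped(self):
        rho, _ = assoc.spearman(
            [0, 1, 2, np.nan], [1, 2, 3, 100]
        )
        assert rho == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho, _ = assoc.spearman(x, y)
        rho_t, _ = assoc.spearman(np.exp(x), y**3 + 5 * y)
        assert rho_t == pytest.approx(rho, abs=1e-12)


class TestResidualize:
    def test_orthogonal_covariate_no_change(self, rng):
        y = rng.normal(size=(50, 3))
        c = rng.normal(size=(50, 1))
        c -= c.mean()
        y_orth = y - c @ (c.T @ y) / (c.T @ c)
        out = assoc.residualize_covariates(y_orth, c)
        np.testing.assert_allclose(out, y_orth + 0, atol=1e-10)

    def test_phenotype_equal_covariate_residual_zero(self, rng):
        c = rng.normal(size=(30, 1))
        out = assoc.residualize_covariates(c.copy(), c)
        np.testing.assert_allclose(out, np.full_like(c, c.mean()), atol=1e-10)

    def test_planted_batch_shift_removed(self, rng):
        batch = np.repeat([0.0, 1.0], 25)
        y = rng.normal(size=50) + 3.0 * batch
        out = assoc.residualize_covariates(y[:, None], batch[:, None])[:, 0]
        assert abs(out[batch == 0].mean() - out[batch == 1].mean()) < 1e-10

    def test_rank_deficient_rejected(self, rng):
        c = rng.normal(size=(20, 1))
        dup = np.hstack([c, c])
        with pytest.raises(ValueError, match="rank-deficient"):
            assoc.residualize_covariates(rng.normal(size=(20, 2)), dup)


def _small_cohort(n=60, n_genes=10, frac_eqtl=0.0, seed=0, **kw):
    spec = sim.SimulationSpec(
        n_individuals=n, n_genes=n_genes, n_snps_per_gene=8,
        frac_eqtl=frac_eqtl, seed=seed, **kw
    )
    rng = np.random.default_rng(seed)
    gm = sim.simulate_gene_models(spec, rng)
    gt = sim.simulate_genotypes(spec, gm, rng)
    truth = sim.plant_effects(spec, gm, gt, rng)
    expr = sim.simulate_expression(spec, gm, gt, truth, rng)
    return spec, gm, gt, truth, expr


class TestMapCis:
    def test_window_boundary_inclusive(self):
        spec, gm, gt, truth, expr = _small_cohort(n=30, n_genes=2, seed=1)
        gene = list(gm.values())[0]
        # move one SNP exactly to the window edge, one just past it
        gt.variants.loc[0, "pos"] = gene.tss + 1_000_000
        gt.variants.loc[1, "pos"] = gene.tss + 1_000_001
        rec = assoc.map_cis(gt, expr["F"], gm, window=1_000_000)
        ids = set(rec["regressor_id"])
        assert gt.variants.loc[0, "id"] in ids
        assert gt.variants.loc[1, "id"] not in ids

    def test_maf_filter_applied(self):
        spec, gm, gt, truth, expr = _small_cohort(n=60, n_genes=2, seed=2)
        gt.low_maf[:] = True
        rec = assoc.map_cis(gt, expr["F"], gm, window=1_000_000)
        assert len(rec) == 0

    def test_planted_eqtl_tiny_p(self):
        spec, gm, gt, truth, expr = _small_cohort(
            n=185, n_genes=10, frac_eqtl=1.0, seed=3,
            eqtl_effect_choices=(1.0,), sharing_class_probs=(0, 0, 1.0),
            maf_range=(0.2, 0.5),
        )
        rec = assoc.map_cis(gt, expr["F"], gm, window=1_000_000)
        merged = rec.merge(
            truth[(truth.family == "eqtl") & (truth.tissue == "F")],
            left_on=["feature_id", "regressor_id"],
            right_on=["feature_id", "regressor_id"],
        )
        assert (merged["nominal_p"] < 1e-10).all()

    def test_signed_distance_follows_transcription_direction(self):
        spec, gm, gt, truth, expr = _small_cohort(n=30, n_genes=4, seed=4)
        rec = assoc.map_cis(gt, expr["F"], gm, window=1_000_000)
        pos = gt.variants.set_index("id")["pos"]
        for row in rec.sample(20, random_state=0).itertuples():
            gene = gm[row.gene_id]
            assert row.distance_to_anchor == gene.signed_distance(
                pos[row.regressor_id]
            )


class TestFixedPermutationScheme:
    def test_fdr_one_declares_everything(self):
        spec, gm, gt, truth, expr = _small_cohort(n=40, n_genes=6, seed=5)
        res = assoc.fixed_permutation_threshold(
            gt, expr["F"], gm, window=1_000_000, n_perm=100, fdr=1.0,
            rng=np.random.default_rng(0),
        )
        assert res.threshold == pytest.approx(res.unit_min_p.max())
        assert len(res.significant_units) == len(res.unit_min_p)

    def test_constant_phenotype_nothing_significant(self):
        spec, gm, gt, truth, expr = _small_cohort(n=40, n_genes=4, seed=6)
        expr["F"].values[:] = 1.0
        res = assoc.fixed_permutation_threshold(
            gt, expr["F"], gm, window=1_000_000, n_perm=100,
            rng=np.random.default_rng(0),
        )
        assert res.significant_units == []

    def test_null_cohort_declares_almost_nothing(self):
        spec, gm, gt, truth, expr = _small_cohort(n=80, n_genes=40, seed=7)
        res = assoc.fixed_permutation_threshold(
            gt, expr["F"], gm, window=1_000_000, n_perm=200,
            rng=np.random.default_rng(1),
        )
        assert len(res.significant_units) <= 1


class TestAdaptivePermutations:
    def test_constant_phenotype_boundary(self):
        emp, nominal, n_perm = assoc.adaptive_empirical_p(
            np.ones(50), np.arange(50), rng=0
        )
        assert emp == 1.0
        assert n_perm == 100

    def test_strong_signal_hits_floor(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(2, 0.4, 200).astype(float)
        y = 2.0 * x + rng.normal(size=200)
        emp, nominal, n_perm = assoc.adaptive_empirical_p(
            y, x, rng=3, max_perm=10_000
        )
        assert n_perm == 10_000
        assert emp == pytest.approx(1 / 10_000)

    def test_never_below_one_over_max_perm(self):
        rng = np.random.default_rng(4)
        for i in range(5):
            y = rng.normal(size=60)
            x = rng.binomial(2, 0.3, 60).astype(float)
            emp, *_ = assoc.adaptive_empirical_p(y, x, rng=i, max_perm=1000)
            assert emp >= 1 / 1000


class TestQvalues:
    def test_null_pi0_near_one(self, rng):
        p = rng.uniform(size=5000)
        q, sig, pi0 = assoc.qvalues(p, fdr=0.10)
        assert pi0 > 0.9
        assert sig.sum() <= 5

    def test_pi0_forced_one_equals_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=1000)
        q, _, _ = assoc.qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_planted_signals_recovered(self, rng):
        p = np.concatenate([np.full(50, 1e-6), rng.uniform(size=950)])
        q, sig, _ = assoc.qvalues(p, fdr=0.10)
        assert sig[:50].all()

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q, _, _ = assoc.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestAseFdrEstimate:
    def test_published_medians_give_twenty_percent(self):
        # 0.005 * 1748 / 41 = 0.213 -> prints as "20% FDR"
        fdr = assoc.ase_fdr_estimate(1748, 41, 0.005)
        assert fdr == pytest.approx(0.2132, abs=5e-4)

    def test_boundary_identities(self):
        assert assoc.ase_fdr_estimate(1000, 5, 0.005) == pytest.approx(1.0)
        assert assoc.ase_fdr_estimate(1000, 1000, 0.005) == pytest.approx(0.005)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            assoc.ase_fdr_estimate(1000, 0)
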