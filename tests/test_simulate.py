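"""Synthetic cohort generators: planted effects must be recoverable."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueqtl import simulate as sim
from tissueqtl.links import InsertSizeDistribution


def _spec(**kw):
    return sim.SimulationSpec(**kw)


class TestGenotypes:
    def test_hwe_frequencies(self):
        spec = _spec(n_individuals=10_000, n_genes=1, n_snps_per_gene=1,
                     maf_range=(0.3, 0.3))
        rng = np.random.default_rng(1)
        gm = sim.simulate_gene_models(spec, rng)
        gt = sim.simulate_genotypes(spec, gm, rng)
        d = gt.dosages[:, 0]
        n = len(d)
        # HWE closed form at maf 0.3: (0.49, 0.42, 0.09)
        for dosage, expected in [(0, 0.49), (1, 0.42), (2, 0.09)]:
            freq = (d == dosage).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * se

    def test_deterministic_under_seed(self):
        spec = _spec(n_individuals=50, n_genes=3)
        a = sim.simulate_genotypes(
            spec, sim.simulate_gene_models(spec, np.random.default_rng(5)),
            np.random.default_rng(5),
        )
        b = sim.simulate_genotypes(
            spec, sim.simulate_gene_models(spec, np.random.default_rng(5)),
            np.random.default_rng(5),
        )
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_half_maf_symmetric_dosage(self):
        spec = _spec(n_individuals=5000, n_genes=1, n_snps_per_gene=2,
                     maf_range=(0.5, 0.5))
        rng = np.random.default_rng(2)
        gm = sim.simulate_gene_models(spec, rng)
        gt = sim.simulate_genotypes(spec, gm, rng)
        assert gt.dosages.mean() == pytest.approx(1.0, abs=0.05)

    def test_maf_range_validated(self):
        with pytest.raises(ValueError, match="maf_range"):
            _spec(maf_range=(0.01, 0.5))


class TestExpression:
    def _cohort(self, **kw):
        spec = _spec(**kw)
        rng = np.random.default_rng(spec.seed)
        gm = sim.simulate_gene_models(spec, rng)
        gt = sim.simulate_genotypes(spec, gm, rng)
        truth = sim.plant_effects(spec, gm, gt, rng)
        expr = sim.simulate_expression(spec, gm, gt, truth, rng)
        return spec, gm, gt, truth, expr

    def test_planted_sd_effect_recovered_by_group_medians(self):
        spec, gm, gt, truth, expr = self._cohort(
            n_individuals=200, n_genes=20, frac_eqtl=1.0,
            eqtl_effect_choices=(1.0,), sharing_class_probs=(0, 0, 1.0), seed=11,
        )
        snp_idx = pd.Series(np.arange(gt.n_variants), index=gt.variants["id"])
        feat_idx = pd.Series(
            np.arange(expr["F"].n_features), index=expr["F"].features["id"]
        )
        tF = truth[(truth.family == "eqtl") & (truth.tissue == "F")]
        diffs = []
        for row in tF.itertuples():
            y = expr["F"].values[:, feat_idx[row.feature_id]]
            d = gt.dosages[:, snp_idx[row.regressor_id]]
            ys = (y - y.mean()) / y.std(ddof=1)
            # oracle: direct group medians on the simulated matrix
            diff = np.median(ys[d == 1]) - np.median(ys[d == 0])
            diffs.append(diff * np.sign(row.effect))
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.15)

    def test_effect_absent_in_non_carrier_tissue(self):
        spec, gm, gt, truth, expr = self._cohort(
            n_individuals=150, n_genes=5, frac_eqtl=1.0,
            eqtl_effect_choices=(1.0,), seed=3,
        )
        from tissueqtl.association import spearman

        snp_idx = pd.Series(np.arange(gt.n_variants), index=gt.variants["id"])
        feat_idx = pd.Series(
            np.arange(expr["F"].n_features), index=expr["F"].features["id"]
        )
        checked = 0
        for (fid, snp), grp in truth[truth.family == "eqtl"].groupby(
            ["feature_id", "regressor_id"]
        ):
            carriers = set(grp["tissue"])
            for t in spec.cell_types:
                if t in carriers:
                    continue
                _, p = spearman(
                    gt.dosages[:, snp_idx[snp]],
                    expr[t].values[:, feat_idx[fid]],
                )
                assert p > 1e-4  # null tissue: no planted association
                checked += 1
        assert checked > 0


class TestMethylation:
    def _cohort(self, **kw):
        spec = _spec(**kw)
        rng = np.random.default_rng(spec.seed)
        gm = sim.simulate_gene_models(spec, rng)
        gt = sim.simulate_genotypes(spec, gm, rng)
        truth = sim.plant_effects(spec, gm, gt, rng)
        expr = sim.simulate_expression(spec, gm, gt, truth, rng)
        meth = sim.simulate_methylation(spec, gm, gt, expr, truth, rng)
        return spec, gm, gt, truth, expr, meth

    def test_beta_values_bounded(self):
        *_, meth = self._cohort(n_individuals=50, n_genes=10, seed=4)
        for pm in meth.values():
            assert (pm.values >= 0).all() and (pm.values <= 1).all()

    def test_logit_effects_recoverable_by_regression(self):
        spec, gm, gt, truth, expr, meth = self._cohort(
            n_individuals=200, n_genes=60, frac_mqtl=1.0, frac_eqtm=0.0,
            mqtl_effect_choices=(0.5, 1.0, 1.5),
            sharing_class_probs=(0, 0, 1.0), seed=5,
        )
        snp_idx = pd.Series(np.arange(gt.n_variants), index=gt.variants["id"])
        feat_idx = pd.Series(
            np.arange(meth["F"].n_features), index=meth["F"].features["id"]
        )
        planted, fitted = [], []
        for row in truth[
            (truth.family == "mqtl") & (truth.tissue == "F")
        ].itertuples():
            beta = meth["F"].values[:, feat_idx[row.feature_id]]
            d = gt.dosages[:, snp_idx[row.regressor_id]]
            logit = np.log(beta / (1 - beta))
            slope = np.polyfit(d, logit, 1)[0]  # regression oracle
            planted.append(row.effect)
            fitted.append(slope)
        r = np.corrcoef(planted, fitted)[0, 1]
        assert r >= 0.9

    def test_negative_eqtm_coupling_gives_negative_rho(self):
        spec, gm, gt, truth, expr, meth = self._cohort(
            n_individuals=200, n_genes=30, frac_mqtl=0.0, frac_eqtm=1.0,
            eqtm_coupling=1.5, sharing_class_probs=(0, 0, 1.0), seed=6,
        )
        from tissueqtl.association import spearman

        feat_idx_e = pd.Series(
            np.arange(expr["F"].n_features), index=expr["F"].features["id"]
        )
        feat_idx_m = pd.Series(
            np.arange(meth["F"].n_features), index=meth["F"].features["id"]
        )
        neg = truth[(truth.family == "eqtm") & (truth.tissue == "F")
                    & (truth.effect < 0)]
        assert len(neg) > 0
        for row in neg.itertuples():
            rho, _ = spearman(
                meth["F"].values[:, feat_idx_m[row.regressor_id]],
                expr["F"].values[:, feat_idx_e[row.feature_id]],
            )
            assert rho < 0


class TestReadPairs:
    def test_single_isoform_only_adjacent_links(self, three_exon_gene, insert_dist, rng):
        from tissueqtl.links import count_links

        two_exon = sim.GeneModel("g2", "chr1", "+", three_exon_gene.exons[:2])
        pairs, _ = sim.simulate_read_pairs(
            two_exon, {"s1": 0.0}, insert_dist, 49, 2000, rng
        )
        lc = count_links(pairs, two_exon)
        assert lc.links[["exon_a", "exon_b"]].values.tolist() == [[0, 1]]

    def test_truth_usage_shift_recorded(self, three_exon_gene, insert_dist):
        # dosage 0 vs 2 with planted usage shift 0.2 -> truth difference 0.2
        usage0, usage2 = 0.3, 0.5
        iso = sim.default_isoforms(three_exon_gene)
        t0 = sim.expected_link_fractions(
            three_exon_gene, {iso[0]: 1 - usage0, iso[1]: usage0},
            insert_dist, 49,
        )
        t2 = sim.expected_link_fractions(
            three_exon_gene, {iso[0]: 1 - usage2, iso[1]: usage2},
            insert_dist, 49,
        )
        assert usage2 - usage0 == pytest.approx(0.2)
        # skipping link fraction strictly increases with skipping usage
        assert t2[(0, 2)] > t0[(0, 2)]

    def test_insert_longer_than_transcript_redrawn(self, rng):
        short_gene = sim.GeneModel("gS", "chr1", "+", [(0, 60), (100, 160)])
        dist = InsertSizeDistribution.from_dict({110: 0.5, 500: 0.5})
        pairs, qc = sim.simulate_read_pairs(
            short_gene, {"s1": 0.0}, dist, 30, 200, rng
        )
        assert qc["n_redrawn"] > 0
        assert len(pairs) > 0


class TestAllelicCounts:
    def test_null_ratio_centred_on_p0(self):
        spec = _spec(n_individuals=60, ase_n_sites=200, ase_fraction=0.0,
                     ase_p0=0.5, ase_background_sd=0.0, ase_tissue_sd=0.0,
                     ase_depth=30)
        recs, truth = sim.simulate_allelic_counts(spec, np.random.default_rng(7))
        ratio = recs["ref_count"] / recs["total_count"]
        assert ratio.mean() == pytest.approx(0.5, abs=0.005)
        assert not truth["is_ase"].any()

    def test_planted_ase_detected_with_exact_binomial_power(self):
        # exact power oracle: P(two-sided p < 0.005 | p=0.8, depth 100)
        from tissueqtl.ase import binomial_ase_test

        depth = 100
        pmf = stats.binom.pmf(np.arange(depth + 1), depth, 0.8)
        power = sum(
            pmf[k] for k in range(depth + 1)
            if binomial_ase_test(k, depth, 0.5) < 0.005
        )
        assert power >= 0.99
        rng = np.random.default_rng(8)
        refs = rng.binomial(depth, 0.8, size=500)
        rejected = np.mean(
            [binomial_ase_test(int(r), depth, 0.5) < 0.005 for r in refs]
        )
        assert rejected == pytest.approx(power, abs=0.02)

    def test_deterministic_under_seed(self):
        spec = _spec(n_individuals=10, ase_n_sites=50)
        a, _ = sim.simulate_allelic_counts(spec, np.random.default_rng(9))
        b, _ = sim.simulate_allelic_counts(spec, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)
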