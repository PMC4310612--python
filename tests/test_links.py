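"""Exon groups, link counting, normalisation, coverage and fractions."""

import numpy as np
import pandas as pd
import pytest

from tissueqtl import links as lk
from tissueqtl.types import GeneModel


class TestExonGroups:
    def test_disjoint_exons_are_singletons(self):
        g = GeneModel("g", "chr1", "+", [(0, 100), (200, 300)])
        groups = lk.build_exon_groups(g)
        assert len(groups) == 2
        assert groups[0].unique_portions[0] == [(0, 100)]
        assert groups[1].unique_portions[1] == [(200, 300)]

    def test_partial_overlap_interval_subtraction(self):
        g = GeneModel("g", "chr1", "+", [(0, 100), (50, 150)])
        (grp,) = lk.build_exon_groups(g)
        assert grp.unique_portions[0] == [(0, 50)]
        assert grp.unique_portions[1] == [(100, 150)]

    def test_nested_exon_has_no_unique_portion(self):
        g = GeneModel("g", "chr1", "+", [(0, 100), (20, 80)])
        (grp,) = lk.build_exon_groups(g)
        assert grp.unique_portions[0] == [(0, 20), (80, 100)]
        assert grp.unique_portions[1] == []

    def test_unique_portions_disjoint_across_group(self):
        g = GeneModel("g", "chr1", "+", [(0, 100), (50, 150), (140, 220)])
        (grp,) = lk.build_exon_groups(g)
        flat = [iv for ivs in grp.unique_portions.values() for iv in ivs]
        flat.sort()
        for (s1, e1), (s2, e2) in zip(flat, flat[1:]):
            assert e1 <= s2


def _pairs(rows):
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "r1_start", "r1_end", "r2_start", "r2_end"]
    )


class TestCountLinks:
    def test_pair_within_one_exon_is_no_link(self, three_exon_gene):
        pairs = _pairs([("s1", "chr1", 1000, 1049, 1100, 1149)])
        lc = lk.count_links(pairs, three_exon_gene)
        assert lc.counts.size == 0

    def test_pair_across_two_exons_links(self, three_exon_gene):
        pairs = _pairs([("s1", "chr1", 1000, 1049, 2300, 2349)])
        lc = lk.count_links(pairs, three_exon_gene)
        assert lc.links[["exon_a", "exon_b"]].values.tolist() == [[0, 2]]
        assert lc.counts[0, 0] == 1

    def test_counts_additive(self, three_exon_gene):
        pairs = _pairs([("s1", "chr1", 1000, 1049, 1650, 1699)] * 100)
        lc = lk.count_links(pairs, three_exon_gene)
        assert lc.counts[0, 0] == 100

    def test_ambiguous_read_dropped_and_counted(self):
        # overlapping exons: a read overlapping unique portions of both
        g = GeneModel("g", "chr1", "+", [(0, 100), (50, 150), (300, 400)])
        pairs = _pairs([("s1", "chr1", 40, 110, 300, 349)])
        lc = lk.count_links(pairs, g)
        assert lc.n_ambiguous == 1
        assert lc.counts.sum() == 0


class TestNormalization:
    def test_zero_components_identity(self, rng):
        X = rng.poisson(20, size=(10, 5)).astype(float)
        np.testing.assert_allclose(lk.normalize_link_counts(X, n_pcs=0), X)

    def test_rank_one_batch_effect_removed(self, rng):
        n, p = 40, 8
        base = rng.poisson(500, size=(n, p)).astype(float)
        batch = np.repeat([0.0, 1.0], n // 2)
        contaminated = base * np.exp(0.8 * batch)[:, None]
        normed = lk.normalize_link_counts(contaminated, n_pcs=1)
        for j in range(p):
            r = np.corrcoef(np.log1p(normed[:, j]), batch)[0, 1]
            assert abs(r) < 0.05

    def test_permutation_equivariance(self, rng):
        X = rng.poisson(30, size=(12, 6)).astype(float)
        perm = rng.permutation(12)
        a = lk.normalize_link_counts(X, n_pcs=3)[perm]
        b = lk.normalize_link_counts(X[perm], n_pcs=3)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_constant_link_passed_through(self, rng):
        X = rng.poisson(30, size=(10, 4)).astype(float)
        X[:, 2] = 7.0
        normed = lk.normalize_link_counts(X, n_pcs=2)
        np.testing.assert_allclose(normed[:, 2], 7.0)


def brute_force_probability(len5, uniq5, len3, uniq3, insert_dist, read_len):
    """Independent oracle: literal loop over every placement of every size."""
    L = len5 + len3
    total_prob = 0.0
    for size, mass in zip(insert_dist.sizes, insert_dist.probs):
        if size < read_len or size > L:
            continue
        valid = 0
        placements = 0
        for f in range(0, L - size + 1):
            placements += 1
            r1s, r1e = f, f + read_len
            r2s, r2e = f + size - read_len, f + size
            ok1 = r1e <= len5 and any(r1s < e and r1e > s for s, e in uniq5)
            ok2 = r2s >= len5 and any(
                r2s < len5 + e and r2e > len5 + s for s, e in uniq3
            )
            if ok1 and ok2:
                valid += 1
        total_prob += mass * valid / placements
    return total_prob


class TestLinkCoverage:
    def test_probability_matches_enumeration_oracle_exactly(self, insert_dist):
        # toy geometries up to 5 exons / 3 insert sizes
        cases = [
            (100, [(0, 100)], 100, [(0, 100)]),
            (150, [(0, 150)], 80, [(10, 60)]),
            (200, [(0, 50), (120, 200)], 150, [(0, 150)]),
            (60, [(0, 60)], 60, [(0, 60)]),
        ]
        for len5, u5, len3, u3 in cases:
            got = lk.link_probability(len5, u5, len3, u3, insert_dist, 49)
            want = brute_force_probability(len5, u5, len3, u3, insert_dist, 49)
            assert got == want

    def test_fixed_insert_whole_exon_probability_one(self):
        dist = lk.InsertSizeDistribution.from_dict({200: 1.0})
        p = lk.link_probability(100, [(0, 100)], 100, [(0, 100)], dist, 50)
        assert p == 1.0

    def test_coverage_is_count_over_probability(self):
        assert lk.link_coverage(10, 0.25) == 40
        assert lk.link_coverage(7, 1.0) == 7

    def test_zero_probability_undefined(self):
        assert np.isnan(lk.link_coverage(10, 0.0))


class TestLinkFractions:
    def _table(self):
        links = pd.DataFrame({"exon_a": [0, 0, 1], "exon_b": [1, 2, 2]})
        return links

    def test_fractions_normalise_per_primary(self):
        links = self._table()
        cov = np.array([[6.0, 2.0, 2.0]])
        frac = lk.link_fractions(cov, links, "+", "forward")
        # primary exon 0 makes links 0-1 and 0-2; exon 1 makes 1-2
        np.testing.assert_allclose(frac[0], [0.75, 0.25, 1.0])

    def test_single_link_fraction_one(self):
        links = pd.DataFrame({"exon_a": [0], "exon_b": [1]})
        frac = lk.link_fractions(np.array([[5.0]]), links, "+", "forward")
        assert frac[0, 0] == 1.0

    def test_zero_coverage_missing_not_zero(self):
        links = self._table()
        frac = lk.link_fractions(np.zeros((1, 3)), links, "+", "forward")
        assert np.isnan(frac).all()

    def test_fractions_sum_to_one_or_missing(self, rng):
        links = self._table()
        cov = rng.uniform(0, 10, size=(20, 3))
        for direction in ("forward", "reverse"):
            frac = lk.link_fractions(cov, links, "+", direction)
            prim = lk.primary_exons(links, "+", direction)
            for p in np.unique(prim):
                s = np.nansum(frac[:, prim == p], axis=1)
                assert np.allclose(s[~np.isnan(s)], 1.0)

    def test_reverse_direction_swaps_primary(self):
        links = self._table()
        np.testing.assert_array_equal(
            lk.primary_exons(links, "+", "forward"), [0, 0, 1]
        )
        np.testing.assert_array_equal(
            lk.primary_exons(links, "+", "reverse"), [1, 2, 2]
        )
        # minus strand: 5'-most is the genomically-right exon
        np.testing.assert_array_equal(
            lk.primary_exons(links, "-", "forward"), [1, 2, 2]
        )


class TestFilterLinks:
    def _setup(self, three_exon_gene, counts):
        links = pd.DataFrame({"exon_a": [0, 0], "exon_b": [1, 2]})
        frac = lk.link_fractions(counts.astype(float), links, "+", "forward")
        return links, frac

    def test_group_below_ten_links_excluded(self, three_exon_gene):
        counts = np.full((10, 2), 4)  # group total 8 < 10 everywhere
        links, frac = self._setup(three_exon_gene, counts)
        keep = lk.filter_links(counts, frac, links, three_exon_gene, "forward")
        assert not keep.any()

    def test_nonvariable_fraction_excluded(self, three_exon_gene):
        counts = np.full((100, 2), 20)
        counts[:4, 0] = 10  # 96% of samples share the modal fraction
        links, frac = self._setup(three_exon_gene, counts)
        keep = lk.filter_links(counts, frac, links, three_exon_gene, "forward")
        assert not keep.any()

    def test_passing_link_retained(self, three_exon_gene, rng):
        counts = rng.poisson(20, size=(50, 2)) + 1
        links, frac = self._setup(three_exon_gene, counts)
        keep = lk.filter_links(counts, frac, links, three_exon_gene, "forward")
        assert keep.all()


class TestDifferentialUsage:
    def test_strong_separation_tiny_p(self, rng):
        a = rng.normal(0.2, 0.05, 50)
        b = rng.normal(0.8, 0.05, 50)
        t, p = lk.differential_link_usage(a, b)
        assert p < 1e-10

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            a = rng.normal(0.5, 0.1, 30)
            b = rng.normal(0.5, 0.1, 30)
            ps.append(lk.differential_link_usage(a, b)[1])
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            lk.differential_link_usage([0.5], [0.4, 0.6])

    def test_zero_variance_both_groups_undefined(self):
        t, p = lk.differential_link_usage([0.5, 0.5], [0.5, 0.5])
        assert np.isnan(p)
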