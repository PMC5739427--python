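"""GRM construction, empirical Me, chromosome-level LD and tier splitting."""

import warnings

import numpy as np
import pytest

from gpplan import (
    GRM,
    GenomeModel,
    GenotypeMatrix,
    build_grm,
    combine_chromosome_variances,
    cross_relationship_variance,
    empirical_me,
    me_theoretical,
    per_chromosome_me,
    qc_filter,
    split_reference_by_relatedness,
)


def geno(dosage, chrom=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        chromosome_of_snp=np.ones(m, dtype=int) if chrom is None else np.asarray(chrom),
        dosage=dosage,
    )


def grm_from_values(values, ids=None):
    n = values.shape[0]
    ids = ids or [f"i{k}" for k in range(n)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GRM(individual_ids=ids, values=values)


class TestBuildGrm:
    def test_single_snp_hand_standardization(self):
        """Dosages (0, 2) at f=0.5 standardize to -/+ sqrt(2): off-diagonal -2."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 1-SNP GRM has diagonal 2
            g = build_grm(geno([[0], [2]]))
        assert g.values[0, 1] == pytest.approx(-2.0)
        assert g.values[0, 0] == pytest.approx(2.0)
        assert g.n_snps == 1

    def test_identical_rows_give_offdiagonal_equal_diagonal(self):
        d = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]])
        g = build_grm(geno(d))
        assert g.values[0, 1] == pytest.approx(g.values[0, 0], rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (8, 30)).astype(np.int8)
        g = build_grm(geno(d))
        perm = rng.permutation(8)
        gp = build_grm(geno(d[perm]))
        assert np.allclose(gp.values, g.values[np.ix_(perm, perm)], atol=1e-12)

    def test_monomorphic_snps_excluded_from_m(self):
        d = np.array([[0, 2, 2], [2, 2, 0], [1, 2, 1]])  # middle SNP monomorphic
        g = build_grm(geno(d))
        assert g.n_snps == 2
        g_only = build_grm(geno(d[:, [0, 2]]))
        assert np.allclose(g.values, g_only.values)

    def test_all_monomorphic_is_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm(geno([[2, 0], [2, 0]]))

    def test_missing_dosages_contribute_zero(self):
        """A missing call equals mean imputation: zero after centering."""
        d_missing = np.array([[0, -1], [2, 0], [1, 2], [1, 1]], dtype=np.int8)
        g = build_grm(geno(d_missing))
        # individual 0's relationship through SNP 1 must vanish
        x1 = g.values[0, 1]
        freq = np.array([1, 3 / 6])  # SNP0 freq from all, SNP1 from 3 observed
        z = lambda dval, f: (dval - 2 * f) / np.sqrt(2 * f * (1 - f))
        expect = (z(0, 4 / 8) * z(2, 4 / 8) + 0.0) / 2
        assert x1 == pytest.approx(expect, rel=1e-12)

    def test_unrelated_panel_mean_near_zero(self, grm_ne50):
        off = grm_ne50.values[np.triu_indices(grm_ne50.n_individuals, 1)]
        assert abs(off.mean()) < 0.01

    def test_diagonal_approaches_one_with_many_markers(self, grm_ne50):
        assert np.mean(np.diag(grm_ne50.values)) == pytest.approx(1.0, abs=0.1)


class TestCrossRelationshipVariance:
    def test_constant_relationships_zero_variance(self):
        v = np.zeros((4, 4))
        v[0, 1:] = v[1:, 0] = 0.2
        v[np.diag_indices(4)] = 1.0
        g = grm_from_values(v)
        out = cross_relationship_variance(g, ["i0"], ["i1", "i2", "i3"])
        assert out[0] == pytest.approx(0.0, abs=1e-15)

    def test_hand_variance_with_n_minus_one(self):
        v = np.eye(5)
        v[0, 1] = v[1, 0] = 0.5
        g = grm_from_values(v)
        out = cross_relationship_variance(g, ["i0"], ["i1", "i2", "i3", "i4"])
        assert out[0] == pytest.approx(0.0625)

    def test_overlap_rejected(self):
        g = grm_from_values(np.eye(3))
        with pytest.raises(ValueError, match="overlap"):
            cross_relationship_variance(g, ["i0"], ["i0", "i1"])

    def test_small_reference_rejected(self):
        g = grm_from_values(np.eye(3))
        with pytest.raises(ValueError):
            cross_relationship_variance(g, ["i0"], ["i1"])


class TestEmpiricalMe:
    def test_homogeneous_reference_is_error(self):
        v = np.zeros((4, 4))
        v[np.diag_indices(4)] = 1.0
        g = grm_from_values(v)
        with pytest.raises(ValueError, match="infinite Me"):
            empirical_me(g, ["i0"], ["i1", "i2", "i3"])

    def test_median_vs_mean_on_skewed_variances(self):
        """Nine targets with variance 0.001 and one with 0.01: the median
        route gives Me=1000, the mean route ~526."""
        n_t = 10
        values = np.eye(n_t + 2)
        for t in range(n_t):
            # var (ddof=1) of relationships (x, -x) is 2 x^2
            x = np.sqrt(0.01 / 2) if t == 0 else np.sqrt(0.001 / 2)
            values[t, n_t] = values[n_t, t] = x
            values[t, n_t + 1] = values[n_t + 1, t] = -x
        g = grm_from_values(values)
        targets = [f"i{t}" for t in range(n_t)]
        refs = [f"i{n_t}", f"i{n_t + 1}"]
        med = empirical_me(g, targets, refs, aggregation="median")
        mean = empirical_me(g, targets, refs, aggregation="mean")
        assert med.me == pytest.approx(1000.0, rel=1e-9)
        assert mean.me == pytest.approx(1.0 / 0.0019, rel=1e-9)
        assert med.aggregation == "median" and med.n_targets == n_t

    def test_gene_dropped_panel_matches_theory(self, grm_ne50, panel_ne50):
        """Empirical Me from a gene-dropped Ne=50 panel is within 20% of the
        closed-form value."""
        ids = grm_ne50.individual_ids
        targets, refs = ids[:100], ids[100:]
        est = empirical_me(grm_ne50, targets, refs, aggregation="mean")
        theory = me_theoretical(GenomeModel(50)).me
        assert est.me == pytest.approx(theory, rel=0.20)

    def test_invalid_aggregation(self, grm_ne50):
        with pytest.raises(ValueError):
            empirical_me(grm_ne50, ["sim_0"], ["sim_1", "sim_2"], aggregation="mode")


class TestPerChromosomeMe:
    def test_perfect_ld_gives_one(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        d = np.stack([col, col, col], axis=1)
        assert per_chromosome_me(geno(d), 1) == pytest.approx(1.0, rel=1e-12)

    def test_uncorrelated_snps_give_marker_count(self):
        d = np.array([[0, 0], [0, 2], [2, 0], [2, 2]])
        assert per_chromosome_me(geno(d), 1) == pytest.approx(2.0, rel=1e-12)

    def test_against_corrcoef_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (40, 12)).astype(np.int8)
        me = per_chromosome_me(geno(d), 1)
        r2 = np.corrcoef(d.T) ** 2
        assert me == pytest.approx(12**2 / r2.sum(), rel=1e-10)

    def test_bounded_by_marker_count(self, panel_ne50):
        me1 = per_chromosome_me(panel_ne50, 1)
        m1 = int((panel_ne50.chromosome_of_snp == 1).sum())
        assert 1.0 <= me1 <= m1

    def test_chromosome_level_theory_agreement(self, panel_ne50):
        """Per-chromosome Me on gene-dropped data within 25% of 1/v."""
        from gpplan import chromosome_segment_variance

        v = chromosome_segment_variance(GenomeModel(50, n_chromosomes=1))
        mes = [per_chromosome_me(panel_ne50, c) for c in (1, 7, 19)]
        assert np.mean(mes) == pytest.approx(1.0 / v, rel=0.25)

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            per_chromosome_me(geno([[0], [2]]), 1)


class TestCombineChromosomeVariances:
    def test_single_chromosome_inverse(self):
        assert combine_chromosome_variances([0.004], ne=500) == pytest.approx(250.0)

    def test_thirty_equal_variances_reproduce_whole_genome_value(self):
        me = combine_chromosome_variances([0.0033026] * 30, ne=1000)
        assert round(me) == 2313

    def test_large_ne_limit(self):
        v = [0.002] * 10
        me = combine_chromosome_variances(v, ne=1e12)
        assert me == pytest.approx(10 / 0.002, rel=1e-6)


class TestTierSplitting:
    def test_threshold_above_everything_empty_tier(self, grm_ne50):
        ids = grm_ne50.individual_ids
        tiers = split_reference_by_relatedness(grm_ne50, ids[:50], thresholds=[99.0], fractions=[1.0], seed=1)
        assert tiers[0] == []
        assert len(tiers[1]) == len(ids) - 50

    def test_fraction_one_low_threshold_takes_all(self, grm_ne50):
        ids = grm_ne50.individual_ids
        tiers = split_reference_by_relatedness(grm_ne50, ids[:50], thresholds=[-10.0], fractions=[1.0], seed=1)
        assert len(tiers[0]) == len(ids) - 50
        assert tiers[1] == []

    def test_deterministic_under_seed(self, grm_ne50):
        ids = grm_ne50.individual_ids
        a = split_reference_by_relatedness(grm_ne50, ids[:50], [0.3, 0.1], [0.5, 0.8], seed=42)
        b = split_reference_by_relatedness(grm_ne50, ids[:50], [0.3, 0.1], [0.5, 0.8], seed=42)
        assert a == b

    def test_tier_me_ordering_follows_relatedness(self, grm_ne50):
        """Closer tiers have smaller Me (larger relationship variance)."""
        ids = grm_ne50.individual_ids
        targets = ids[:100]
        tiers = split_reference_by_relatedness(grm_ne50, targets, [0.3, 0.1], [0.5, 0.8], seed=3)
        mes = [empirical_me(grm_ne50, targets, t).me for t in tiers if len(t) >= 2]
        assert mes == sorted(mes)

    def test_weighted_me_consistency_on_tiers(self, grm_ne50):
        """1/Me(combined) ~ sum p_k / Me(tier k) on a tiered panel (15%)."""
        ids = grm_ne50.individual_ids
        targets = ids[:100]
        reference = ids[100:]
        tiers = split_reference_by_relatedness(grm_ne50, targets, [0.3, 0.1], [0.5, 0.8], seed=3, reference_ids=reference)
        combined = empirical_me(grm_ne50, targets, reference)
        inv_expected = sum(
            (len(t) / len(reference)) / empirical_me(grm_ne50, targets, t).me
            for t in tiers
            if len(t) >= 2
        )
        assert 1.0 / combined.me == pytest.approx(inv_expected, rel=0.15)

    def test_validation(self, grm_ne50):
        with pytest.raises(ValueError, match="descending"):
            split_reference_by_relatedness(grm_ne50, ["sim_0"], [0.1, 0.3], [0.5, 0.5])
        with pytest.raises(ValueError, match="empty reference"):
            split_reference_by_relatedness(grm_ne50, grm_ne50.individual_ids, [0.3], [0.5])


class TestQc:
    def test_filters_low_call_and_rare_snps(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, (80, 30)).astype(np.int8)
        d[:8, 0] = -1  # SNP 0: call rate 0.9; individuals keep 29/30
        d[:, 1] = 0
        d[0, 1] = 1  # SNP 1: MAF 1/160 < 0.01
        out = qc_filter(geno(d), maf=0.01, snp_call_rate=0.95)
        assert out.n_individuals == 80
        assert "s0" not in out.snp_ids and "s1" not in out.snp_ids
        assert {"s2", "s3", "s4"} <= set(out.snp_ids)

    def test_filters_low_call_individuals(self):
        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, (10, 20)).astype(np.int8)
        d[0, :5] = -1  # individual 0: call rate 0.75
        out = qc_filter(geno(d), individual_call_rate=0.95)
        assert "i0" not in out.individual_ids and out.n_individuals == 9

    def test_hwe_flag_drops_extreme_disequilibrium(self):
        d = np.ones((60, 3), dtype=np.int8)  # SNP columns all heterozygous
        d[:, 1] = np.tile([0, 2], 30)  # SNP 1 in HWE-compatible spread? no hets at all
        d[:30, 2] = 0
        d[30:, 2] = 1  # SNP 2 mixture
        out = qc_filter(geno(d), maf=0.0, hwe_p=1e-4)
        assert "s0" not in out.snp_ids  # all-het SNP grossly violates HWE
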