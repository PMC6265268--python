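import numpy as np
import pytest

from conftest import decay_matrix, make_matrix
from lowhic.genome import ChromosomeSet, make_bins
from lowhic.matrix import (
    BALANCED,
    RAW,
    BalancingError,
    ContactMatrix,
    _sinkhorn,
    bin_pairs,
    difference_matrix,
    distance_stratified_correlation,
    expected_by_distance,
    kr_balance,
    mask_low_coverage,
    oe_transform,
)
from lowhic.pairs import ValidPair


def vp(chrom1, pos1, chrom2, pos2, rid="r"):
    return ValidPair(rid, chrom1, pos1, "+", chrom2, pos2, "+")


class TestBinPairs:
    def test_counting(self, two_chrom_bins):
        pairs = [vp("chr1", 10, "chr1", 60_000, rid=f"r{i}") for i in range(3)]
        m = bin_pairs(pairs, two_chrom_bins)
        assert m.matrix[0, 1] == 3 and m.matrix[1, 0] == 3

    def test_diagonal(self, two_chrom_bins):
        m = bin_pairs([vp("chr2", 100, "chr2", 200)], two_chrom_bins)
        assert m.matrix[2, 2] == 1

    def test_mass_conservation(self, two_chrom_bins):
        rng = np.random.default_rng(0)
        pairs = [
            vp("chr1", int(rng.integers(0, 100_000)), "chr2", int(rng.integers(0, 60_000)), rid=f"r{i}")
            for i in range(57)
        ]
        m = bin_pairs(pairs, two_chrom_bins)
        assert m.mass() == 57

    def test_marginals_match_locus_recount(self, two_chrom_bins):
        rng = np.random.default_rng(1)
        pairs = []
        for i in range(200):
            c1, c2 = sorted(rng.choice(["chr1", "chr2"], size=2))
            lim1 = 100_000 if c1 == "chr1" else 60_000
            lim2 = 100_000 if c2 == "chr1" else 60_000
            pairs.append(vp(c1, int(rng.integers(lim1)), c2, int(rng.integers(lim2)), rid=f"r{i}"))
        m = bin_pairs(pairs, two_chrom_bins)
        counts = np.zeros(4)
        for p in pairs:
            i = two_chrom_bins.bin_index(p.chrom1, p.pos1)
            j = two_chrom_bins.bin_index(p.chrom2, p.pos2)
            counts[i] += 1
            counts[j] += 1
        col_sums = m.matrix.sum(axis=0) + np.diagonal(m.matrix)
        assert np.array_equal(col_sums, counts)

    def test_flagged_pair_rejected(self, two_chrom_bins):
        p = vp("chr1", 10, "chr1", 60_000)
        p.flags.add("duplicate")
        with pytest.raises(ValueError):
            bin_pairs([p], two_chrom_bins)


class TestMaskLowCoverage:
    def test_direct_evaluation(self):
        m = make_matrix(np.diag([100.0, 100.0, 100.0, 5.0]))
        out = mask_low_coverage(m)
        assert list(out.mappable) == [True, True, True, False]
        assert out.matrix[3].sum() == 0

    def test_uniform_nothing_masked(self):
        m = make_matrix(np.full((5, 5), 4.0))
        assert mask_low_coverage(m).mappable.all()

    def test_zero_coverage_always_masked(self):
        vals = np.full((4, 4), 5.0)
        vals[2, :] = 0
        vals[:, 2] = 0
        out = mask_low_coverage(make_matrix(vals))
        assert not out.mappable[2]

    def test_all_empty_error(self):
        with pytest.raises(ValueError):
            mask_low_coverage(make_matrix(np.zeros((3, 3))))

    def test_requires_raw(self):
        m = make_matrix(np.ones((3, 3)), state=BALANCED)
        with pytest.raises(ValueError):
            mask_low_coverage(m)


class TestKRBalance:
    def test_equal_row_sums_identity_bias(self):
        m = make_matrix(np.array([[1.0, 2, 1], [2, 0, 2], [1, 2, 1]]))  # all row sums 4
        out = kr_balance(m)
        assert np.allclose(out.bias, out.bias[0], rtol=1e-5)
        assert np.allclose(out.matrix.sum(axis=1), 1.0, atol=1e-6)

    def test_closed_form_2x2(self):
        m = make_matrix(np.array([[4.0, 2.0], [2.0, 1.0]]))
        out = kr_balance(m)
        assert out.bias == pytest.approx([0.35355, 0.70711], abs=1e-4)
        assert np.allclose(out.matrix.sum(axis=1), 1.0, atol=1e-6)

    def test_convergence_contract(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.uniform(0.5, 2.0, (30, 30)) + np.eye(30))
        sym = make_matrix((m.matrix + m.matrix.T) / 2)
        out = kr_balance(sym, tol=1e-8)
        assert np.abs(out.matrix[out.mappable].sum(axis=1) - 1).max() < 1e-8

    def test_agrees_with_sinkhorn_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.uniform(0.1, 1.0, (20, 20))
            a = (a + a.T) / 2
            out = kr_balance(make_matrix(a, bin_size=1000), tol=1e-10)
            oracle = _sinkhorn(a, 1e-12)
            assert np.allclose(out.bias, oracle, rtol=1e-4)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 1.0, (15, 15))
        out = kr_balance(make_matrix((a + a.T) / 2))
        assert np.allclose(out.matrix, out.matrix.T)

    def test_masked_bins_undefined_bias(self):
        vals = np.full((5, 5), 3.0)
        vals[4, :] = 0
        vals[:, 4] = 0
        masked = mask_low_coverage(make_matrix(vals))
        out = kr_balance(masked)
        assert np.isnan(out.bias[4])
        assert np.isfinite(out.bias[:4]).all()

    def test_per_chromosome_mode(self, two_chrom_bins):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.5, 1.5, (4, 4))
        m = ContactMatrix(two_chrom_bins, (a + a.T) / 2)
        out = kr_balance(m, per_chromosome=True)
        # trans pixels are zeroed; each cis block has unit row sums
        assert out.matrix[0, 2] == 0
        assert np.allclose(out.matrix[:2, :2].sum(axis=1), 1.0, atol=1e-6)

    def test_non_convergence_raises(self):
        # a mappable zero row cannot be balanced
        vals = np.ones((3, 3))
        vals[1, :] = 0
        vals[:, 1] = 0
        m = make_matrix(vals)
        with pytest.raises(BalancingError):
            kr_balance(m, max_iter=5)


class TestExpectedByDistance:
    def test_constant_diagonals(self):
        m = decay_matrix(10, alpha=1.0)
        prof = expected_by_distance(m)
        d = np.arange(10)
        assert np.allclose(prof.expected["chr1"], (d + 1.0) ** -1.0)

    def test_hand_sum(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 2
        vals[1, 2] = vals[2, 1] = 4
        m = make_matrix(vals, state=BALANCED)
        prof = expected_by_distance(m)
        assert prof.expected["chr1"][1] == pytest.approx(3.0)

    def test_masked_aware(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 2
        vals[1, 2] = vals[2, 1] = 4
        vals[0, 2] = vals[2, 0] = 8
        mappable = np.array([True, False, True])
        m = make_matrix(vals, state=BALANCED, mappable=mappable)
        prof = expected_by_distance(m)
        # only the (0,2) pair remains at d=2; d=1 has no mappable pairs
        assert prof.expected["chr1"][2] == pytest.approx(8.0)
        assert np.isnan(prof.expected["chr1"][1])
        assert prof.n_possible["chr1"][1] == 0


class TestOETransform:
    def test_constructed_constant(self):
        n = 12
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        e = (d + 1.0) ** -1.2
        profile = expected_by_distance(make_matrix(e, state=BALANCED))
        m = make_matrix(2.5 * e, state=BALANCED)
        oe = oe_transform(m, profile)
        assert np.allclose(oe.matrix, 2.5)

    def test_per_distance_mean_is_one(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.1, 1.0, (15, 15))
        m = make_matrix((vals + vals.T) / 2, state=BALANCED)
        oe = oe_transform(m)
        for d in range(15):
            diag = np.diagonal(oe.matrix, d)
            assert abs(np.nanmean(diag) - 1.0) < 1e-10

    def test_masked_stays_undefined(self):
        vals = np.ones((5, 5))
        mappable = np.array([True, True, False, True, True])
        m = make_matrix(vals, state=BALANCED, mappable=mappable)
        oe = oe_transform(m)
        assert np.isnan(oe.matrix[2]).all()

    def test_requires_balanced(self):
        m = make_matrix(np.ones((4, 4)), state=RAW)
        with pytest.raises(ValueError):
            oe_transform(m)
        # explicit opt-out for coverage-uniform input
        out = oe_transform(m, require_balanced=False)
        assert np.allclose(out.matrix, 1.0)


class TestDifferenceMatrix:
    def test_identity_zero(self):
        rng = np.random.default_rng(8)
        a = make_matrix(rng.uniform(0.5, 1, (6, 6)), state=BALANCED)
        d = difference_matrix(a, a)
        assert np.all(d[np.isfinite(d)] == 0)

    def test_zero_in_both_masked(self):
        a = make_matrix(np.eye(3), state=BALANCED)
        b = make_matrix(np.eye(3), state=BALANCED)
        d = difference_matrix(a, b)
        assert np.isnan(d[0, 1])
        assert d[0, 0] == 0

    def test_one_sided_signal_retained_in_both_mode(self):
        a = make_matrix(np.eye(3) + np.diag([1, 1], 1) + np.diag([1, 1], -1), state=BALANCED)
        b = make_matrix(np.eye(3), state=BALANCED)
        assert difference_matrix(a, b, "both")[0, 1] == 1
        assert np.isnan(difference_matrix(a, b, "any")[0, 1])

    def test_planted_gain_is_positive(self):
        base = decay_matrix(20)
        gained = base.copy()
        gained.matrix[5:10, 5:10] *= 3
        d = difference_matrix(gained, base)
        assert np.nanmean(d[5:10, 5:10]) > 0
        assert abs(np.nanmean(d[12:18, 12:18])) < 1e-12

    def test_mismatched_bins_rejected(self, two_chrom_bins):
        a = ContactMatrix(two_chrom_bins, np.ones((4, 4)), state=BALANCED)
        b = make_matrix(np.ones((4, 4)), bin_size=25_000, state=BALANCED)
        with pytest.raises(ValueError):
            difference_matrix(a, b)


class TestStratifiedCorrelation:
    def test_self_correlation(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.1, 1, (20, 20))
        a = make_matrix((vals + vals.T) / 2, state=BALANCED)
        df = distance_stratified_correlation(a, a, 250_000)
        defined = df["pearson_r"].dropna()
        assert np.allclose(defined, 1.0)

    def test_anti_correlation(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(0.1, 1, (20, 20))
        vals = (vals + vals.T) / 2
        a = make_matrix(vals, state=BALANCED)
        b = make_matrix(5.0 - vals, state=BALANCED)
        df = distance_stratified_correlation(a, b, 250_000)
        assert df["pearson_r"].dropna().iloc[0] == pytest.approx(-1.0)

    def test_stratum_width_in_diagonals(self):
        a = decay_matrix(20)  # 50 kb bins
        df = distance_stratified_correlation(a, a, 250_000)
        # 250 kb strata at 50 kb = 5 diagonals each; 20 bins -> 4 strata
        assert len(df) == 4
        assert df["n_pixels"].iloc[0] == sum(20 - d for d in range(5))
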