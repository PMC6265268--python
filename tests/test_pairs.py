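import itertools

import numpy as np
import pytest

from lowhic.genome import ChromosomeSet, make_bins
from lowhic.pairs import (
    AlignedRead,
    RawPair,
    ValidPair,
    assign_fragments,
    cis_trans_ratio,
    classify_read_group,
    compute_stats,
    deduplicate,
    filter_pairs,
    mapq_filter,
    scan_ligation_junctions,
)

ORDER = {"chr1": 0, "chr2": 1}.__getitem__


def vp(chrom1, pos1, s1, chrom2, pos2, s2, f1=-1, f2=-1, d1=0, d2=0, rid="r"):
    return ValidPair(rid, chrom1, pos1, s1, chrom2, pos2, s2, f1, f2, d1, d2)


class TestJunctionScan:
    def test_single_junction(self):
        assert scan_ligation_junctions("AAAAGATCGATCTTTT") == ["AAAAGATC", "GATCTTTT"]

    def test_no_junction_identity(self):
        assert scan_ligation_junctions("ACGTACGT") == ["ACGTACGT"]

    def test_two_junctions_three_subreads(self):
        seq = "AAGATCGATCTTGATCGATCCC"
        parts = scan_ligation_junctions(seq)
        assert len(parts) == 1 + seq.count("GATCGATC")
        assert parts == ["AAGATC", "GATCTTGATC", "GATCCC"]

    def test_empty_sequence(self):
        assert scan_ligation_junctions("") == []

    def test_empty_junction_rejected(self):
        with pytest.raises(ValueError):
            scan_ligation_junctions("ACGT", "")


class TestMapqFilter:
    @pytest.mark.parametrize("mapq,kept", [(3, True), (2, False), (0, False), (60, True)])
    def test_strict_threshold(self, mapq, kept):
        reads = [AlignedRead("r", "chr1", 100, "+", mapq)]
        retained, dropped = mapq_filter(reads, 3)
        assert (len(retained) == 1) is kept
        assert dropped == (0 if kept else 1)


class TestClassify:
    def test_plain_pair(self):
        reads = [AlignedRead("r", "chr1", 1000, "+", 30), AlignedRead("r", "chr2", 5000, "-", 30)]
        p = classify_read_group(reads, ORDER)
        assert p.classification == "case_i"
        assert (p.chrom1, p.pos1, p.chrom2, p.pos2) == ("chr1", 1000, "chr2", 5000)

    def test_split_triple_merges_colocated(self):
        reads = [
            AlignedRead("r", "chr1", 1000, "+", 30),
            AlignedRead("r", "chr1", 1050, "+", 30),
            AlignedRead("r", "chr2", 5000, "-", 30),
        ]
        p = classify_read_group(reads, ORDER)
        assert p.classification == "case_ii"
        # 5'-most of the co-located reads is the representative
        assert (p.chrom1, p.pos1, p.chrom2, p.pos2) == ("chr1", 1000, "chr2", 5000)

    def test_triple_without_merge_discarded(self):
        reads = [
            AlignedRead("r", "chr1", 1000, "+", 30),
            AlignedRead("r", "chr1", 2000, "+", 30),
            AlignedRead("r", "chr2", 5000, "-", 30),
        ]
        assert classify_read_group(reads, ORDER) is None

    def test_four_reads_discarded(self):
        reads = [AlignedRead("r", "chr1", p, "+", 30) for p in (0, 200, 400, 600)]
        assert classify_read_group(reads, ORDER) is None

    def test_single_read_discarded(self):
        assert classify_read_group([AlignedRead("r", "chr1", 0, "+", 30)], ORDER) is None

    def test_canonical_ordering(self):
        reads = [AlignedRead("r", "chr2", 10, "+", 30), AlignedRead("r", "chr1", 99, "-", 30)]
        p = classify_read_group(reads, ORDER)
        assert (p.chrom1, p.chrom2) == ("chr1", "chr2")
        assert (p.strand1, p.strand2) == ("-", "+")


class TestAssignFragments:
    def test_interval_search(self, simple_fragments):
        p = assign_fragments(RawPair("r", "chr1", 3_100, "+", "chr1", 10_000, "-"), simple_fragments)
        assert p.fragment1 == 1
        assert p.site_dist1 == 100

    def test_half_open_boundary(self, simple_fragments):
        p = assign_fragments(RawPair("r", "chr1", 3_000, "+", "chr1", 10_000, "-"), simple_fragments)
        assert p.fragment1 == 1 and p.site_dist1 == 0

    def test_midpoint_distance(self, simple_fragments):
        p = assign_fragments(RawPair("r", "chr1", 6_000, "+", "chr1", 10_000, "-"), simple_fragments)
        assert p.site_dist1 == 3_000  # fragment [3k,9k) length 6k

    def test_unknown_chromosome(self, simple_fragments):
        with pytest.raises(KeyError):
            assign_fragments(RawPair("r", "chrX", 0, "+", "chr1", 0, "-"), simple_fragments)


class TestFilters:
    def test_same_fragment(self):
        p = vp("chr1", 100, "+", "chr1", 50_200, "+", f1=5, f2=5)
        filter_pairs([p])
        assert "same_fragment" in p.flags

    def test_inward_cutoff(self):
        near = vp("chr1", 100, "+", "chr1", 8_100, "-", f1=1, f2=2)
        far = vp("chr1", 100, "+", "chr1", 12_100, "-", f1=1, f2=4)
        filter_pairs([near, far])
        assert "inward_short" in near.flags
        assert not far.flags

    def test_outward_short(self):
        p = vp("chr1", 100, "-", "chr1", 8_100, "+", f1=1, f2=2)
        filter_pairs([p])
        assert "outward_short" in p.flags

    def test_same_orientation_never_flagged(self):
        p = vp("chr1", 100, "+", "chr1", 900, "+", f1=1, f2=2)
        q = vp("chr1", 100, "-", "chr1", 900, "-", f1=1, f2=2)
        filter_pairs([p, q])
        assert not p.flags and not q.flags

    def test_trans_never_orientation_flagged(self):
        p = vp("chr1", 100, "+", "chr2", 900, "-", f1=1, f2=9)
        filter_pairs([p])
        assert not p.flags

    def test_far_from_site(self):
        p = vp("chr1", 100, "+", "chr1", 90_000, "+", f1=1, f2=2, d1=6_000)
        filter_pairs([p])
        assert "far_from_site" in p.flags

    def test_flag_counts_match_naive_oracle(self):
        rng = np.random.default_rng(0)
        pairs = []
        for k in range(300):
            c1, c2 = rng.choice(["chr1", "chr2"], size=2)
            p1, p2 = sorted(rng.integers(0, 100_000, size=2))
            if c1 > c2:
                c1, c2 = c2, c1
            pairs.append(
                vp(
                    c1, int(p1), str(rng.choice(["+", "-"])),
                    c2, int(p2), str(rng.choice(["+", "-"])),
                    f1=int(rng.integers(0, 40)), f2=int(rng.integers(0, 40)),
                    d1=int(rng.integers(0, 8_000)), d2=int(rng.integers(0, 8_000)),
                    rid=f"r{k}",
                )
            )
        filter_pairs(pairs)
        for p in pairs:
            expect = set()
            if p.fragment1 == p.fragment2:
                expect.add("same_fragment")
            if p.site_dist1 > 5_000 or p.site_dist2 > 5_000:
                expect.add("far_from_site")
            if p.chrom1 == p.chrom2 and p.strand1 != p.strand2 and abs(p.pos2 - p.pos1) < 10_000:
                up = p.strand1 if p.pos1 <= p.pos2 else p.strand2
                expect.add("inward_short" if up == "+" else "outward_short")
            assert p.flags == expect


class TestDeduplicate:
    def test_within_tolerance_flagged(self):
        a = vp("chr1", 100, "+", "chr2", 200, "-", rid="a")
        b = vp("chr1", 101, "+", "chr2", 199, "-", rid="b")
        retained, n = deduplicate([a, b])
        assert n == 1 and "duplicate" in b.flags and not a.flags

    def test_beyond_tolerance_retained(self):
        a = vp("chr1", 100, "+", "chr2", 200, "-", rid="a")
        b = vp("chr1", 103, "+", "chr2", 200, "-", rid="b")
        retained, n = deduplicate([a, b])
        assert n == 0 and len(retained) == 2

    def test_strand_mismatch_not_duplicate(self):
        a = vp("chr1", 100, "+", "chr2", 200, "-", rid="a")
        b = vp("chr1", 100, "-", "chr2", 200, "-", rid="b")
        _, n = deduplicate([a, b])
        assert n == 0

    def test_k_copies_one_retained(self):
        copies = [vp("chr1", 500, "+", "chr1", 9_000, "+", rid=f"c{i}") for i in range(7)]
        retained, n = deduplicate(copies)
        assert len(retained) == 1 and n == 6

    def test_matches_brute_force_clustering(self):
        rng = np.random.default_rng(1)
        base = [
            vp("chr1", int(rng.integers(0, 2_000)), "+", "chr1", int(rng.integers(5_000, 7_000)), "-", rid=f"p{k}")
            for k in range(120)
        ]
        flagged_fast = [p.read_id for p in base if ("duplicate" in deduplicate_copy(base)[0].get(p.read_id, set()))]
        # brute-force greedy oracle
        kept: list[ValidPair] = []
        flagged_oracle = []
        for p in base:
            if any(
                q.strand1 == p.strand1 and q.strand2 == p.strand2
                and abs(q.pos1 - p.pos1) <= 2 and abs(q.pos2 - p.pos2) <= 2
                for q in kept
            ):
                flagged_oracle.append(p.read_id)
            else:
                kept.append(p)
        assert sorted(flagged_fast) == sorted(flagged_oracle)

    def test_order_stability_on_non_duplicates(self):
        rng = np.random.default_rng(2)
        pairs = [
            vp("chr1", int(p1), "+", "chr1", int(p2), "+", rid=f"u{k}")
            for k, (p1, p2) in enumerate(zip(rng.choice(10_000, 50, replace=False) * 10,
                                             rng.choice(10_000, 50, replace=False) * 10))
        ]
        loci = lambda ps: sorted((p.pos1, p.pos2) for p in ps)
        r1, _ = deduplicate([vp(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2, rid=p.read_id) for p in pairs])
        perm = list(reversed(pairs))
        r2, _ = deduplicate([vp(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2, rid=p.read_id) for p in perm])
        assert loci(r1) == loci(r2)


def deduplicate_copy(base):
    """Run deduplicate on fresh copies; return read_id -> flags."""
    fresh = [vp(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2, rid=p.read_id) for p in base]
    deduplicate(fresh)
    return {p.read_id: p.flags for p in fresh}, None


class TestStats:
    def test_partition_invariant(self):
        pairs = [
            vp("chr1", 100, "+", "chr1", 50_200, "+", f1=0, f2=0, rid="a"),  # same_fragment
            vp("chr1", 100, "+", "chr1", 8_100, "-", f1=0, f2=1, rid="b"),  # inward_short
            vp("chr1", 100, "+", "chr2", 900, "-", f1=0, f2=9, rid="c"),  # valid trans
            vp("chr1", 200, "+", "chr1", 90_000, "+", f1=0, f2=8, rid="d"),  # valid cis
        ]
        filter_pairs(pairs)
        deduplicate(pairs)
        stats = compute_stats(pairs)
        assert stats.valid + sum(stats.categories.values()) == stats.total == 4
        assert stats.cis == 1 and stats.trans == 1

    def test_first_flag_precedence(self):
        # same_fragment outranks inward_short in the accounting
        p = vp("chr1", 100, "+", "chr1", 900, "-", f1=3, f2=3)
        filter_pairs([p])
        stats = compute_stats([p])
        assert stats.categories["same_fragment"] == 1
        assert stats.categories["inward_short"] == 0


class TestCisTrans:
    def test_raw_ratio(self, two_chrom_bins):
        raw, _ = cis_trans_ratio(80, 20, two_chrom_bins)
        assert raw == 4.0

    def test_normalised_enumeration(self, two_chrom_bins):
        # 2+2 bins: intra pairs 3+3=6, inter 4, f=1.5
        raw, norm = cis_trans_ratio(6, 4, two_chrom_bins)
        assert norm == pytest.approx(1.0)

    def test_normalisation_factor_vs_enumeration(self):
        bins = make_bins(ChromosomeSet({"a": 150_000, "b": 100_000, "c": 50_000}), 50_000)
        n = bins.n_bins
        chrom = [bins.bin_of(i)[0] for i in range(n)]
        intra = sum(1 for i, j in itertools.combinations_with_replacement(range(n), 2) if chrom[i] == chrom[j])
        inter = sum(1 for i, j in itertools.combinations(range(n), 2) if chrom[i] != chrom[j])
        _, norm = cis_trans_ratio(intra, inter, bins)
        assert norm == pytest.approx(1.0)

    def test_zero_trans_undefined(self, two_chrom_bins):
        raw, norm = cis_trans_ratio(10, 0, two_chrom_bins)
        assert np.isnan(raw) and np.isnan(norm)
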