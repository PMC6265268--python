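"""Valid-pair extraction from aligned Hi-C reads.

Pipeline order: junction scanning (pre-alignment), mapping-quality filter,
read-group classification, fragment assignment, ligation-bias filtering,
duplicate removal. Filter accounting uses a fixed first-triggering-flag
order so that statistics are deterministic:

    low_mapq -> case_iii -> same_fragment -> far_from_site
    -> inward_short -> outward_short -> duplicate
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from .genome import BinTable, FragmentMap

#: filled-in re-ligated MboI site
MBOI_JUNCTION = "GATCGATC"
#: filled-in re-ligated HindIII site (configurable; by analogy with MboI)
HINDIII_JUNCTION = "AAGCTAGCTT"

FILTER_ORDER = (
    "low_mapq",
    "case_iii",
    "same_fragment",
    "far_from_site",
    "inward_short",
    "outward_short",
    "duplicate",
)


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read record (5' position, strand, mapping quality)."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    mapq: int
    is_split: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class RawPair:
    """A classified mate pair: two loci in canonical order."""

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    classification: str = "case_i"  # case_i | case_ii | case_iii_discarded


@dataclass
class ValidPair:
    """A fragment-assigned pair with filter flags; valid iff no flag is set."""

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    fragment1: int = -1
    fragment2: int = -1
    site_dist1: int = -1
    site_dist2: int = -1
    flags: set = field(default_factory=set)

    @property
    def valid(self) -> bool:
        return not self.flags

    @property
    def is_cis(self) -> bool:
        return self.chrom1 == self.chrom2

    def loci(self):
        return (self.chrom1, self.pos1, self.strand1, self.chrom2, self.pos2, self.strand2)


@dataclass
class PairStats:
    """Filter-category counts; each pair is counted once, under its first flag."""

    total: int = 0
    valid: int = 0
    categories: dict = field(default_factory=lambda: {name: 0 for name in FILTER_ORDER})
    cis: int = 0
    trans: int = 0

    @property
    def duplicate_fraction(self) -> float:
        return self.categories["duplicate"] / self.total if self.total else math.nan

    def count(self, pair: ValidPair) -> None:
        self.total += 1
        if pair.valid:
            self.valid += 1
            if pair.is_cis:
                self.cis += 1
            else:
                self.trans += 1
        else:
            for name in FILTER_ORDER:
                if name in pair.flags:
                    self.categories[name] += 1
                    break


def scan_ligation_junctions(sequence: str, junction: str = MBOI_JUNCTION) -> list[str]:
    """Split a read sequence at ligation-junction occurrences.

    Each sub-read retains half of the junction (the re-constituted
    restriction site) at the split point; a read without a junction is
    returned unchanged. An empty sequence yields no sub-reads.
    """
    if not junction:
        raise ValueError("junction must be non-empty")
    if not sequence:
        return []
    half = len(junction) // 2
    parts: list[str] = []
    rest = sequence
    while True:
        i = rest.upper().find(junction.upper())
        if i < 0:
            parts.append(rest)
            return parts
        parts.append(rest[: i + half])
        rest = rest[i + half :]


def mapq_filter(reads: list[AlignedRead], threshold: int = 3) -> tuple[list[AlignedRead], int]:
    """Drop reads with mapping quality strictly below ``threshold``."""
    kept = [r for r in reads if r.mapq >= threshold]
    return kept, len(reads) - len(kept)


def _canonical(read_id, l1, l2, classification, chrom_order):
    (c1, p1, s1), (c2, p2, s2) = l1, l2
    if (chrom_order(c1), p1) > (chrom_order(c2), p2):
        (c1, p1, s1), (c2, p2, s2) = (c2, p2, s2), (c1, p1, s1)
    return RawPair(read_id, c1, p1, s1, c2, p2, s2, classification)


def classify_read_group(
    reads: list[AlignedRead],
    chrom_order,
    merge_distance: int = 100,
) -> RawPair | None:
    """Classify all mapped reads sharing a read ID into a pair or a discard.

    2 reads: a plain pair. 3 reads (one mate was split): if two of them lie
    within ``merge_distance`` bp on the same chromosome they are merged
    (5'-most record as representative) and paired with the third; otherwise
    the group is discarded. 1 or >= 4 reads: discarded.

    ``chrom_order`` maps a chromosome name to its rank for canonical locus
    ordering (e.g. ``ChromosomeSet.order``).
    """
    if len(reads) == 2:
        a, b = reads
        return _canonical(a.read_id, (a.chrom, a.pos, a.strand), (b.chrom, b.pos, b.strand), "case_i", chrom_order)
    if len(reads) == 3:
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = reads[i], reads[j]
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= merge_distance:
                    rep = a if a.pos <= b.pos else b
                    third = reads[3 - i - j]
                    return _canonical(
                        rep.read_id,
                        (rep.chrom, rep.pos, rep.strand),
                        (third.chrom, third.pos, third.strand),
                        "case_ii",
                        chrom_order,
                    )
        return None
    return None


def assign_fragments(pair: RawPair, fragments: FragmentMap) -> ValidPair:
    """Map each locus to its restriction fragment and record site distances.

    Distance to the nearest restriction site is the distance to the closer
    fragment boundary.
    """
    f1, s1, e1 = fragments.fragment_at(pair.chrom1, pair.pos1)
    f2, s2, e2 = fragments.fragment_at(pair.chrom2, pair.pos2)
    return ValidPair(
        pair.read_id,
        pair.chrom1,
        pair.pos1,
        pair.strand1,
        pair.chrom2,
        pair.pos2,
        pair.strand2,
        fragment1=f1,
        fragment2=f2,
        site_dist1=min(pair.pos1 - s1, e1 - pair.pos1),
        site_dist2=min(pair.pos2 - s2, e2 - pair.pos2),
    )


def filter_pairs(
    pairs: list[ValidPair],
    site_distance_cutoff: int = 5000,
    orientation_cutoff: int = 10000,
) -> list[ValidPair]:
    """Apply the ligation-bias filters, setting flags in place.

    far_from_site: either locus further than ``site_distance_cutoff`` from
    its nearest restriction site. same_fragment: both loci on one fragment.
    For intra-chromosomal opposite-strand pairs closer than
    ``orientation_cutoff``: inward-facing (+/-) pairs are unligated
    fragments, outward-facing (-/+) are self-ligated. Same-orientation
    pairs are never orientation-flagged.
    """
    for p in pairs:
        if p.fragment1 == p.fragment2:
            p.flags.add("same_fragment")
        if p.site_dist1 > site_distance_cutoff or p.site_dist2 > site_distance_cutoff:
            p.flags.add("far_from_site")
        if p.is_cis and p.strand1 != p.strand2:
            separation = abs(p.pos2 - p.pos1)
            if separation < orientation_cutoff:
                upstream_strand = p.strand1 if p.pos1 <= p.pos2 else p.strand2
                if upstream_strand == "+":
                    p.flags.add("inward_short")
                else:
                    p.flags.add("outward_short")
    return pairs


def deduplicate(pairs: list[ValidPair], tolerance: int = 2) -> tuple[list[ValidPair], int]:
    """Flag PCR duplicates: both loci within ``tolerance`` bp of an earlier
    retained pair with matching chromosomes and strands. Greedy in input
    order; exactly one representative per duplicate cluster is retained.
    """
    cell = tolerance + 1
    grid: dict = defaultdict(list)
    retained: list[ValidPair] = []
    n_dup = 0
    for p in pairs:
        key = (p.chrom1, p.strand1, p.chrom2, p.strand2)
        c1, c2 = p.pos1 // cell, p.pos2 // cell
        dup = False
        for d1 in (-1, 0, 1):
            for d2 in (-1, 0, 1):
                for q1, q2 in grid.get((key, c1 + d1, c2 + d2), ()):
                    if abs(p.pos1 - q1) <= tolerance and abs(p.pos2 - q2) <= tolerance:
                        dup = True
                        break
                if dup:
                    break
            if dup:
                break
        if dup:
            p.flags.add("duplicate")
            n_dup += 1
        else:
            grid[(key, c1, c2)].append((p.pos1, p.pos2))
            retained.append(p)
    return retained, n_dup


def compute_stats(pairs: list[ValidPair]) -> PairStats:
    stats = PairStats()
    for p in pairs:
        stats.count(p)
    return stats


def cis_trans_ratio(cis: int, trans: int, bins: BinTable) -> tuple[float, float]:
    """Raw and species-normalised cis/trans ratios.

    The normalisation factor f is the ratio of possible intra-chromosomal
    bin pairs (upper triangle including the diagonal) to inter-chromosomal
    bin pairs; the normalised ratio is cis / (trans * f). With zero trans
    contacts both ratios are NaN.
    """
    if trans == 0:
        return math.nan, math.nan
    ns = [bins.n_bins_of(c) for c in bins.chromosomes]
    intra = sum(n * (n + 1) // 2 for n in ns)
    total = bins.n_bins
    inter = (total * (total + 1) // 2) - intra
    f = intra / inter
    return cis / trans, cis / (trans * f)


def process_pairs(
    raw_pairs: list[RawPair],
    fragments: FragmentMap,
    site_distance_cutoff: int = 5000,
    orientation_cutoff: int = 10000,
    dup_tolerance: int = 2,
) -> tuple[list[ValidPair], PairStats]:
    """Fragment assignment + bias filtering + deduplication + statistics.

    Returns all flagged pairs (valid and filtered) and the aggregate stats.
    """
    assigned = [assign_fragments(p, fragments) for p in raw_pairs]
    filter_pairs(assigned, site_distance_cutoff, orientation_cutoff)
    deduplicate(assigned, dup_tolerance)
    return assigned, compute_stats(assigned)


def group_reads_by_id(reads: list[AlignedRead]) -> dict[str, list[AlignedRead]]:
    groups: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        groups[r.read_id].append(r)
    return dict(groups)


def reads_to_pairs(
    reads: list[AlignedRead],
    chrom_order,
    mapq_threshold: int = 3,
    merge_distance: int = 100,
) -> tuple[list[RawPair], dict]:
    """Full read-level stage: mapq filter, grouping, classification.

    Returns the raw pairs plus discard counts keyed by reason
    (``low_mapq`` = groups reduced below pair size by the mapq filter,
    ``case_iii`` = unresolvable split groups).
    """
    discards = {"low_mapq": 0, "case_iii": 0}
    out: list[RawPair] = []
    for read_id, group in group_reads_by_id(reads).items():
        kept, n_removed = mapq_filter(group, mapq_threshold)
        if len(kept) < 2:
            if n_removed:
                discards["low_mapq"] += 1
            continue
        pair = classify_read_group(kept, chrom_order, merge_distance)
        if pair is None:
            discards["case_iii"] += 1
        else:
            out.append(pair)
    return out, discards
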