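"""Ground-truth contact-map and read-pair simulator.

Every pipeline stage can be exercised on these outputs without external
data: power-law distance decay, TAD blocks, loop foci, compartment
checkerboards, reciprocal translocations, and pair-level artefacts
(duplicates, self-ligations, unligated fragments, same-fragment pairs).
All sampling is driven by a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinTable, ChromosomeSet, Enzyme, FragmentMap, make_bins
from .matrix import RAW, ContactMatrix
from .pairs import RawPair


@dataclass
class TadSpec:
    chrom: str
    start: int  # bp
    end: int
    multiplier: float = 3.0


@dataclass
class LoopSpec:
    chrom: str
    pos1: int  # bp
    pos2: int
    fold: float = 4.0
    sigma_bins: float = 1.0


@dataclass
class MapSpec:
    """Parameters for one synthetic contact map. ``seed`` is mandatory."""

    chrom_lengths: dict[str, int]
    resolution: int
    seed: int
    alpha: float = 1.0
    depth: float = 1_000_000
    tads: list[TadSpec] = field(default_factory=list)
    loops: list[LoopSpec] = field(default_factory=list)
    compartment_block: int | None = None  # bp; alternating A/B blocks
    compartment_same: float = 1.5
    compartment_cross: float = 0.67
    masked_fraction: float = 0.0
    trans_level: float = 0.02

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for t in self.tads:
            if t.multiplier <= 0:
                raise ValueError("TAD multiplier must be positive")
        for l in self.loops:
            if l.fold <= 0:
                raise ValueError("loop fold must be positive")


@dataclass
class RearrangementSpec:
    """A (possibly reciprocal) translocation between two chromosomes."""

    chrom_a: str
    chrom_b: str
    breakpoint_a: int  # bp
    breakpoint_b: int
    reciprocal: bool = True
    intensity: float = 1.0
    lost_segments: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class PairSimSpec:
    """Parameters for simulated aligned read pairs over a fragment map."""

    fragments: FragmentMap
    n_pairs: int
    seed: int
    duplicate_fraction: float = 0.0
    self_ligation_fraction: float = 0.0  # outward-facing < cutoff
    unligated_fraction: float = 0.0  # inward-facing < cutoff
    same_fragment_fraction: float = 0.0
    trans_fraction: float = 0.1
    orientation_cutoff: int = 10_000
    min_cis_separation: int = 20_000

    def __post_init__(self) -> None:
        fracs = (
            self.duplicate_fraction,
            self.self_ligation_fraction,
            self.unligated_fraction,
            self.same_fragment_fraction,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("artefact fractions must be non-negative and sum to at most 1")


def _intensity_field(spec: MapSpec, bins: BinTable) -> np.ndarray:
    """Expected-intensity field lambda before depth scaling."""
    n = bins.n_bins
    lam = np.zeros((n, n))
    comp_label = None
    if spec.compartment_block:
        comp_label = np.zeros(n, dtype=int)
        for chrom in bins.chromosomes:
            sl = bins.chrom_slice(chrom)
            starts = bins.bin_start[sl]
            comp_label[sl] = (starts // spec.compartment_block) % 2
    for chrom in bins.chromosomes:
        sl = bins.chrom_slice(chrom)
        nc = sl.stop - sl.start
        d = np.abs(np.arange(nc)[:, None] - np.arange(nc)[None, :])
        block = (d + 1.0) ** (-spec.alpha)
        if comp_label is not None:
            lab = comp_label[sl]
            same = lab[:, None] == lab[None, :]
            block = block * np.where(same, spec.compartment_same, spec.compartment_cross)
        lam[sl, sl] = block
    for t in spec.tads:
        sl = bins.chrom_slice(t.chrom)
        b0 = sl.start + t.start // spec.resolution
        b1 = sl.start + -(-t.end // spec.resolution)
        lam[b0:b1, b0:b1] *= t.multiplier
    for l in spec.loops:
        sl = bins.chrom_slice(l.chrom)
        i = sl.start + l.pos1 // spec.resolution
        j = sl.start + l.pos2 // spec.resolution
        reach = int(np.ceil(4 * l.sigma_bins))
        for a in range(max(0, i - reach), min(n, i + reach + 1)):
            for b in range(max(0, j - reach), min(n, j + reach + 1)):
                g = np.exp(-((a - i) ** 2 + (b - j) ** 2) / (2 * l.sigma_bins**2))
                bump = 1.0 + (l.fold - 1.0) * g
                lam[a, b] *= bump
                lam[b, a] *= bump
    # flat trans background, relative to the cis diagonal level
    for i1, c1 in enumerate(bins.chromosomes):
        for c2 in list(bins.chromosomes)[i1 + 1 :]:
            s1, s2 = bins.chrom_slice(c1), bins.chrom_slice(c2)
            lam[s1, s2] = spec.trans_level
            lam[s2, s1] = spec.trans_level
    return lam


def simulate_contact_map(spec: MapSpec) -> tuple[ContactMatrix, dict]:
    """Draw a Poisson contact map from the spec's intensity field.

    Returns the raw-count matrix plus a ground-truth record (intensity
    scale, masked bins, planted feature bin coordinates).
    """
    rng = np.random.default_rng(spec.seed)
    chroms = ChromosomeSet(spec.chrom_lengths)
    bins = make_bins(chroms, spec.resolution)
    n = bins.n_bins
    lam = _intensity_field(spec, bins)
    upper_mass = np.triu(lam).sum()
    scale = spec.depth / upper_mass
    lam *= scale
    counts = np.zeros((n, n))
    iu = np.triu_indices(n)
    draws = rng.poisson(lam[iu]).astype(np.float64)
    counts[iu] = draws
    counts = counts + np.triu(counts, 1).T
    mappable = np.ones(n, dtype=bool)
    if spec.masked_fraction > 0:
        n_mask = int(round(spec.masked_fraction * n))
        masked = rng.choice(n, size=n_mask, replace=False)
        mappable[masked] = False
        counts[~mappable, :] = 0
        counts[:, ~mappable] = 0
    m = ContactMatrix(bins, counts, mappable=mappable, state=RAW)
    truth = {
        "scale": scale,
        "masked_bins": np.flatnonzero(~mappable),
        "tad_bins": [
            (
                bins.chrom_slice(t.chrom).start + t.start // spec.resolution,
                bins.chrom_slice(t.chrom).start + -(-t.end // spec.resolution),
                t.multiplier,
            )
            for t in spec.tads
        ],
        "loop_bins": [
            (
                bins.chrom_slice(l.chrom).start + l.pos1 // spec.resolution,
                bins.chrom_slice(l.chrom).start + l.pos2 // spec.resolution,
                l.fold,
            )
            for l in spec.loops
        ],
    }
    return m, truth


def inject_translocation(
    m: ContactMatrix, spec: RearrangementSpec, alpha: float = 1.0, seed: int = 0
) -> tuple[ContactMatrix, dict]:
    """Overlay cis-like decay on the trans block of a translocated pair.

    For a reciprocal t(A;B) with breakpoints (bpA, bpB), the derivative
    chromosomes join A[:bpA]+B[bpB:] and A[bpA:]+B[:bpB]; contacts between
    bins that become adjacent decay with their distance on the derivative
    chromosome. Counts are drawn Poisson at ``intensity`` times the map's
    own near-diagonal level. Optional lost segments are binomially thinned
    to half coverage (one-allele loss).
    """
    bins = m.bins
    for chrom, bp in ((spec.chrom_a, spec.breakpoint_a), (spec.chrom_b, spec.breakpoint_b)):
        if chrom not in bins.chromosomes or not 0 <= bp < bins.chromosomes.length(chrom):
            raise ValueError(f"breakpoint {chrom}:{bp} outside the genome")
    rng = np.random.default_rng(seed)
    out = m.copy()
    res = bins.bin_size
    sa, sb = bins.chrom_slice(spec.chrom_a), bins.chrom_slice(spec.chrom_b)
    na, nb = sa.stop - sa.start, sb.stop - sb.start
    bpa = spec.breakpoint_a // res
    bpb = spec.breakpoint_b // res
    # the map's own diagonal count level sets the overlay scale
    diag = np.concatenate([np.diagonal(out.matrix[sa, sa]), np.diagonal(out.matrix[sb, sb])])
    diag = diag[diag > 0]
    level = float(np.median(diag)) if diag.size else 1.0
    a_idx = np.arange(na)[:, None]
    b_idx = np.arange(nb)[None, :]
    lam = np.zeros((na, nb))
    # derivative 1: A[:bpa] joined to B[bpb:]
    q1 = (a_idx < bpa) & (b_idx >= bpb)
    d1 = (bpa - 1 - a_idx) + (b_idx - bpb) + 1
    lam[q1] = level * spec.intensity * (d1[q1] + 1.0) ** (-alpha)
    if spec.reciprocal:
        # derivative 2: B[:bpb] joined to A[bpa:]
        q2 = (a_idx >= bpa) & (b_idx < bpb)
        d2 = (a_idx - bpa) + (bpb - 1 - b_idx) + 1
        lam[q2] = level * spec.intensity * (d2[q2] + 1.0) ** (-alpha)
    add = rng.poisson(lam).astype(np.float64)
    out.matrix[sa, sb] += add
    out.matrix[sb, sa] += add.T
    n = bins.n_bins
    for chrom, start, end in spec.lost_segments:
        sl = bins.chrom_slice(chrom)
        b0 = sl.start + start // res
        b1 = sl.start + -(-end // res)
        in_seg = np.zeros(n, dtype=bool)
        in_seg[b0:b1] = True
        # thin each touching pixel exactly once, keeping symmetry
        touch = (in_seg[:, None] | in_seg[None, :]) & np.triu(np.ones((n, n), dtype=bool))
        vals = out.matrix[touch].astype(np.int64)
        out.matrix[touch] = rng.binomial(vals, 0.5).astype(np.float64)
        out.matrix = np.triu(out.matrix) + np.triu(out.matrix, 1).T
    truth = {
        "breakpoint_bins": (sa.start + bpa, sb.start + bpb),
        "reciprocal": spec.reciprocal,
    }
    return out, truth


def synthetic_fragment_map(
    chrom_lengths: dict[str, int],
    seed: int,
    mean_fragment: int = 600,
    enzyme: Enzyme | None = None,
) -> FragmentMap:
    """Random fragment map with roughly exponential fragment lengths,
    standing in for an in-silico digest during pair simulation."""
    rng = np.random.default_rng(seed)
    chroms = ChromosomeSet(chrom_lengths)
    enz = enzyme or Enzyme("MboI", "GATC", 0)
    starts: dict[str, np.ndarray] = {}
    for name in chroms:
        length = chroms.length(name)
        n_cuts = max(1, int(length / mean_fragment))
        cuts = np.sort(rng.choice(np.arange(1, length), size=min(n_cuts, length - 1), replace=False))
        starts[name] = np.concatenate([[0], cuts]).astype(np.int64)
    return FragmentMap(chromosomes=chroms, enzyme=enz, starts=starts)


def _random_locus(rng, fragments: FragmentMap, chrom: str) -> tuple[int, int, int]:
    """(position, fragment start, fragment end) uniform within a random fragment."""
    s = fragments.starts[chrom]
    i = int(rng.integers(len(s)))
    start = int(s[i])
    end = int(s[i + 1]) if i + 1 < len(s) else fragments.chromosomes.length(chrom)
    return int(rng.integers(start, end)), start, end


def simulate_read_pairs(spec: PairSimSpec) -> tuple[list[RawPair], list[str]]:
    """Simulate classified raw pairs with planted artefact classes.

    Labels (parallel to the returned pairs): 'valid', 'duplicate',
    'self_ligation', 'unligated', 'same_fragment'. Valid cis pairs are
    drawn at separations of at least ``min_cis_separation`` so that
    orientation filters only fire on planted artefacts.
    """
    rng = np.random.default_rng(spec.seed)
    frags = spec.fragments
    chroms = frags.chromosomes
    names = list(chroms)
    weights = np.array([chroms.length(c) for c in names], dtype=float)
    weights /= weights.sum()
    n_dup = int(round(spec.duplicate_fraction * spec.n_pairs))
    n_self = int(round(spec.self_ligation_fraction * spec.n_pairs))
    n_unlig = int(round(spec.unligated_fraction * spec.n_pairs))
    n_same = int(round(spec.same_fragment_fraction * spec.n_pairs))
    n_valid = spec.n_pairs - n_dup - n_self - n_unlig - n_same

    order = chroms.order
    pairs: list[RawPair] = []
    labels: list[str] = []
    k = 0

    def emit(c1, p1, s1, c2, p2, s2, label):
        nonlocal k
        if (order(c1), p1) > (order(c2), p2):
            (c1, p1, s1), (c2, p2, s2) = (c2, p2, s2), (c1, p1, s1)
        pairs.append(RawPair(f"sim{k}", c1, p1, s1, c2, p2, s2, "case_i"))
        labels.append(label)
        k += 1

    strand = lambda: "+" if rng.random() < 0.5 else "-"

    for _ in range(n_valid):
        if rng.random() < spec.trans_fraction and len(names) > 1:
            c1, c2 = rng.choice(names, size=2, replace=False, p=weights)
            p1, _, _ = _random_locus(rng, frags, c1)
            p2, _, _ = _random_locus(rng, frags, c2)
        else:
            c1 = c2 = str(rng.choice(names, p=weights))
            length = chroms.length(c1)
            while True:
                p1, _, _ = _random_locus(rng, frags, c1)
                sep = int(spec.min_cis_separation * (1.0 + rng.pareto(1.2)))
                p2 = p1 + sep if rng.random() < 0.5 else p1 - sep
                if 0 <= p2 < length:
                    break
        emit(c1, p1, strand(), c2, p2, strand(), "valid")

    def orientation_artifact(label: str, upstream_strand: str) -> None:
        # opposite-strand cis pair on different fragments, separation < cutoff
        while True:
            c = str(rng.choice(names, p=weights))
            p1, fs, fe = _random_locus(rng, frags, c)
            sep = int(rng.integers(200, spec.orientation_cutoff - 1))
            p2 = p1 + sep
            if p2 >= chroms.length(c):
                continue
            f1 = frags.fragment_at(c, p1)[0]
            f2 = frags.fragment_at(c, p2)[0]
            if f1 == f2:
                continue
            down = "-" if upstream_strand == "+" else "+"
            emit(c, p1, upstream_strand, c, p2, down, label)
            return

    for _ in range(n_self):
        orientation_artifact("self_ligation", "-")  # outward: upstream on '-'
    for _ in range(n_unlig):
        orientation_artifact("unligated", "+")  # inward: upstream on '+'
    for _ in range(n_same):
        c = str(rng.choice(names, p=weights))
        while True:
            p1, fs, fe = _random_locus(rng, frags, c)
            if fe - fs >= 2:
                break
        p2 = int(rng.integers(fs, fe))
        emit(c, p1, "+", c, p2, "+", "same_fragment")
    # duplicates: jittered copies of valid originals only — clusters then have
    # diameter <= 2 bp regardless of input order, and the duplicate flag is
    # always the first-triggering flag in the statistics
    n_sources = n_valid if n_valid > 0 else len(pairs)
    for _ in range(n_dup):
        src = pairs[int(rng.integers(n_sources))]
        j1 = int(rng.integers(-1, 2))
        j2 = int(rng.integers(-1, 2))
        emit(src.chrom1, src.pos1 + j1, src.strand1, src.chrom2, src.pos2 + j2, src.strand2, "duplicate")
    # shuffle so planted classes are interleaved
    perm = rng.permutation(len(pairs))
    return [pairs[i] for i in perm], [labels[i] for i in perm]
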