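"""Genome coordinate model: chromosomes, in-silico restriction digestion, bin tables.

All coordinates are 0-based, half-open. 1-based coordinates appear only at
the ``.pairs`` file boundary (see :mod:`lowhic.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_VALID_SITE_CHARS = set("ACGT")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site and cut offset within the site."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        if not site or not set(site) <= _VALID_SITE_CHARS:
            raise ValueError(f"invalid recognition site {self.site!r}: must be a non-empty string over ACGT")
        if not 0 <= self.cut_offset < len(site):
            raise ValueError(f"cut offset {self.cut_offset} outside site of length {len(site)}")
        if _revcomp(site) != site:
            raise ValueError(f"non-palindromic site {site!r} is not supported")
        object.__setattr__(self, "site", site)


#: REBASE definitions: MboI cuts ^GATC, HindIII cuts A^AGCTT.
ENZYMES = {
    "mboi": Enzyme("MboI", "GATC", 0),
    "hindiii": Enzyme("HindIII", "AAGCTT", 1),
}


def get_enzyme(name: str) -> Enzyme:
    try:
        return ENZYMES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(ENZYMES)}") from None


class ChromosomeSet:
    """Ordered chromosome names with lengths; order fixes genome-wide numbering."""

    def __init__(self, lengths: dict[str, int]):
        if not lengths:
            raise ValueError("empty chromosome set")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths = dict(lengths)
        self.names: tuple[str, ...] = tuple(lengths)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromosomeSet) and self.names == other.names and self._lengths == other._lengths

    def length(self, name: str) -> int:
        return self._lengths[name]

    def order(self, name: str) -> int:
        return self.names.index(name)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)


@dataclass
class FragmentMap:
    """Restriction fragments tiling each chromosome, with global indexing."""

    chromosomes: ChromosomeSet
    enzyme: Enzyme
    # per chromosome: array of fragment start positions (first is 0); ends are
    # implied by the next start and the chromosome length
    starts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        offset = 0
        self._offsets: dict[str, int] = {}
        for name in self.chromosomes:
            self._offsets[name] = offset
            offset += len(self.starts[name])
        self.n_fragments = offset

    def ends(self, chrom: str) -> np.ndarray:
        s = self.starts[chrom]
        return np.append(s[1:], self.chromosomes.length(chrom))

    def fragment_at(self, chrom: str, pos: int) -> tuple[int, int, int]:
        """Return (global index, start, end) of the fragment containing ``pos``."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chromosomes.length(chrom):
            raise ValueError(f"position {pos} outside {chrom} (length {self.chromosomes.length(chrom)})")
        s = self.starts[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        end = int(s[i + 1]) if i + 1 < len(s) else self.chromosomes.length(chrom)
        return self._offsets[chrom] + i, int(s[i]), end

    def iter_fragments(self):
        for chrom in self.chromosomes:
            s = self.starts[chrom]
            e = self.ends(chrom)
            off = self._offsets[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), off + i


class BinTable:
    """Uniform genome bins; last bin per chromosome is truncated at its end."""

    def __init__(self, chromosomes: ChromosomeSet, bin_size: int):
        if bin_size <= 0:
            raise ValueError(f"bin size must be positive, got {bin_size}")
        self.chromosomes = chromosomes
        self.bin_size = int(bin_size)
        self._offsets: dict[str, int] = {}
        self._n_bins_per_chrom: dict[str, int] = {}
        offset = 0
        for name in chromosomes:
            self._offsets[name] = offset
            n = -(-chromosomes.length(name) // bin_size)  # ceil division
            self._n_bins_per_chrom[name] = n
            offset += n
        self.n_bins = offset
        # dense per-bin arrays for fast lookup
        self.bin_chrom = np.empty(self.n_bins, dtype=object)
        self.bin_start = np.zeros(self.n_bins, dtype=np.int64)
        self.bin_end = np.zeros(self.n_bins, dtype=np.int64)
        for name in chromosomes:
            off, n = self._offsets[name], self._n_bins_per_chrom[name]
            self.bin_chrom[off : off + n] = name
            starts = np.arange(n, dtype=np.int64) * bin_size
            self.bin_start[off : off + n] = starts
            self.bin_end[off : off + n] = np.minimum(starts + bin_size, chromosomes.length(name))
        self.mappable = np.ones(self.n_bins, dtype=bool)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinTable)
            and self.bin_size == other.bin_size
            and self.chromosomes == other.chromosomes
        )

    def n_bins_of(self, chrom: str) -> int:
        return self._n_bins_per_chrom[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self._n_bins_per_chrom[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a 0-based position."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chromosomes.length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_of(self, global_index: int) -> tuple[str, int, int]:
        return (
            str(self.bin_chrom[global_index]),
            int(self.bin_start[global_index]),
            int(self.bin_end[global_index]),
        )


def make_bins(chromosomes: ChromosomeSet, bin_size: int) -> BinTable:
    """Partition the genome into equidistant bins (last bin truncated)."""
    return BinTable(chromosomes, bin_size)


def find_sites(sequence: str, site: str) -> np.ndarray:
    """All forward-strand match start positions of ``site`` in ``sequence``.

    Matching is case-insensitive; ``N`` (and any non-ACGT character) never
    matches, so assembly gaps produce no cut sites.
    """
    seq = sequence.upper()
    positions = []
    start = 0
    while True:
        i = seq.find(site, start)
        if i < 0:
            break
        positions.append(i)
        start = i + 1
    return np.asarray(positions, dtype=np.int64)


def digest_genome(sequences: dict[str, str], enzyme: Enzyme) -> FragmentMap:
    """In-silico digestion: cut every forward-strand site occurrence.

    Cut positions are ``match_start + cut_offset``; fragments are the
    intervals between consecutive cuts plus the chromosome ends.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    lengths = {name: len(seq) for name, seq in sequences.items()}
    chroms = ChromosomeSet(lengths)
    starts: dict[str, np.ndarray] = {}
    for name, seq in sequences.items():
        cuts = find_sites(seq, enzyme.site) + enzyme.cut_offset
        cuts = cuts[(cuts > 0) & (cuts < len(seq))]
        starts[name] = np.concatenate([[0], cuts]).astype(np.int64)
    return FragmentMap(chromosomes=chroms, enzyme=enzyme, starts=starts)
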