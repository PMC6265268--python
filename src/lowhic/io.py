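"""Readers and writers for the toolkit's text formats.

Conventions: BED/bedGraph/BEDPE and the matrix bin table are 0-based
half-open; the ``.pairs`` dialect is 1-based with upper-triangle locus
ordering (chrom1 <= chrom2 in genome order).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .genome import BinTable, ChromosomeSet, FragmentMap, make_bins
from .matrix import ContactMatrix
from .pairs import RawPair, ValidPair

PAIRS_HEADER = "## pairs format v1.0"
PAIRS_COLUMNS = "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2"


class FormatError(ValueError):
    pass


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Multi-record, wrapped-line FASTA into name -> sequence."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def _atomic_write(path: str | os.PathLike, lines) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for line in lines:
            fh.write(line)
            fh.write("\n")
    os.replace(tmp, path)


def write_pairs(path, pairs: list, chrom_order) -> None:
    """Write pairs in the 4DN-style text dialect (1-based positions).

    Loci are canonicalised to upper-triangle order on write.
    """
    lines = [PAIRS_HEADER, PAIRS_COLUMNS]
    for p in pairs:
        c1, p1, s1 = p.chrom1, p.pos1, p.strand1
        c2, p2, s2 = p.chrom2, p.pos2, p.strand2
        if (chrom_order(c1), p1) > (chrom_order(c2), p2):
            (c1, p1, s1), (c2, p2, s2) = (c2, p2, s2), (c1, p1, s1)
        lines.append(f"{p.read_id}\t{c1}\t{p1 + 1}\t{c2}\t{p2 + 1}\t{s1}\t{s2}")
    _atomic_write(path, lines)


def read_pairs(path) -> list[RawPair]:
    out: list[RawPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            rid, c1, p1, c2, p2, s1, s2 = fields
            try:
                pos1, pos2 = int(p1) - 1, int(p2) - 1
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            if s1 not in "+-" or s2 not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand")
            out.append(RawPair(rid, c1, pos1, s1, c2, pos2, s2, "case_i"))
    return out


def write_matrix(prefix, m: ContactMatrix) -> tuple[str, str]:
    """Write a matrix as <prefix>.bins.bed + <prefix>.coo.tsv.

    The bin BED carries chrom/start/end/global-index/mappable-flag plus a
    bias column when a bias vector is present; the COO file lists
    upper-triangle non-zero entries (NaN entries are dropped).
    """
    bins_path = f"{prefix}.bins.bed"
    coo_path = f"{prefix}.coo.tsv"
    b = m.bins
    lines = []
    for i in range(b.n_bins):
        chrom, start, end = b.bin_of(i)
        row = f"{chrom}\t{start}\t{end}\t{i}\t{int(m.mappable[i])}"
        if m.bias is not None:
            row += f"\t{float(m.bias[i])!r}"
        lines.append(row)
    _atomic_write(bins_path, lines)
    iu = np.triu_indices(m.n_bins)
    vals = m.matrix[iu]
    keep = np.isfinite(vals) & (vals != 0)
    lines = [f"# state={m.state}\tresolution={m.resolution}"]
    for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep]):
        lines.append(f"{i}\t{j}\t{float(v)!r}")
    _atomic_write(coo_path, lines)
    return bins_path, coo_path


def read_matrix(bins_path, coo_path) -> ContactMatrix:
    chrom_lengths: dict[str, int] = {}
    mappable = []
    bias = []
    bin_sizes = []
    with open(bins_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) not in (5, 6):
                raise FormatError(f"{bins_path}:{lineno}: expected 5 or 6 columns")
            chrom, start, end, _idx, flag = fields[:5]
            start, end = int(start), int(end)
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end)
            mappable.append(bool(int(flag)))
            bias.append(float(fields[5]) if len(fields) == 6 else np.nan)
            bin_sizes.append(end - start)
    if not bin_sizes:
        raise FormatError(f"{bins_path}: empty bin table")
    bin_size = max(bin_sizes)
    bins = make_bins(ChromosomeSet(chrom_lengths), bin_size)
    if bins.n_bins != len(mappable):
        raise FormatError(f"{bins_path}: bin table is not a uniform tiling")
    n = bins.n_bins
    matrix = np.zeros((n, n))
    state = "raw"
    with open(coo_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].split("\t"):
                    if token.strip().startswith("state="):
                        state = token.strip().split("=", 1)[1]
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{coo_path}:{lineno}: expected 3 columns")
            i, j, v = int(fields[0]), int(fields[1]), float(fields[2])
            if not (0 <= i < n and 0 <= j < n):
                raise FormatError(f"{coo_path}:{lineno}: index ({i},{j}) outside bin table")
            if j < i:
                raise FormatError(f"{coo_path}:{lineno}: lower-triangle entry ({i},{j})")
            matrix[i, j] = v
            matrix[j, i] = v
    cm = ContactMatrix(bins, matrix, mappable=np.array(mappable, dtype=bool), state=state)
    bias_arr = np.array(bias)
    if np.isfinite(bias_arr).any():
        cm.bias = bias_arr
    cm.bins.mappable = cm.mappable.copy()
    return cm


def write_bed(path, intervals: list[tuple]) -> None:
    """Intervals as (chrom, start, end[, name[, score]])."""
    _atomic_write(path, ("\t".join(str(x) for x in iv) for iv in intervals))


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out


def write_bedgraph(path, bins: BinTable, values: np.ndarray) -> None:
    lines = []
    for i, v in enumerate(values):
        if np.isnan(v):
            continue
        chrom, start, end = bins.bin_of(i)
        lines.append(f"{chrom}\t{start}\t{end}\t{float(v)!r}")
    _atomic_write(path, lines)


def write_bedpe(path, records: list[tuple]) -> None:
    """Records as (chrom1, start1, end1, chrom2, start2, end2, *extra)."""
    _atomic_write(path, ("\t".join(str(x) for x in rec) for rec in records))


def read_bedpe(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 BEDPE columns")
            out.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), *f[6:]))
    return out


def write_fragments_bed(path, fragments: FragmentMap) -> None:
    write_bed(path, [(c, s, e, i) for c, s, e, i in fragments.iter_fragments()])


def write_bins_bed(path, bins: BinTable) -> None:
    write_bed(
        path,
        [(*bins.bin_of(i), i, int(bins.mappable[i])) for i in range(bins.n_bins)],
    )


def write_expected(path, profile) -> None:
    lines = ["chrom\tdistance_bp\texpected\tn_possible"]
    for chrom, e in profile.expected.items():
        counts = profile.n_possible[chrom]
        for d in range(len(e)):
            if counts[d] > 0:
                lines.append(f"{chrom}\t{d * profile.resolution}\t{float(e[d])!r}\t{counts[d]}")
    _atomic_write(path, lines)


def read_sam_reads(path, use_5prime: bool = True):
    """SAM/BAM records into :class:`lowhic.pairs.AlignedRead` objects.

    The 5' mapping position is the leftmost aligned base for + strand
    reads and the rightmost for - strand reads.
    """
    import pysam

    from .pairs import AlignedRead

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            if use_5prime and rec.is_reverse:
                pos = rec.reference_end - 1
            else:
                pos = rec.reference_start
            reads.append(
                AlignedRead(
                    rec.query_name,
                    rec.reference_name,
                    pos,
                    strand,
                    rec.mapping_quality,
                    is_split=rec.is_supplementary or rec.has_tag("SA"),
                )
            )
    return reads


def read_tsv_reads(path):
    """Aligned-read TSV dialect: read_id, chrom, pos, strand, mapq."""
    from .pairs import AlignedRead

    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            reads.append(AlignedRead(f[0], f[1], int(f[2]), f[3], int(f[4])))
    return reads
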