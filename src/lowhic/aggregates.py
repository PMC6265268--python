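"""Aggregate (average) matrix analysis over region and anchor-pair sets,
plus TAD-strength and loop-strength ratio statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix


@dataclass
class AggregateResult:
    """Elementwise average of resampled sub-matrices."""

    mean_matrix: np.ndarray
    n_instances: int
    n_skipped: int
    strengths: list[float] = field(default_factory=list)


def resample_nearest(sub: np.ndarray, grid: int) -> np.ndarray:
    """Nearest-neighbour resample of a square matrix to grid x grid.

    Source index for output i is floor(i * n / grid) — the classic
    'nearest' imresize mapping.
    """
    n = sub.shape[0]
    idx = (np.arange(grid) * n // grid).astype(int)
    return sub[np.ix_(idx, idx)]


def _region_to_bins(m: ContactMatrix, chrom: str, start: int, end: int) -> tuple[int, int]:
    sl = m.bins.chrom_slice(chrom)
    res = m.resolution
    b0 = max(0, start // res)
    b1 = min(sl.stop - sl.start, -(-end // res))
    return sl.start + b0, sl.start + b1


def aggregate_tads(
    oe: ContactMatrix,
    regions: list[tuple[str, int, int]],
    expand: float = 3.0,
    grid: int = 90,
    max_undefined_fraction: float = 0.5,
) -> AggregateResult:
    """Average the OE sub-matrices over expanded TAD regions.

    Each region is expanded to ``expand`` times its size, centred on the
    region; the square sub-matrix is resampled to ``grid`` pixels by
    nearest-neighbour. Instances with more than
    ``max_undefined_fraction`` NaN pixels are skipped and counted.
    """
    if not regions:
        raise ValueError("empty region list")
    stack = []
    skipped = 0
    for chrom, start, end in regions:
        size = end - start
        centre = (start + end) // 2
        half = int(round(expand * size / 2))
        b0, b1 = _region_to_bins(oe, chrom, max(0, centre - half), centre + half)
        sub = oe.matrix[b0:b1, b0:b1]
        if sub.size == 0 or np.isnan(sub).mean() > max_undefined_fraction:
            skipped += 1
            continue
        stack.append(resample_nearest(sub, grid))
    if not stack:
        return AggregateResult(np.full((grid, grid), np.nan), 0, skipped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.stack(stack), axis=0)
    return AggregateResult(mean, len(stack), skipped)


def tad_strength(oe: ContactMatrix, region: tuple[str, int, int]) -> float:
    """Ratio of the OE sum inside the region square to the mean of the two
    equally-sized neighbouring squares. NaN (with a warning) if a
    neighbour does not fit on the chromosome.
    """
    chrom, start, end = region
    sl = oe.bins.chrom_slice(chrom)
    res = oe.resolution
    b0 = start // res
    b1 = -(-end // res)
    r = b1 - b0
    n = sl.stop - sl.start
    if b0 - r < 0 or b1 + r > n:
        warnings.warn(f"TAD strength undefined: neighbour of {chrom}:{start}-{end} exits chromosome")
        return float("nan")
    sub = oe.matrix[sl, sl]
    centre = np.nansum(sub[b0:b1, b0:b1])
    left = np.nansum(sub[b0 - r : b0, b0 - r : b0])
    right = np.nansum(sub[b1 : b1 + r, b1 : b1 + r])
    denom = 0.5 * (left + right)
    return float(centre / denom) if denom > 0 else float("nan")


def aggregate_loops(
    m: ContactMatrix,
    anchors: list[tuple[str, int, int]],
    window: int = 400_000,
    max_undefined_fraction: float = 0.5,
) -> AggregateResult:
    """Average sub-matrices centred on loop anchor pairs.

    Each anchor pair (chrom, pos1, pos2) contributes the window x window
    square centred on (anchor1, anchor2). Windows exiting the matrix are
    skipped and counted.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    res = m.resolution
    half = window // (2 * res)
    size = 2 * half + 1
    stack = []
    skipped = 0
    for chrom, pos1, pos2 in anchors:
        sl = m.bins.chrom_slice(chrom)
        i = sl.start + pos1 // res
        j = sl.start + pos2 // res
        if i - half < sl.start or j - half < sl.start or i + half >= sl.stop or j + half >= sl.stop:
            skipped += 1
            continue
        sub = m.matrix[i - half : i + half + 1, j - half : j + half + 1]
        if np.isnan(sub).mean() > max_undefined_fraction:
            skipped += 1
            continue
        stack.append(sub)
    if not stack:
        return AggregateResult(np.full((size, size), np.nan), 0, skipped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.stack(stack), axis=0)
    return AggregateResult(mean, len(stack), skipped)


def loop_strength(
    m: ContactMatrix, anchor_pair: tuple[str, int, int], window: int = 300_000
) -> float:
    """Signal square at the anchors versus equidistant control squares.

    S is the window x window sum centred on (a1, a2); the controls keep
    one anchor and reflect the other to the opposite side at the same
    separation d: C1 at (a2, a2 + d) and C2 at (a1 - d, a1). The strength
    is S / mean(C1, C2); NaN (with warning) when a control exits the
    chromosome.
    """
    chrom, pos1, pos2 = anchor_pair
    if pos1 > pos2:
        pos1, pos2 = pos2, pos1
    res = m.resolution
    sl = m.bins.chrom_slice(chrom)
    half = window // (2 * res)
    a1 = sl.start + pos1 // res
    a2 = sl.start + pos2 // res
    d = a2 - a1

    def square_sum(i: int, j: int) -> float:
        if i - half < sl.start or j - half < sl.start or i + half >= sl.stop or j + half >= sl.stop:
            return float("nan")
        return float(np.nansum(m.matrix[i - half : i + half + 1, j - half : j + half + 1]))

    s = square_sum(a1, a2)
    c1 = square_sum(a2, a2 + d)
    c2 = square_sum(a1 - d, a1)
    if np.isnan(s) or np.isnan(c1) or np.isnan(c2):
        warnings.warn(f"loop strength undefined for {chrom}:{pos1}-{pos2}: window or control exits chromosome")
        return float("nan")
    denom = 0.5 * (c1 + c2)
    return s / denom if denom > 0 else float("nan")
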