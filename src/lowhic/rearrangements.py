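"""Whole-genome virtual-4C scanning and case-vs-control comparison for
structural-rearrangement candidates, plus comparative TAD intensity."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix
from .tracks import BoundarySet


@dataclass(frozen=True)
class V4CPeak:
    viewpoint: int  # global bin index
    target: int
    target_value: float  # v_j
    viewpoint_height: float  # v_i
    percentile_rank: float


@dataclass
class RearrangementCall:
    viewpoint_bins: tuple[int, int]  # inclusive global-bin range
    target_bins: tuple[int, int]
    n_peaks: int
    breakpoint: tuple[int, int]  # refined (viewpoint, target) bin pair
    max_target_value: float
    case_only: bool = True


@dataclass
class TadIntensityDiff:
    chrom: str
    start_bin: int  # chromosome-local
    end_bin: int
    case_mean: float
    control_mean: float

    @property
    def difference(self) -> float:
        return self.case_mean - self.control_mean


def v4c_profile(m: ContactMatrix, viewpoint: int) -> np.ndarray:
    """Row ``viewpoint`` of the genome-wide matrix; NaN at masked bins."""
    if not m.mappable[viewpoint]:
        raise ValueError(f"viewpoint bin {viewpoint} is masked")
    v = m.matrix[viewpoint].astype(float).copy()
    v[~m.mappable] = np.nan
    return v


def v4c_peak_scan(
    m: ContactMatrix,
    height_fraction: float = 0.15,
    percentile: float = 99.5,
    exclusion: int = 50,
    mappability_halfwidth: int = 7,
    viewpoints: list[int] | None = None,
) -> list[V4CPeak]:
    """Scan every bin as a virtual-4C viewpoint and collect distal peaks.

    A viewpoint is skipped if any bin within +-``mappability_halfwidth``
    is unmappable (such regions produce false-positive rearrangements).
    An entry v_j is a peak iff v_j > height_fraction * v_i, v_j strictly
    exceeds the ``percentile`` of all other defined entries of v, and the
    target is either on another chromosome or at least ``exclusion`` bins
    away from the viewpoint.
    """
    n = m.n_bins
    chrom_of = np.empty(n, dtype=object)
    for chrom in m.bins.chromosomes:
        chrom_of[m.bins.chrom_slice(chrom)] = chrom
    peaks: list[V4CPeak] = []
    vp_iter = range(n) if viewpoints is None else viewpoints
    for i in vp_iter:
        lo, hi = i - mappability_halfwidth, i + mappability_halfwidth + 1
        if lo < 0 or hi > n or not m.mappable[lo:hi].all():
            continue
        v = m.matrix[i].astype(float).copy()
        v[~m.mappable] = np.nan
        v_i = v[i]
        others = np.delete(v, i)
        others = others[~np.isnan(others)]
        if others.size == 0 or not np.isfinite(v_i) or v_i <= 0:
            continue
        cutoff = np.percentile(others, percentile)
        height_cut = height_fraction * v_i
        for j in range(n):
            if j == i or np.isnan(v[j]):
                continue
            if chrom_of[j] == chrom_of[i] and abs(j - i) < exclusion:
                continue
            if v[j] > height_cut and v[j] > cutoff:
                rank = float((others < v[j]).mean() * 100.0)
                peaks.append(V4CPeak(i, j, float(v[j]), float(v_i), rank))
    return peaks


def _peak_matches(peak: V4CPeak, pool: list[V4CPeak], tolerance: int) -> bool:
    return any(
        abs(peak.viewpoint - q.viewpoint) <= tolerance and abs(peak.target - q.target) <= tolerance
        for q in pool
    )


def compare_scans(
    case_peaks: list[V4CPeak],
    control_peaks: list[V4CPeak],
    tolerance: int = 2,
    merge_radius: int = 2,
) -> list[RearrangementCall]:
    """Retain case peaks with no control peak within ``tolerance`` bins in
    both coordinates, then merge the survivors into calls by adjacency
    (runs of nearby viewpoint bins targeting nearby target bins).

    The refined breakpoint of a call is the (viewpoint, target) pair of
    its maximum-value peak.
    """
    case_only = [p for p in case_peaks if not _peak_matches(p, control_peaks, tolerance)]
    calls: list[RearrangementCall] = []
    unused = list(case_only)
    while unused:
        seed = unused.pop(0)
        cluster = [seed]
        frontier = [seed]
        while frontier:
            a = frontier.pop()
            hits = [
                b
                for b in unused
                if abs(a.viewpoint - b.viewpoint) <= merge_radius and abs(a.target - b.target) <= merge_radius
            ]
            for b in hits:
                unused.remove(b)
                cluster.append(b)
                frontier.append(b)
        best = max(cluster, key=lambda pk: pk.target_value)
        calls.append(
            RearrangementCall(
                viewpoint_bins=(min(p.viewpoint for p in cluster), max(p.viewpoint for p in cluster)),
                target_bins=(min(p.target for p in cluster), max(p.target for p in cluster)),
                n_peaks=len(cluster),
                breakpoint=(best.viewpoint, best.target),
                max_target_value=best.target_value,
            )
        )
    return calls


def merge_boundaries(a: BoundarySet, b: BoundarySet, collapse: int = 1) -> list[int]:
    """Sorted union of two boundary sets; boundaries within ``collapse``
    bins are collapsed to a single position (the earlier one)."""
    merged: list[int] = []
    for pos in sorted(set(a.positions) | set(b.positions)):
        if merged and pos - merged[-1] <= collapse:
            continue
        merged.append(pos)
    return merged


def tad_intensity_difference(
    case: ContactMatrix,
    control: ContactMatrix,
    case_boundaries: BoundarySet,
    control_boundaries: BoundarySet,
    collapse: int = 1,
) -> list[TadIntensityDiff]:
    """Mean Hi-C signal between consecutive merged boundaries, per sample.

    For each inter-boundary region the mean over all pixel pairs of the
    region's square sub-matrix is computed in case and control; the
    difference is case - control.
    """
    if case.bins != control.bins:
        raise ValueError("case and control require identical bin tables")
    merged = merge_boundaries(case_boundaries, control_boundaries, collapse)
    out: list[TadIntensityDiff] = []
    for chrom in case.bins.chromosomes:
        sl = case.bins.chrom_slice(chrom)
        local = sorted(p - sl.start for p in merged if sl.start <= p < sl.stop)
        if len(local) < 2:
            continue
        c_sub = case.matrix[sl, sl]
        k_sub = control.matrix[sl, sl]
        for b0, b1 in zip(local[:-1], local[1:]):
            if b1 <= b0:
                continue
            region_c = c_sub[b0:b1, b0:b1]
            region_k = k_sub[b0:b1, b0:b1]
            out.append(
                TadIntensityDiff(
                    chrom,
                    b0,
                    b1,
                    float(np.nanmean(region_c)),
                    float(np.nanmean(region_k)),
                )
            )
    return out
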