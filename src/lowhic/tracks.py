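"""1-D genome tracks derived from contact matrices: insulation scores,
TAD boundary calls, and A/B compartment eigenvectors."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import BinTable
from .matrix import ContactMatrix, OBSERVED_EXPECTED


@dataclass
class InsulationTrack:
    """Per-bin insulation score for one sliding-window size.

    Scores are log2 ratios to the chromosomal mean of the raw window
    average; NaN near chromosome ends and at masked windows.
    """

    bins: BinTable
    window: int
    scores: np.ndarray  # genome-wide, NaN where undefined

    def chrom_scores(self, chrom: str) -> np.ndarray:
        return self.scores[self.bins.chrom_slice(chrom)]


@dataclass
class BoundarySet:
    """Ordered TAD boundary bin indices with delta-based strengths."""

    bins: BinTable
    positions: list[int] = field(default_factory=list)  # global bin indices
    strengths: list[float] = field(default_factory=list)

    def per_chrom(self, chrom: str) -> list[int]:
        sl = self.bins.chrom_slice(chrom)
        return [p - sl.start for p in self.positions if sl.start <= p < sl.stop]


@dataclass
class CompartmentTrack:
    """First eigenvector of the per-chromosome OE correlation matrix.

    Labels: 'A' / 'B' by eigenvector sign, '' where undefined.
    """

    bins: BinTable
    eigenvector: np.ndarray
    labels: np.ndarray  # dtype=object: 'A', 'B' or ''


def insulation_score(
    m: ContactMatrix, window: int, max_masked_fraction: float = 0.5
) -> InsulationTrack:
    """Mean contact weight in a k x k square sliding along the diagonal.

    The square at bin i spans bins [i-k, i) x (i, i+k]. Windows leaving
    the chromosome, or overlapping more than ``max_masked_fraction``
    masked pixels, are NaN. The final score is
    log2(raw / chromosomal mean of raw).
    """
    res = m.resolution
    k = window // res
    if k < 1:
        raise ValueError(f"window {window} smaller than one bin ({res})")
    scores = np.full(m.n_bins, np.nan)
    for chrom in m.bins.chromosomes:
        sl = m.bins.chrom_slice(chrom)
        sub = m.matrix[sl, sl]
        mask = m.mappable[sl]
        n = sub.shape[0]
        raw = np.full(n, np.nan)
        for i in range(k, n - k):
            rows = slice(i - k, i)
            cols = slice(i + 1, i + k + 1)
            pix_ok = np.outer(mask[rows], mask[cols])
            if pix_ok.mean() < 1.0 - max_masked_fraction or not mask[i]:
                continue
            vals = sub[rows, cols][pix_ok]
            raw[i] = vals.mean() if vals.size else np.nan
        defined = ~np.isnan(raw)
        if defined.any():
            chrom_mean = raw[defined].mean()
            if chrom_mean > 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    raw = np.where(defined & (raw > 0), np.log2(raw / chrom_mean), np.nan)
            else:
                raw[:] = np.nan
        scores[sl] = raw
    return InsulationTrack(m.bins, window, scores)


def call_boundaries(
    track: InsulationTrack, delta_window: int = 7, min_strength: float = 0.1
) -> BoundarySet:
    """Call boundaries at insulation minima via the delta-vector method.

    delta[i] = mean(score over (i, i+delta_window]) - mean(score over
    [i-delta_window, i)); a boundary sits where delta crosses zero from
    negative to positive around a local score minimum. Strength is the
    delta range across the crossing; calls below ``min_strength`` are
    dropped.
    """
    out = BoundarySet(track.bins)
    dw = delta_window
    for chrom in track.bins.chromosomes:
        sl = track.bins.chrom_slice(chrom)
        score = track.scores[sl]
        n = len(score)
        if n < 2 * dw:
            continue
        delta = np.full(n, np.nan)
        for i in range(dw, n - dw):
            right = score[i + 1 : i + dw + 1]
            left = score[i - dw : i]
            if np.isnan(right).all() or np.isnan(left).all():
                continue
            delta[i] = np.nanmean(right) - np.nanmean(left)
        for i in range(dw, n - dw - 1):
            if np.isnan(delta[i]) or np.isnan(delta[i + 1]):
                continue
            if delta[i] < 0 <= delta[i + 1]:
                # local score minimum between the crossing flanks
                lo = max(0, i - dw)
                hi = min(n, i + dw + 2)
                window = score[lo:hi]
                if np.isnan(window).all():
                    continue
                b = lo + int(np.nanargmin(window))
                left_seg = delta[max(0, i - dw) : i + 1]
                right_seg = delta[i + 1 : min(n, i + 1 + dw)]
                strength = float(np.nanmax(right_seg) - np.nanmin(left_seg))
                if strength >= min_strength:
                    gpos = sl.start + b
                    if gpos not in out.positions:
                        out.positions.append(gpos)
                        out.strengths.append(strength)
    order = np.argsort(out.positions)
    out.positions = [out.positions[i] for i in order]
    out.strengths = [out.strengths[i] for i in order]
    return out


def compartment_eigenvector(oe: ContactMatrix) -> tuple[CompartmentTrack, dict[str, np.ndarray]]:
    """Per-chromosome leading eigenvector of the OE correlation matrix.

    The correlation matrix holds Pearson correlations between OE rows
    (mappable bins only). Labels follow the eigenvector sign; the sign is
    oriented so that 'A' bins have the larger mean within-group OE signal.
    Degenerate (constant-row) chromosomes yield an undefined track with a
    warning. Returns the track and the per-chromosome correlation
    matrices.
    """
    if oe.state != OBSERVED_EXPECTED:
        raise ValueError(f"compartments expect an observed/expected matrix, got {oe.state!r}")
    ev = np.full(oe.n_bins, np.nan)
    labels = np.full(oe.n_bins, "", dtype=object)
    corrs: dict[str, np.ndarray] = {}
    for chrom in oe.bins.chromosomes:
        sl = oe.bins.chrom_slice(chrom)
        sub = oe.matrix[sl, sl]
        mask = oe.mappable[sl].copy()
        idx = np.flatnonzero(mask)
        if idx.size < 3:
            warnings.warn(f"{chrom}: fewer than 3 mappable bins; compartments undefined")
            continue
        rows = sub[np.ix_(idx, idx)]
        rows = np.where(np.isnan(rows), 1.0, rows)  # undefined pixels treated as no enrichment
        stds = rows.std(axis=1)
        if np.any(stds == 0):
            keep = stds > 0
            if keep.sum() < 3:
                warnings.warn(f"{chrom}: degenerate correlation matrix; compartments undefined")
                continue
            idx = idx[keep]
            rows = rows[np.ix_(keep, keep)]
        corr = np.corrcoef(rows)
        if not np.all(np.isfinite(corr)):
            warnings.warn(f"{chrom}: degenerate correlation matrix; compartments undefined")
            continue
        corrs[chrom] = corr
        eigval, eigvec = np.linalg.eigh(corr)
        lead = eigvec[:, int(np.argmax(np.abs(eigval)))]
        lead = lead / np.linalg.norm(lead)
        pos = lead > 0
        if pos.any() and (~pos).any():
            mean_pos = np.nanmean(rows[np.ix_(pos, pos)])
            mean_neg = np.nanmean(rows[np.ix_(~pos, ~pos)])
            if mean_neg > mean_pos:
                lead = -lead
        ev[sl.start + idx] = lead
        labels[sl.start + idx] = np.where(lead > 0, "A", np.where(lead < 0, "B", ""))
    return CompartmentTrack(oe.bins, ev, labels), corrs


def insulation_multi_window(
    m: ContactMatrix, windows: list[int]
) -> dict[int, InsulationTrack]:
    """Insulation tracks for a list of window sizes (heatmap-style output)."""
    return {w: insulation_score(m, w) for w in windows}
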