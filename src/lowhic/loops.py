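"""De-novo loop calling: local-neighbourhood enrichment with Poisson
statistics and FDR control, plus the retention filters

  (i)  >= 2.0-fold enrichment over donut OR lower-left,
  (ii) >= 1.5-fold over horizontal AND vertical,
  (iii) >= 1.75-fold over donut AND lower-left,
  (iv) FDR <= 0.1 in every neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .matrix import BALANCED, ContactMatrix, ExpectedProfile, expected_by_distance

NEIGHBOURHOODS = ("donut", "lower_left", "horizontal", "vertical")


@dataclass
class LoopCandidate:
    chrom: str
    bin_i: int  # chromosome-local bin indices
    bin_j: int
    observed: float  # balanced value
    raw_count: float
    expected: dict[str, float] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)
    pvalue: dict[str, float] = field(default_factory=dict)
    fdr: dict[str, float] = field(default_factory=dict)


@dataclass
class LoopSet:
    calls: list[LoopCandidate]
    candidates: int
    params: dict = field(default_factory=dict)


def neighbourhood_masks(p: int, w: int) -> dict[str, np.ndarray]:
    """Boolean offset masks of shape (2w+1, 2w+1), centre at (w, w).

    donut: the square annulus between radii p and w (Chebyshev), minus the
    centre row and column. lower_left: the below-left quadrant of that
    annulus (di in [1, w], dj in [-w, -1], excluding the inner p-box).
    horizontal/vertical: 3-wide stripes along the row/column within +-w,
    excluding the +-p core.
    """
    if not (w > p >= 1):
        raise ValueError(f"need w > p >= 1, got p={p}, w={w}")
    size = 2 * w + 1
    di, dj = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    cheb = np.maximum(np.abs(di), np.abs(dj))
    donut = (cheb > p) & (cheb <= w) & (di != 0) & (dj != 0)
    lower_left = (di >= 1) & (di <= w) & (dj <= -1) & (dj >= -w) & ~((di <= p) & (dj >= -p))
    horizontal = (np.abs(di) <= 1) & (np.abs(dj) <= w) & (np.abs(dj) > p)
    vertical = (np.abs(dj) <= 1) & (np.abs(di) <= w) & (np.abs(di) > p)
    masks = {"donut": donut, "lower_left": lower_left, "horizontal": horizontal, "vertical": vertical}
    assert all(not m[w, w] for m in masks.values())
    return masks


def neighbourhood_expected(
    m: ContactMatrix,
    pixel: tuple[str, int, int],
    p: int = 2,
    w: int = 5,
    profile: ExpectedProfile | None = None,
) -> dict[str, float]:
    """Expected value at one pixel for each neighbourhood shape.

    expected = (sum of observed over the shape / sum of distance-expected
    over the shape) * distance-expected at the pixel. Shapes are clipped
    at matrix edges and masked bins.
    """
    chrom, i, j = pixel
    if profile is None:
        profile = expected_by_distance(m)
    sl = m.bins.chrom_slice(chrom)
    sub = m.matrix[sl, sl]
    mask = m.mappable[sl]
    n = sub.shape[0]
    e = profile.expected[chrom]
    masks = neighbourhood_masks(p, w)
    out = {}
    for name, shape in masks.items():
        o_sum = 0.0
        e_sum = 0.0
        for di, dj in zip(*np.nonzero(shape)):
            a, b = i + di - w, j + dj - w
            if 0 <= a < n and 0 <= b < n and mask[a] and mask[b]:
                ed = e[abs(a - b)]
                if np.isfinite(ed):
                    o_sum += sub[a, b]
                    e_sum += ed
        out[name] = (o_sum / e_sum) * e[abs(i - j)] if e_sum > 0 else np.nan
    return out


def passes_retention(
    enrichment: dict[str, float],
    fdr: dict[str, float],
    fold_donut_or_ll: float = 2.0,
    fold_h_v: float = 1.5,
    fold_donut_and_ll: float = 1.75,
    max_fdr: float = 0.1,
) -> bool:
    """The four retention filters applied to one scored pixel."""
    return (
        (enrichment["donut"] >= fold_donut_or_ll or enrichment["lower_left"] >= fold_donut_or_ll)
        and enrichment["horizontal"] >= fold_h_v
        and enrichment["vertical"] >= fold_h_v
        and enrichment["donut"] >= fold_donut_and_ll
        and enrichment["lower_left"] >= fold_donut_and_ll
        and all(fdr[name] <= max_fdr for name in NEIGHBOURHOODS)
    )


def _lambda_chunk_fdr(pvals: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg within lambda chunks of width 2^(1/3) on the
    log scale of the expected value."""
    fdr = np.full_like(pvals, np.nan)
    with np.errstate(divide="ignore"):
        chunk = np.where(lam > 0, np.floor(3 * np.log2(np.maximum(lam, 1e-300))), -1000).astype(int)
    for c in np.unique(chunk):
        idx = np.flatnonzero(chunk == c)
        fdr[idx] = _bh(pvals[idx])
    return fdr


def _bh(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_loops(
    m: ContactMatrix,
    p: int = 2,
    w: int = 5,
    min_distance_bins: int = 2,
    max_distance_bins: int = 400,
    fold_donut_or_ll: float = 2.0,
    fold_h_v: float = 1.5,
    fold_donut_and_ll: float = 1.75,
    max_fdr: float = 0.1,
    fdr_method: str = "lambda",
    merge_radius: int = 1,
    profile: ExpectedProfile | None = None,
) -> LoopSet:
    """HICCUPS-style loop calling on a balanced matrix.

    Per candidate pixel the raw count (balanced value unscaled by the two
    bin biases) is tested against a Poisson with mean equal to each
    neighbourhood expected divided by the bias product; FDR per
    neighbourhood via lambda-chunked BH (``fdr_method='bh'`` for plain
    BH). Retained pixels are merged by adjacency, keeping the local
    maximum of observed signal.
    """
    if m.state != BALANCED:
        raise ValueError(f"loop calling expects a balanced matrix, got {m.state!r}")
    if profile is None:
        profile = expected_by_distance(m)
    masks = neighbourhood_masks(p, w)
    kernels = {name: shape.astype(float) for name, shape in masks.items()}
    all_calls: list[LoopCandidate] = []
    n_candidates = 0
    for chrom in m.bins.chromosomes:
        sl = m.bins.chrom_slice(chrom)
        sub = m.matrix[sl, sl]
        mask = m.mappable[sl]
        bias = m.bias[sl] if m.bias is not None else np.ones(sub.shape[0])
        n = sub.shape[0]
        if n < 2 * w + 1:
            continue
        e = profile.expected[chrom]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        emat = np.where(np.isfinite(e[d]), e[d], 0.0)
        pix_ok = np.outer(mask, mask)
        emat = emat * pix_ok
        obs = np.where(pix_ok, sub, 0.0)
        # per-shape sliding sums via correlation (zero padding = edge clip)
        exp_nb = {}
        for name, kern in kernels.items():
            o_sum = ndimage.correlate(obs, kern, mode="constant", cval=0.0)
            e_sum = ndimage.correlate(emat, kern, mode="constant", cval=0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                exp_nb[name] = np.where(e_sum > 0, o_sum / e_sum * emat, np.nan)
        dist = d
        cand = (
            pix_ok
            & (dist >= min_distance_bins)
            & (dist <= max_distance_bins)
            & (np.triu(np.ones((n, n), dtype=bool)))
            & (emat > 0)
        )
        for name in NEIGHBOURHOODS:
            cand &= np.isfinite(exp_nb[name]) & (exp_nb[name] > 0)
        ii, jj = np.nonzero(cand)
        n_candidates += len(ii)
        if len(ii) == 0:
            continue
        observed = sub[ii, jj]
        bias_prod = bias[ii] * bias[jj]
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = observed / bias_prod
        raw_int = np.round(raw).astype(np.int64)
        enr = {}
        pvals = {}
        fdrs = {}
        for name in NEIGHBOURHOODS:
            exp_vals = exp_nb[name][ii, jj]
            enr[name] = observed / exp_vals
            lam = exp_vals / bias_prod
            pvals[name] = stats.poisson.sf(raw_int - 1, lam)
            fdrs[name] = (
                _lambda_chunk_fdr(pvals[name], lam) if fdr_method == "lambda" else _bh(pvals[name])
            )
        keep = (
            ((enr["donut"] >= fold_donut_or_ll) | (enr["lower_left"] >= fold_donut_or_ll))
            & (enr["horizontal"] >= fold_h_v)
            & (enr["vertical"] >= fold_h_v)
            & (enr["donut"] >= fold_donut_and_ll)
            & (enr["lower_left"] >= fold_donut_and_ll)
        )
        for name in NEIGHBOURHOODS:
            keep &= fdrs[name] <= max_fdr
        kept_idx = np.flatnonzero(keep)
        if kept_idx.size == 0:
            continue
        pts = [
            LoopCandidate(
                chrom,
                int(ii[t]),
                int(jj[t]),
                float(observed[t]),
                float(raw[t]),
                expected={nm: float(exp_nb[nm][ii[t], jj[t]]) for nm in NEIGHBOURHOODS},
                enrichment={nm: float(enr[nm][t]) for nm in NEIGHBOURHOODS},
                pvalue={nm: float(pvals[nm][t]) for nm in NEIGHBOURHOODS},
                fdr={nm: float(fdrs[nm][t]) for nm in NEIGHBOURHOODS},
            )
            for t in kept_idx
        ]
        all_calls.extend(_merge_adjacent(pts, merge_radius))
    return LoopSet(
        all_calls,
        n_candidates,
        params={
            "p": p,
            "w": w,
            "resolution": m.resolution,
            "fold_donut_or_ll": fold_donut_or_ll,
            "fold_h_v": fold_h_v,
            "fold_donut_and_ll": fold_donut_and_ll,
            "max_fdr": max_fdr,
            "fdr_method": fdr_method,
        },
    )


def _merge_adjacent(points: list[LoopCandidate], radius: int) -> list[LoopCandidate]:
    """Cluster retained pixels within Chebyshev distance ``radius``; each
    cluster is represented by its maximum-observed pixel."""
    if radius <= 0:
        return points
    unused = list(range(len(points)))
    clusters: list[list[int]] = []
    while unused:
        seed = unused.pop(0)
        cluster = [seed]
        frontier = [seed]
        while frontier:
            a = frontier.pop()
            hits = [
                b
                for b in unused
                if max(abs(points[a].bin_i - points[b].bin_i), abs(points[a].bin_j - points[b].bin_j)) <= radius
            ]
            for b in hits:
                unused.remove(b)
                cluster.append(b)
                frontier.append(b)
        clusters.append(cluster)
    return [max((points[t] for t in c), key=lambda pt: pt.observed) for c in clusters]
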