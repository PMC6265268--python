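"""Contact-matrix construction, masking, balancing and transforms.

Matrices are stored dense (float64, symmetric) — the toolkit targets
desk-scale maps where a genome-wide dense array is cheap. Masked
(unmappable) bins hold zeros; derived quantities at masked bins are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import BinTable
from .pairs import ValidPair

RAW = "raw"
BALANCED = "balanced"
OBSERVED_EXPECTED = "observed_expected"


class BalancingError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    """Symmetric binned contact map with mask and bias vector."""

    bins: BinTable
    matrix: np.ndarray
    mappable: np.ndarray = None
    bias: np.ndarray | None = None
    state: str = RAW

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = self.bins.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match {n} bins")
        if self.mappable is None:
            self.mappable = np.ones(n, dtype=bool)
        else:
            self.mappable = np.asarray(self.mappable, dtype=bool).copy()

    @property
    def resolution(self) -> int:
        return self.bins.bin_size

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins,
            self.matrix.copy(),
            self.mappable.copy(),
            None if self.bias is None else self.bias.copy(),
            self.state,
        )

    def chrom_view(self, chrom: str) -> np.ndarray:
        s = self.bins.chrom_slice(chrom)
        return self.matrix[s, s]

    def mass(self) -> float:
        """Total matrix mass counted over the upper triangle plus diagonal."""
        return float(np.triu(self.matrix).sum())


@dataclass
class ExpectedProfile:
    """Per-chromosome mean contact weight at each bin distance."""

    resolution: int
    expected: dict[str, np.ndarray] = field(default_factory=dict)
    n_possible: dict[str, np.ndarray] = field(default_factory=dict)
    trans_expected: float = np.nan

    def at(self, chrom: str, distance_bins: int) -> float:
        e = self.expected[chrom]
        if 0 <= distance_bins < len(e):
            return float(e[distance_bins])
        return np.nan


def bin_pairs(pairs: list[ValidPair], bins: BinTable) -> ContactMatrix:
    """Accumulate valid pairs into a raw symmetric contact matrix."""
    n = bins.n_bins
    m = np.zeros((n, n), dtype=np.float64)
    for p in pairs:
        if not p.valid:
            raise ValueError(f"pair {p.read_id!r} carries filter flags {sorted(p.flags)}")
        i = bins.bin_index(p.chrom1, p.pos1)
        j = bins.bin_index(p.chrom2, p.pos2)
        m[i, j] += 1
        if i != j:
            m[j, i] += 1
    return ContactMatrix(bins, m, state=RAW)


def mask_low_coverage(m: ContactMatrix, threshold_fraction: float = 0.10) -> ContactMatrix:
    """Mask bins with coverage below ``threshold_fraction`` of the median.

    Coverage is the per-bin marginal sum; the median is taken over bins
    with non-zero coverage. Masked rows/columns are zeroed. Bins with no
    contacts are always masked.
    """
    if m.state != RAW:
        raise ValueError(f"low-coverage masking expects a raw matrix, got {m.state!r}")
    out = m.copy()
    coverage = out.matrix.sum(axis=1)
    nonzero = coverage[coverage > 0]
    if nonzero.size == 0:
        raise ValueError("all bins are empty; nothing to mask against")
    cutoff = threshold_fraction * float(np.median(nonzero))
    masked = (coverage < cutoff) | (coverage == 0) | ~out.mappable
    out.mappable = ~masked
    out.matrix[masked, :] = 0.0
    out.matrix[:, masked] = 0.0
    out.bins.mappable = out.mappable.copy()
    return out


def _kr_core(A: np.ndarray, tol: float, max_outer: int) -> np.ndarray | None:
    """Knight–Ruiz inner-outer Newton iteration (bnewt) targeting row sums 1.

    Returns the positive scaling vector, or None if it failed to converge.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > stop_tol**2:
        outer += 1
        if outer > max_outer:
            return None
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, stop_tol**2)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = float(((delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = float(((big_delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k > n:
                break
        x = x * y
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            return None
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), 0.5 * stop_tol / res_norm) if res_norm > 0 else etamax
    return x


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int = 50000, x0: np.ndarray | None = None):
    """Symmetric Sinkhorn fixed point x <- sqrt(x / (A x)); row sums -> 1."""
    n = A.shape[0]
    x = np.ones(n) if x0 is None else x0.copy()
    for _ in range(max_iter):
        s = A @ x
        if np.any(s <= 0):
            return None
        x_new = np.sqrt(x / s)
        x = x_new
        dev = np.abs(x * (A @ x) - 1.0).max()
        if dev < tol:
            return x
    return None


def kr_balance(
    m: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 300,
    per_chromosome: bool = False,
) -> ContactMatrix:
    """Knight–Ruiz matrix balancing: b_i M_ij b_j has unit row sums over
    mappable bins. Falls back to Sinkhorn iteration on a stalled Newton
    solve; raises :class:`BalancingError` on non-convergence.
    """
    out = m.copy()
    n = out.n_bins
    bias = np.full(n, np.nan)
    regions = (
        [(c, out.bins.chrom_slice(c)) for c in out.bins.chromosomes]
        if per_chromosome
        else [("genome", slice(0, n))]
    )
    balanced = np.zeros_like(out.matrix)
    for label, sl in regions:
        idx = np.flatnonzero(out.mappable[sl]) + sl.start
        if idx.size == 0:
            continue
        A = out.matrix[np.ix_(idx, idx)]
        with np.errstate(divide="ignore", invalid="ignore"):
            x = _kr_core(A, tol, max_iter)
            if x is None or np.abs(x * (A @ x) - 1.0).max() >= tol:
                x = _sinkhorn(A, tol, x0=x if x is not None else None)
        if x is None or np.abs(x * (A @ x) - 1.0).max() >= tol:
            raise BalancingError(f"KR balancing did not converge for {label}")
        bias[idx] = x
        balanced[np.ix_(idx, idx)] = A * np.outer(x, x)
    # per-chromosome mode yields a cis-only matrix (trans pixels zeroed)
    out.matrix = balanced
    out.bias = bias
    out.state = BALANCED
    return out


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Per-chromosome mean contact weight at each bin distance.

    Pairs touching unmappable bins are excluded from both numerator and
    denominator. Also records the mean mappable inter-chromosomal pixel
    value as the trans expected.
    """
    prof = ExpectedProfile(resolution=m.resolution)
    for chrom in m.bins.chromosomes:
        sl = m.bins.chrom_slice(chrom)
        sub = m.matrix[sl, sl]
        mask = m.mappable[sl]
        n = sub.shape[0]
        e = np.full(n, np.nan)
        counts = np.zeros(n, dtype=np.int64)
        for d in range(n):
            pair_ok = mask[: n - d] & mask[d:]
            c = int(pair_ok.sum())
            counts[d] = c
            if c > 0:
                e[d] = float(np.diagonal(sub, d)[pair_ok].sum()) / c
        prof.expected[chrom] = e
        prof.n_possible[chrom] = counts
    # trans expected: mean over mappable inter-chromosomal pixels
    num = 0.0
    den = 0
    for i, c1 in enumerate(m.bins.chromosomes):
        for c2 in list(m.bins.chromosomes)[i + 1 :]:
            s1, s2 = m.bins.chrom_slice(c1), m.bins.chrom_slice(c2)
            block = m.matrix[s1, s2]
            ok = np.outer(m.mappable[s1], m.mappable[s2])
            num += float(block[ok].sum())
            den += int(ok.sum())
    prof.trans_expected = num / den if den else np.nan
    return prof


def oe_transform(
    m: ContactMatrix,
    profile: ExpectedProfile | None = None,
    require_balanced: bool = True,
) -> ContactMatrix:
    """Observed/expected transform: each cis pixel divided by its
    distance-expected value. Pixels without a defined expected value (and
    all pixels touching masked bins, and trans pixels) are NaN.

    ``require_balanced=False`` permits raw input — appropriate only when
    per-bin coverage biases are known to be uniform (e.g. simulator
    output), where balancing would rescale planted block multipliers.
    """
    if require_balanced and m.state != BALANCED:
        raise ValueError(f"OE transform expects a balanced matrix, got {m.state!r}")
    if profile is None:
        profile = expected_by_distance(m)
    out = m.copy()
    oe = np.full_like(m.matrix, np.nan)
    for chrom in m.bins.chromosomes:
        sl = m.bins.chrom_slice(chrom)
        sub = m.matrix[sl, sl]
        e = profile.expected[chrom]
        n = sub.shape[0]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            block = sub / e[d]
        block[e[d] <= 0] = np.nan
        mask = m.mappable[sl]
        block[~mask, :] = np.nan
        block[:, ~mask] = np.nan
        oe[sl, sl] = block
    out.matrix = oe
    out.state = OBSERVED_EXPECTED
    return out


def difference_matrix(a: ContactMatrix, b: ContactMatrix, no_signal: str = "both") -> np.ndarray:
    """Signed difference a - b with no-signal pixels masked to NaN.

    ``no_signal='both'`` masks pixels that are zero/undefined in both
    matrices (retaining one-sided gains/losses); ``'any'`` masks pixels
    lacking signal in at least one matrix.
    """
    if a.bins != b.bins:
        raise ValueError("difference requires identical bin tables")
    if no_signal not in ("both", "any"):
        raise ValueError("no_signal must be 'both' or 'any'")
    av = np.where(np.isnan(a.matrix), 0.0, a.matrix)
    bv = np.where(np.isnan(b.matrix), 0.0, b.matrix)
    has_a = (av != 0) & ~np.isnan(a.matrix)
    has_b = (bv != 0) & ~np.isnan(b.matrix)
    keep = (has_a | has_b) if no_signal == "both" else (has_a & has_b)
    d = av - bv
    d[~keep] = np.nan
    return d


def distance_stratified_correlation(
    a: ContactMatrix, b: ContactMatrix, stratum_width: int = 250_000
) -> "pd.DataFrame":
    """Pearson correlation of cis pixel values per distance stratum.

    Strata are [0, w), [w, 2w), ... in bp. Strata with fewer than 3
    defined pixel pairs are NaN.
    """
    import pandas as pd

    if a.bins != b.bins:
        raise ValueError("correlation requires identical bin tables")
    res = a.resolution
    if stratum_width % res:
        warnings.warn("stratum width is not a multiple of the resolution; strata are truncated")
    diags_per_stratum = max(1, stratum_width // res)
    rows = []
    max_bins = max(a.bins.n_bins_of(c) for c in a.bins.chromosomes)
    n_strata = -(-max_bins // diags_per_stratum)
    for s in range(n_strata):
        va, vb = [], []
        for chrom in a.bins.chromosomes:
            sl = a.bins.chrom_slice(chrom)
            sa, sb = a.matrix[sl, sl], b.matrix[sl, sl]
            n = sa.shape[0]
            for d in range(s * diags_per_stratum, min((s + 1) * diags_per_stratum, n)):
                va.append(np.diagonal(sa, d))
                vb.append(np.diagonal(sb, d))
        if not va:
            continue
        va = np.concatenate(va)
        vb = np.concatenate(vb)
        ok = ~np.isnan(va) & ~np.isnan(vb)
        if ok.sum() < 3 or np.std(va[ok]) == 0 or np.std(vb[ok]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
        rows.append(
            {
                "stratum_start": s * stratum_width,
                "stratum_end": (s + 1) * stratum_width,
                "pearson_r": r,
                "n_pixels": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
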