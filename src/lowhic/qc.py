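"""Library-quality read-outs: filter statistics, cis/trans ratios and the
library-complexity (unique fragment pairs vs depth) curve."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .genome import BinTable
from .pairs import PairStats, ValidPair, cis_trans_ratio, deduplicate


@dataclass
class QCReport:
    stats: PairStats
    cis_trans_raw: float
    cis_trans_normalised: float
    complexity: list[tuple[int, int]] = field(default_factory=list)  # (depth, unique)

    def as_rows(self) -> list[tuple[str, object]]:
        rows: list[tuple[str, object]] = [
            ("total_pairs", self.stats.total),
            ("valid_pairs", self.stats.valid),
            ("cis", self.stats.cis),
            ("trans", self.stats.trans),
            ("cis_trans_ratio", self.cis_trans_raw),
            ("cis_trans_ratio_normalised", self.cis_trans_normalised),
            ("duplicate_fraction", self.stats.duplicate_fraction),
        ]
        rows += [(f"filtered_{k}", v) for k, v in self.stats.categories.items()]
        rows += [(f"unique_at_{d}", u) for d, u in self.complexity]
        return rows


def complexity_curve(
    pairs: list[ValidPair], depths: list[int], seed: int, tolerance: int = 2
) -> list[tuple[int, int]]:
    """Unique fragment-pair counts at down-sampled depths.

    Each depth draws that many pairs without replacement (seeded) and
    counts distinct loci pairs at the duplicate-matching tolerance.
    """
    rng = np.random.default_rng(seed)
    n = len(pairs)
    out = []
    for depth in depths:
        if depth > n:
            raise ValueError(f"depth {depth} exceeds total pairs {n}")
        if depth == 0:
            out.append((0, 0))
            continue
        idx = rng.choice(n, size=depth, replace=False)
        sample = [copy.copy(pairs[i]) for i in idx]
        for p in sample:
            p.flags = set()
        retained, _ = deduplicate(sample, tolerance)
        out.append((depth, len(retained)))
    return out


def qc_report(
    flagged_pairs: list[ValidPair],
    stats: PairStats,
    bins: BinTable,
    depths: list[int] | None = None,
    seed: int = 0,
) -> QCReport:
    raw, norm = cis_trans_ratio(stats.cis, stats.trans, bins)
    curve = complexity_curve(flagged_pairs, depths, seed) if depths else []
    return QCReport(stats, raw, norm, curve)
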