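"""Primer–gene proximity enrichment.

Tests whether a primer's genomic occurrences are enriched within a fixed
flank (default 100 kb each side) of a focal gene set relative to an
equally-sized random control set, with a 2×2 chi-square on the counts of
genes with/without at least one proximal site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .io import Interval
from .irap import PrimerSite

DEFAULT_FLANK_BP = 100_000


@dataclass
class ProximityCount:
    gene_set: str
    n_genes: int
    n_with_hit: int
    flank_bp: int = DEFAULT_FLANK_BP

    @property
    def n_without_hit(self) -> int:
        return self.n_genes - self.n_with_hit


@dataclass
class ChiSquareResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_value: float
    df: int = 1
    continuity_correction: bool = True


def count_proximal(genes: Sequence[Interval],
                   sites: Sequence[PrimerSite | tuple[str, int]],
                   chrom_lengths: Mapping[str, int],
                   flank_bp: int = DEFAULT_FLANK_BP,
                   gene_set: str = "genes") -> ProximityCount:
    """Count genes with ≥1 primer site within [start − flank, end + flank]
    (inclusive boundaries, windows clipped at chromosome edges)."""
    pos_by_chrom: dict[str, list[int]] = {}
    for s in sites:
        chrom, pos = (s.chrom, s.position) if isinstance(s, PrimerSite) else s
        pos_by_chrom.setdefault(chrom, []).append(pos)
    arrays = {c: np.sort(np.asarray(p)) for c, p in pos_by_chrom.items()}
    n_with = 0
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.name!r} on unknown chromosome {g.chrom!r}")
        lo = max(1, g.start - flank_bp)
        hi = min(chrom_lengths[g.chrom], g.end + flank_bp)
        pos = arrays.get(g.chrom)
        if pos is None:
            continue
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        if j > i:
            n_with += 1
    return ProximityCount(gene_set=gene_set, n_genes=len(genes),
                          n_with_hit=n_with, flank_bp=flank_bp)


def sample_control_genes(all_genes: Sequence[Interval],
                         exclude: Sequence[Interval],
                         n: int, seed: int = 0) -> list[Interval]:
    """Uniform sample without replacement from the gene pool, excluding the
    focal set; deterministic per seed."""
    excl = {(g.chrom, g.start, g.end) for g in exclude}
    pool = [g for g in all_genes if (g.chrom, g.start, g.end) not in excl]
    if len(pool) < n:
        raise ValueError(f"gene pool ({len(pool)}) smaller than n ({n})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def chi_square_2x2(a_with: int, a_without: int, b_with: int, b_without: int,
                   continuity_correction: bool = True) -> ChiSquareResult:
    """Pearson chi-square on a 2×2 table, Yates-corrected by default
    (the correction is what reproduces gene-set enrichment p-values computed
    from small gene counts), df = 1."""
    cells = np.array([[a_with, a_without], [b_with, b_without]], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be >= 0")
    rows = cells.sum(axis=1)
    cols = cells.sum(axis=0)
    total = cells.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    expected = np.outer(rows, cols) / total
    diff = np.abs(cells - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return ChiSquareResult(table=((a_with, a_without), (b_with, b_without)),
                           statistic=stat, p_value=p,
                           continuity_correction=continuity_correction)


def enrichment_test(focal: ProximityCount, control: ProximityCount,
                    continuity_correction: bool = True) -> ChiSquareResult:
    return chi_square_2x2(focal.n_with_hit, focal.n_without_hit,
                          control.n_with_hit, control.n_without_hit,
                          continuity_correction=continuity_correction)
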