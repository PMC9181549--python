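"""Insertion-time estimation for LTR retrotransposons.

Two complementary procedures:

* **LTR-pair dating** — the two LTRs of an element are identical at insertion
  and diverge independently afterwards, so the Kimura two-parameter (K2P)
  distance K between them converts to an age ``T = K / (2 r)`` with r the
  per-LTR substitution rate (default 2e-8 /site/year, i.e. twice a typical
  synonymous rate, reflecting the faster decay of repeats).
* **RT-read dating** — short reads are aligned to reverse-transcriptase
  (RT) encoding reference sequences of a lineage; pairwise K2P distances
  between co-mapped reads on their overlap estimate divergence between the
  element copies the reads came from, and convert to MYA the same way.
  This sidesteps the bias of full-length element isolation toward young
  insertions.

Age profiles are histograms of the per-element (or per-read-pair) ages;
peaks of a kernel-smoothed density are read as transposition bursts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .align import ReadMapper
from .simulate import DEFAULT_RATE


class SaturationError(ValueError):
    """K2P distance undefined: too many differences for the correction."""


@dataclass
class K2PDistance:
    P: float               # transition proportion
    Q: float               # transversion proportion
    K: float               # substitutions per site
    sites_compared: int    # gap columns excluded


@dataclass
class AgeEstimate:
    id: str
    K: float
    T: float               # MYA
    rate: float
    lineage: str | None = None


@dataclass
class AgeProfile:
    lineage: str | None
    bin_edges: np.ndarray      # MYA
    counts: np.ndarray
    mean_age: float
    peak_ages: list[float]
    n_excluded: int = 0        # saturated / undatable inputs


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
# transition pairs differ but share purine/pyrimidine class
_IS_PURINE = np.array([True, False, True, False])


def k2p(seq_a: str, seq_b: str) -> K2PDistance:
    """Kimura two-parameter distance between two aligned sequences.

    ``K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`` with P and Q the transition
    and transversion proportions over gap-free, unambiguous columns.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = _CODE[np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)]
    b = _CODE[np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)]
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable (gap-free) sites")
    av, bv = a[valid], b[valid]
    diff = av != bv
    ts = diff & (_IS_PURINE[av] == _IS_PURINE[bv])
    P = float(ts.sum()) / n
    Q = float(diff.sum() - ts.sum()) / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution saturation (P={P:.3f}, Q={Q:.3f}): distance undefined")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PDistance(P=P, Q=Q, K=K, sites_compared=n)


def k2p_to_mya(K: float, rate: float = DEFAULT_RATE) -> float:
    """T (MYA) = K / (2 r) / 1e6 — each LTR accumulates r per year."""
    return K / (2.0 * rate) / 1e6


_NW_ALIGNER = None


def _global_alignment(a: str, b: str) -> tuple[str, str]:
    """End-to-end alignment with affine gap penalties (EDNAFULL-like
    match 5 / mismatch -4, gap open 16 / extend 4).

    Equal-length pairs are compared column-wise: with gaps this expensive a
    substitution-only pair aligns without gaps, and cheap unit-cost gaps
    would otherwise absorb mismatch columns at high divergence and bias K
    downward (gap columns are excluded from the K2P counts).
    """
    if len(a) == len(b):
        return a, b
    global _NW_ALIGNER
    if _NW_ALIGNER is None:
        from Bio import Align
        _NW_ALIGNER = Align.PairwiseAligner()
        _NW_ALIGNER.mode = "global"
        _NW_ALIGNER.match_score = 5
        _NW_ALIGNER.mismatch_score = -4
        _NW_ALIGNER.open_gap_score = -16
        _NW_ALIGNER.extend_gap_score = -4
    aln = _NW_ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def ltr_pair_age(ltr5: str, ltr3: str, rate: float = DEFAULT_RATE,
                 element_id: str = "", lineage: str | None = None) -> AgeEstimate:
    """Globally align the two LTR sequences, then K2P → MYA."""
    aln_a, aln_b = _global_alignment(ltr5, ltr3)
    dist = k2p(aln_a, aln_b)
    return AgeEstimate(id=element_id, K=dist.K, T=k2p_to_mya(dist.K, rate),
                       rate=rate, lineage=lineage)


def ltr_insertion_age(element, genome, rate: float = DEFAULT_RATE,
                      lineage: str | None = None) -> AgeEstimate:
    """Age of one detected element (any object exposing ``chrom``, ``ltr5``
    and ``ltr3`` interval attributes) on its genome."""
    s5, e5 = element.ltr5
    s3, e3 = element.ltr3
    ltr5 = genome.fetch(element.chrom, s5, e5)
    ltr3 = genome.fetch(element.chrom, s3, e3)
    eid = getattr(element, "element_id", "")
    return ltr_pair_age(ltr5, ltr3, rate=rate, element_id=eid, lineage=lineage)


def date_elements(elements: Iterable, genome, rate: float = DEFAULT_RATE,
                  lineages: Mapping[str, str] | None = None,
                  ) -> tuple[list[AgeEstimate], int]:
    """LTR-pair ages for a set of elements; saturated elements are excluded
    and counted rather than clamped."""
    estimates: list[AgeEstimate] = []
    n_saturated = 0
    for el in elements:
        eid = getattr(el, "element_id", "")
        lin = lineages.get(eid) if lineages else None
        try:
            estimates.append(ltr_insertion_age(el, genome, rate, lineage=lin))
        except SaturationError:
            n_saturated += 1
    return estimates, n_saturated


# ---------------------------------------------------------------------------
# RT-read dating
# ---------------------------------------------------------------------------

def rt_read_dating(rt_refs: Mapping[str, tuple[str, str]],
                   reads: Sequence[tuple[str, str]],
                   rate: float = DEFAULT_RATE,
                   min_overlap: int = 40,
                   length_fraction: float = 0.9,
                   similarity: float = 0.8,
                   max_pairs_per_ref: int = 5000,
                   seed: int = 0) -> dict[str, list[AgeEstimate]]:
    """Per-lineage insertion-age estimates from read pairs co-mapped to RT
    references.

    ``rt_refs`` maps a reference id to ``(lineage, sequence)``; references
    shorter than 150 nt are rejected.  Reads are kept when at least
    ``length_fraction`` of their length aligns at ``similarity`` identity or
    better.  All (sub-sampled) pairs of reads on the same reference whose
    mapped spans overlap by ``min_overlap`` nt are compared with K2P on the
    overlap (pairwise deletion; reads whose alignment needed gaps are
    skipped), and each pairwise K converts to MYA.
    """
    for rid, (_lin, seq) in rt_refs.items():
        if len(seq) < 150:
            raise ValueError(f"RT reference {rid!r} shorter than 150 nt")
    mapper = ReadMapper({rid: seq for rid, (_l, seq) in rt_refs.items()},
                        length_fraction=length_fraction, similarity=similarity)
    by_ref: dict[str, list] = {rid: [] for rid in rt_refs}
    for rid, seq in reads:
        aln = mapper.map_read(rid, seq)
        if aln is not None and not aln.gapped:
            by_ref[aln.ref_id].append(aln)
    rng = np.random.default_rng(seed)
    out: dict[str, list[AgeEstimate]] = {}
    for ref_id, alns in by_ref.items():
        lineage = rt_refs[ref_id][0]
        ests = out.setdefault(lineage, [])
        n = len(alns)
        if n < 2:
            continue
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        if len(pairs) > max_pairs_per_ref:
            idx = rng.choice(len(pairs), size=max_pairs_per_ref, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]
        for i, j in pairs:
            a, b = alns[i], alns[j]
            lo = max(a.ref_start, b.ref_start)
            hi = min(a.ref_start + a.aligned_length,
                     b.ref_start + b.aligned_length)   # exclusive
            if hi - lo < min_overlap:
                continue
            sa = a.read_sequence[lo - a.ref_start: hi - a.ref_start]
            sb = b.read_sequence[lo - b.ref_start: hi - b.ref_start]
            try:
                dist = k2p(sa, sb)
            except SaturationError:
                continue
            ests.append(AgeEstimate(id=f"{a.read_id}|{b.read_id}", K=dist.K,
                                    T=k2p_to_mya(dist.K, rate), rate=rate,
                                    lineage=lineage))
    return out


# ---------------------------------------------------------------------------
# age profiles
# ---------------------------------------------------------------------------

def age_profile(estimates: Sequence[AgeEstimate] | Sequence[float],
                bin_width_mya: float = 0.25,
                smoothing_bandwidth: float | None = None,
                peak_prominence: float = 0.05,
                lineage: str | None = None,
                n_excluded: int = 0) -> AgeProfile:
    """Histogram of ages with burst peaks.

    Peaks are local maxima of the histogram smoothed with a Gaussian kernel
    (bandwidth defaults to the bin width) whose prominence exceeds
    ``peak_prominence`` times the density maximum.
    """
    ages = np.asarray([e.T if isinstance(e, AgeEstimate) else float(e)
                       for e in estimates], dtype=float)
    if ages.size == 0:
        raise ValueError("no age estimates")
    if smoothing_bandwidth is None:
        smoothing_bandwidth = bin_width_mya
    top = max(ages.max(), bin_width_mya)
    n_bins = int(math.ceil(top / bin_width_mya)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width_mya - 1e-12, bin_width_mya)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width_mya)
    counts, edges = np.histogram(ages, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma = smoothing_bandwidth / bin_width_mya
    density = gaussian_filter1d(counts.astype(float), sigma=sigma,
                                mode="constant")
    padded = np.concatenate([[0.0], density, [0.0]])
    peaks, _props = find_peaks(padded,
                               prominence=peak_prominence * padded.max())
    peak_ages = [float(centers[p - 1]) for p in peaks]
    return AgeProfile(lineage=lineage, bin_edges=edges, counts=counts,
                      mean_age=float(ages.mean()), peak_ages=peak_ages,
                      n_excluded=n_excluded)
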