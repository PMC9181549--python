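"""De-novo structural detection of full-length LTR retrotransposons.

The search looks for pairs of near-identical direct repeats (the two LTRs) at
an element-like separation: exact k-mer matches on the same diagonal are
chained into repeat-pair candidates, candidate repeat copies are extended by
ungapped X-drop extension, and candidates are then scored by global LTR-LTR
alignment identity, annotated with TG…CA terminal motifs and target-site
duplications, filtered, and de-overlapped.

Because a direct repeat stays a direct repeat under reverse complementation,
one forward scan finds elements of both orientations; strand is left to the
protein-domain annotation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .io import Genome, GffRecord

DEFAULT_MIN_LTR = 100
DEFAULT_MAX_LTR = 3000
DEFAULT_MIN_ELEM = 1000
DEFAULT_MAX_ELEM = 16000
DEFAULT_SEED_K = 20
DEFAULT_MIN_IDENTITY = 85.0

_BASE_INDEX = np.full(256, 255, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class Candidate:
    chrom: str
    copy1: tuple[int, int]   # putative 5' LTR, 1-based inclusive
    copy2: tuple[int, int]   # putative 3' LTR
    n_seeds: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.copy1[0], self.copy2[1])

    @property
    def length(self) -> int:
        return self.copy2[1] - self.copy1[0] + 1


@dataclass
class FullLengthElement:
    element_id: str
    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float              # percent, 0-100
    tg_ca_5: bool = False
    tg_ca_3: bool = False
    tsd: str | None = None
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def internal(self) -> tuple[int, int]:
        return (self.ltr5[1] + 1, self.ltr3[0] - 1)


# ---------------------------------------------------------------------------
# seeding and chaining
# ---------------------------------------------------------------------------

def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = arr.size
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + arr[j:j + m]
    invalid = (arr == 255).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    clean = (csum[k:] - csum[:-k]) == 0
    return codes, clean


def _seed_pairs(codes: np.ndarray, clean: np.ndarray, sep_min: int,
                sep_max: int, max_occ: int) -> tuple[np.ndarray, np.ndarray]:
    pos = np.nonzero(clean)[0]
    vals = codes[pos]
    order = np.argsort(vals, kind="stable")
    sv, sp = vals[order], pos[order]
    bounds = np.nonzero(np.diff(sv))[0] + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [sv.size]])
    p1_all, p2_all = [], []
    for s, e in zip(starts, ends):
        g = e - s
        if g < 2 or g > max_occ:
            continue
        p = np.sort(sp[s:e])
        d = p[None, :] - p[:, None]
        i, j = np.nonzero((d >= sep_min) & (d <= sep_max))
        if i.size:
            p1_all.append(p[i])
            p2_all.append(p[j])
    if not p1_all:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    return np.concatenate(p1_all), np.concatenate(p2_all)


def _chain(p1: np.ndarray, p2: np.ndarray, k: int, band: int = 16,
           max_gap: int = 400) -> list[tuple[int, int, int, int, int]]:
    """Chain co-diagonal seed pairs; returns (a1, b1, a2, b2, n) 0-based
    inclusive bounds of the two repeat copies."""
    if p1.size == 0:
        return []
    diag = p2 - p1
    order = np.lexsort((p1, diag))
    p1o, p2o, do = p1[order], p2[order], diag[order]
    chains = []
    a1 = b1 = int(p1o[0])
    a2 = b2 = int(p2o[0])
    cur_d = int(do[0])
    n = 1
    for x1, x2, d in zip(p1o[1:], p2o[1:], do[1:]):
        if abs(int(d) - cur_d) <= band and int(x1) - b1 <= max_gap:
            b1, b2 = max(b1, int(x1)), max(b2, int(x2))
            a2 = min(a2, int(x2))
            n += 1
        else:
            chains.append((a1, b1 + k - 1, a2, b2 + k - 1, n))
            a1 = b1 = int(x1)
            a2 = b2 = int(x2)
            cur_d = int(d)
            n = 1
    chains.append((a1, b1 + k - 1, a2, b2 + k - 1, n))
    return chains


def _extend(arr: np.ndarray, e1: int, e2: int, direction: int,
            limit: int, xdrop: int = 15) -> int:
    """Ungapped X-drop extension (match +1, mismatch -2) of positions e1/e2
    in direction ±1; returns the number of steps of the best extension."""
    best = cur = 0
    best_t = 0
    t = 1
    n = arr.size
    while t <= limit:
        i, j = e1 + direction * t, e2 + direction * t
        if i < 0 or j < 0 or i >= n or j >= n:
            break
        if arr[i] == 255 or arr[j] == 255:
            break
        cur += 1 if arr[i] == arr[j] else -2
        if cur > best:
            best, best_t = cur, t
        if best - cur > xdrop:
            break
        t += 1
    return best_t


def find_candidates(genome: Genome, k: int = DEFAULT_SEED_K,
                    min_ltr: int = DEFAULT_MIN_LTR,
                    max_ltr: int = DEFAULT_MAX_LTR,
                    min_elem: int = DEFAULT_MIN_ELEM,
                    max_elem: int = DEFAULT_MAX_ELEM,
                    max_kmer_occ: int = 200) -> list[Candidate]:
    """Repeat-pair candidates: same-strand maximal exact-match seed chains
    whose separation is compatible with a full-length element."""
    if min_ltr < k:
        raise ValueError("min_ltr must be >= seed length k")
    if min_elem <= 2 * min_ltr:
        raise ValueError("min_elem must exceed 2 * min_ltr")
    sep_min = max(min_ltr, min_elem - max_ltr)
    sep_max = max_elem - min_ltr
    out: list[Candidate] = []
    for chrom in genome:
        seq = genome.sequences[chrom]
        if len(seq) < max(k, min_elem):
            continue
        arr = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
        codes, clean = _kmer_codes(arr, k)
        p1, p2 = _seed_pairs(codes, clean, sep_min, sep_max, max_kmer_occ)
        chains = _chain(p1, p2, k)
        cands: list[Candidate] = []
        for a1, b1, a2, b2, n in chains:
            # extend both copies jointly at each end
            left = _extend(arr, a1, a2, -1, limit=max_ltr)
            right = _extend(arr, b1, b2, +1, limit=max_ltr)
            a1e, a2e = a1 - left, a2 - left
            b1e, b2e = b1 + right, b2 + right
            if b1e >= a2e:                        # copies must not overlap
                continue
            l1 = b1e - a1e + 1
            l2 = b2e - a2e + 1
            if not (min_ltr <= l1 <= max_ltr and min_ltr <= l2 <= max_ltr):
                continue
            span = b2e - a1e + 1
            if not (min_elem <= span <= max_elem):
                continue
            cands.append(Candidate(chrom=chrom, copy1=(a1e + 1, b1e + 1),
                                   copy2=(a2e + 1, b2e + 1), n_seeds=n))
        out.extend(_dedupe(cands))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _dedupe(cands: list[Candidate]) -> list[Candidate]:
    """Collapse candidates describing the same repeat pair (both copies
    reciprocally overlapping ≥ 50%); the best-supported one is kept."""
    cands = sorted(cands, key=lambda c: (-c.n_seeds, c.copy1[0]))
    kept: list[Candidate] = []
    for c in cands:
        dup = False
        for kc in kept:
            for iv_c, iv_k in ((c.copy1, kc.copy1), (c.copy2, kc.copy2)):
                ov = _overlap(iv_c, iv_k)
                len_c = iv_c[1] - iv_c[0] + 1
                len_k = iv_k[1] - iv_k[0] + 1
                if ov < 0.5 * len_c or ov < 0.5 * len_k:
                    break
            else:
                dup = True
            if dup:
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda c: c.copy1[0])
    return kept


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def _ltr_identity(seq1: str, seq2: str) -> float:
    res = edlib.align(seq1, seq2, mode="NW", task="distance")
    return 100.0 * (1.0 - res["editDistance"] / max(len(seq1), len(seq2)))


def _find_tsd(seq: str, start: int, end: int,
              lengths: Sequence[int] = (6, 5, 4)) -> str | None:
    """Identical flank words immediately outside [start, end] (1-based)."""
    for d in lengths:
        if start - 1 - d < 0 or end + d > len(seq):
            continue
        left = seq[start - 1 - d:start - 1]
        right = seq[end:end + d]
        if left == right and len(set(left)) > 1:
            return left
    return None


_JITTER_ORDER = (0, -1, 1, -2, 2, -3, 3)


def _snap_to_motif(seq: str, copy1: tuple[int, int], copy2: tuple[int, int],
                   ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Nudge both repeat copies by a common shift (<= 3 bp) so that they
    start with TG and end with CA when such a shift exists; ungapped X-drop
    extension can overshoot repeat edges by chance matches."""
    (s1, e1), (s2, e2) = copy1, copy2
    for d in _JITTER_ORDER:
        a, b = s1 + d, s2 + d
        if a >= 1 and seq[a - 1:a + 1] == "TG" == seq[b - 1:b + 1]:
            s1, s2 = a, b
            break
    for d in _JITTER_ORDER:
        a, b = e1 + d, e2 + d
        if b <= len(seq) and seq[a - 2:a] == "CA" == seq[b - 2:b]:
            e1, e2 = a, b
            break
    if s1 < e1 and s2 < e2 and e1 < s2:
        return (s1, e1), (s2, e2)
    return copy1, copy2


def refine_and_filter(genome: Genome, candidates: Sequence[Candidate],
                      min_identity: float = DEFAULT_MIN_IDENTITY,
                      require_tg_ca: bool = False,
                      tsd_search: bool = True,
                      max_ltr_length_ratio: float = 0.2,
                      ) -> list[FullLengthElement]:
    """Score candidates by global LTR-LTR identity, annotate TG…CA and TSD
    evidence, apply thresholds, and resolve overlaps.

    Overlap resolution ranks candidates by LTR identity plus small bonuses
    for structural corroboration (+3 for a TSD, +1 for TG…CA on both LTRs):
    a spurious repeat pair formed between two neighbouring same-lineage
    elements (or a solo LTR) can out-score a genuine element on raw identity
    but essentially never shows a shared target-site duplication.  Remaining
    ties go to the longer, then leftmost candidate (deterministic).  TG…CA
    and TSD stay annotations, not filters, unless ``require_tg_ca`` is set.
    """
    scored: list[FullLengthElement] = []
    for c in candidates:
        seq = genome.sequences[c.chrom]
        copy1, copy2 = _snap_to_motif(seq, c.copy1, c.copy2)
        c = Candidate(chrom=c.chrom, copy1=copy1, copy2=copy2,
                      n_seeds=c.n_seeds)
        s1 = seq[c.copy1[0] - 1:c.copy1[1]]
        s2 = seq[c.copy2[0] - 1:c.copy2[1]]
        l1, l2 = len(s1), len(s2)
        if abs(l1 - l2) > max_ltr_length_ratio * max(l1, l2):
            continue
        identity = _ltr_identity(s1, s2)
        if identity < min_identity:
            continue
        el = FullLengthElement(
            element_id="", chrom=c.chrom,
            start=c.copy1[0], end=c.copy2[1],
            ltr5=c.copy1, ltr3=c.copy2, ltr_identity=identity,
            tg_ca_5=s1.startswith("TG") and s1.endswith("CA"),
            tg_ca_3=s2.startswith("TG") and s2.endswith("CA"),
            tsd=_find_tsd(seq, c.copy1[0], c.copy2[1]) if tsd_search else None)
        if require_tg_ca and not (el.tg_ca_5 and el.tg_ca_3):
            continue
        scored.append(el)

    def resolution_score(e: FullLengthElement) -> float:
        return (e.ltr_identity + (3.0 if e.tsd else 0.0)
                + (1.0 if e.tg_ca_5 and e.tg_ca_3 else 0.0))

    scored.sort(key=lambda e: (-resolution_score(e), -e.length, e.start))
    kept: list[FullLengthElement] = []
    for el in scored:
        ok = True
        for ke in kept:
            if ke.chrom != el.chrom:
                continue
            ov = _overlap((el.start, el.end), (ke.start, ke.end))
            if ov == 0:
                continue
            # true nesting: the inner element sits inside the outer's
            # internal region (a nested insertion never touches host LTRs)
            nested = ((ke.internal[0] <= el.start and el.end <= ke.internal[1])
                      or (el.internal[0] <= ke.start
                          and ke.end <= el.internal[1]))
            if not nested:
                ok = False
                break
        if ok:
            kept.append(el)
    kept.sort(key=lambda e: (e.chrom, e.start))
    for i, el in enumerate(kept):
        el.element_id = f"RE{i:05d}"
    return kept


def detect_elements(genome: Genome, **kwargs) -> list[FullLengthElement]:
    """find_candidates + refine_and_filter with shared defaults."""
    cand_keys = {"k", "min_ltr", "max_ltr", "min_elem", "max_elem",
                 "max_kmer_occ"}
    ckw = {k: v for k, v in kwargs.items() if k in cand_keys}
    rkw = {k: v for k, v in kwargs.items() if k not in cand_keys}
    return refine_and_filter(genome, find_candidates(genome, **ckw), **rkw)


# ---------------------------------------------------------------------------
# evaluation against simulation truth
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = _overlap(a, b)
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def evaluate(predictions: Sequence[FullLengthElement], truth: Sequence,
             min_reciprocal_overlap: float = 0.8) -> dict[str, float]:
    """Precision/recall of predicted elements against truth records, matched
    one-to-one at a reciprocal-overlap threshold."""
    unmatched = list(truth)
    tp = 0
    for p in predictions:
        best_i, best_ov = -1, 0.0
        for i, t in enumerate(unmatched):
            if t.chrom != p.chrom:
                continue
            ov = _reciprocal_overlap((p.start, p.end), (t.start, t.end))
            if ov > best_ov:
                best_i, best_ov = i, ov
        if best_i >= 0 and best_ov >= min_reciprocal_overlap:
            tp += 1
            unmatched.pop(best_i)
    n_pred, n_truth = len(predictions), len(truth)
    return {
        "true_positives": tp,
        "n_predicted": n_pred,
        "n_truth": n_truth,
        "precision": tp / n_pred if n_pred else 0.0,
        "recall": tp / n_truth if n_truth else 0.0,
    }


def elements_to_gff(elements: Sequence[FullLengthElement]) -> list[GffRecord]:
    out: list[GffRecord] = []
    for el in elements:
        attrs = {"ID": el.element_id,
                 "ltr_identity": f"{el.ltr_identity:.2f}"}
        if el.tsd:
            attrs["tsd"] = el.tsd
        out.append(GffRecord(el.chrom, "retroscape", "LTR_retrotransposon",
                             el.start, el.end, strand=el.strand,
                             attributes=attrs))
        for side, (s, e) in (("ltr5", el.ltr5), ("ltr3", el.ltr3)):
            out.append(GffRecord(el.chrom, "retroscape", "long_terminal_repeat",
                                 s, e, strand=el.strand,
                                 attributes={"Parent": el.element_id,
                                             "side": side}))
    return out
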