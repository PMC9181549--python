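"""Short-read to reference alignment used by abundance estimation and
read-based dating.

A seed-and-verify semi-global mapper: exact k-mer seeds vote for
(reference, diagonal) candidates, each candidate is verified by direct
base-wise comparison on its diagonal (the simulated data are
substitution-only), with an edit-distance (edlib) fallback for gapped cases.
Acceptance follows the mapping filters used for repeat abundance work:
at least ``length_fraction`` of the read aligned at ``similarity`` identity
or better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from .io import revcomp

_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _enc(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class ReadAlignment:
    read_id: str
    ref_id: str
    ref_start: int            # 1-based position of the first aligned ref base
    strand: str               # orientation of the read relative to the ref
    aligned_length: int
    matches: int
    identity: float           # matches / aligned_length
    read_sequence: str        # read in reference orientation
    gapped: bool = False
    tie_refs: list[str] = field(default_factory=list)  # equally good other refs


class ReadMapper:
    """Index a reference set once, then map reads against it."""

    def __init__(self, refs: Mapping[str, str], k: int = 14,
                 length_fraction: float = 0.9, similarity: float = 0.8,
                 n_seeds: int = 5, gapped_fallback: bool = True):
        self.k = k
        self.length_fraction = length_fraction
        self.similarity = similarity
        self.n_seeds = n_seeds
        self.gapped_fallback = gapped_fallback
        self.ref_ids = list(refs)
        self.ref_seqs = [refs[r] for r in self.ref_ids]
        self.ref_arrs = [_enc(s) for s in self.ref_seqs]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, seq in enumerate(self.ref_seqs):
            for pos in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[pos:pos + k], []).append((ri, pos))

    # -- single read -----------------------------------------------------
    def _candidates(self, seq: str) -> dict[tuple[int, int], int]:
        L, k = len(seq), self.k
        if L < k:
            return {}
        offs = np.unique(np.linspace(0, L - k, self.n_seeds).astype(int))
        votes: dict[tuple[int, int], int] = {}
        for off in offs:
            for ri, pos in self.index.get(seq[off:off + k], ()):
                key = (ri, pos - int(off))
                votes[key] = votes.get(key, 0) + 1
        return votes

    def _verify(self, seq: str, arr: np.ndarray, ri: int, diag: int):
        """Ungapped verification on one diagonal; returns
        (ref_start0, aligned_len, matches) or None."""
        ref = self.ref_arrs[ri]
        L = arr.size
        r0, r1 = max(diag, 0), min(diag + L, ref.size)
        alen = r1 - r0
        if alen < self.length_fraction * L:
            return None
        q0 = r0 - diag
        matches = int((ref[r0:r1] == arr[q0:q0 + alen]).sum())
        if matches / alen < self.similarity:
            return None
        return (r0, alen, matches)

    def _verify_gapped(self, seq: str, ri: int):
        """edlib semi-global (whole read into ref infix)."""
        max_ed = int((1.0 - self.similarity) * len(seq))
        res = edlib.align(seq, self.ref_seqs[ri], mode="HW", task="locations",
                          k=max_ed)
        if res["editDistance"] < 0:
            return None
        s, e = res["locations"][0]
        alen = e - s + 1
        matches = max(alen, len(seq)) - res["editDistance"]
        if matches / max(alen, len(seq)) < self.similarity:
            return None
        return (s, alen, matches)

    def map_read(self, read_id: str, seq: str,
                 exhaustive: bool = False) -> ReadAlignment | None:
        best: ReadAlignment | None = None
        ties: list[str] = []
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            arr = _enc(oriented)
            cands = self._candidates(oriented)
            tried: set[int] = set()
            items = sorted(cands.items(), key=lambda kv: (-kv[1], kv[0]))
            for (ri, diag), _votes in items[:20]:
                hit = self._verify(oriented, arr, ri, diag)
                gapped = False
                if hit is None and self.gapped_fallback and ri not in tried:
                    tried.add(ri)
                    hit = self._verify_gapped(oriented, ri)
                    gapped = hit is not None
                if hit is None:
                    continue
                r0, alen, matches = hit
                aln = ReadAlignment(read_id=read_id, ref_id=self.ref_ids[ri],
                                    ref_start=r0 + 1, strand=strand,
                                    aligned_length=alen, matches=matches,
                                    identity=matches / alen,
                                    read_sequence=oriented, gapped=gapped)
                if best is None or matches > best.matches:
                    best, ties = aln, []
                elif (matches == best.matches
                      and aln.ref_id != best.ref_id
                      and aln.ref_id not in ties):
                    ties.append(aln.ref_id)
            if exhaustive and best is None:
                for ri in range(len(self.ref_ids)):
                    hit = self._verify_gapped(oriented, ri)
                    if hit is None:
                        continue
                    r0, alen, matches = hit
                    aln = ReadAlignment(read_id=read_id,
                                        ref_id=self.ref_ids[ri],
                                        ref_start=r0 + 1, strand=strand,
                                        aligned_length=alen, matches=matches,
                                        identity=matches / alen,
                                        read_sequence=oriented, gapped=True)
                    if best is None or matches > best.matches:
                        best, ties = aln, []
                    elif matches == best.matches and aln.ref_id != best.ref_id:
                        ties.append(aln.ref_id)
        if best is not None:
            best.tie_refs = ties
        return best

    def map_reads(self, reads: Sequence[tuple[str, str]],
                  exhaustive: bool = False) -> list[ReadAlignment | None]:
        return [self.map_read(rid, seq, exhaustive=exhaustive)
                for rid, seq in reads]
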