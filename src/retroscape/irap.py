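"""In-silico IRAP: primer-site scanning, amplicon prediction, band matrices
and PCA ordination.

IRAP (inter-retrotransposon amplified polymorphism) amplifies the region
between LTRs of two neighbouring elements.  Here a primer is scanned against
a genome (IUPAC-aware, limited mismatches, 3'-protected), facing site pairs
within gel-resolvable product sizes become amplicons, per-accession amplicon
sets are pooled into size-binned presence/absence band matrices, and a PCA
of the matrix ordinates the accessions.

Admixture inference and Evanno ΔK model selection live in
:mod:`retroscape.structure` and are re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import Genome, bundled_data, revcomp
from .structure import (AncestryEstimate, AdmixtureResults, DominantAdmixture,
                        EvannoResult, classify_admixed, evanno_delta_k)

__all__ = [
    "PrimerSite", "Amplicon", "find_primer_sites", "predict_amplicons",
    "band_matrix", "pca", "load_primers",
    "DominantAdmixture", "AdmixtureResults", "AncestryEstimate",
    "EvannoResult", "evanno_delta_k", "classify_admixed",
]

DEFAULT_MIN_AMPLICON = 100
DEFAULT_MAX_AMPLICON = 3000

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PrimerSite:
    chrom: str
    position: int          # 1-based genome position of the primer's 3' end
    strand: str            # "+" or "-"
    mismatches: int
    primer_length: int

    @property
    def five_prime(self) -> int:
        if self.strand == "+":
            return self.position - self.primer_length + 1
        return self.position + self.primer_length - 1


@dataclass(frozen=True)
class Amplicon:
    chrom: str
    start: int             # 1-based inclusive span between the primer 5' ends
    end: int
    forward_site: PrimerSite
    reverse_site: PrimerSite

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def load_primers() -> pd.DataFrame:
    """The bundled IRAP primer panel (11 LTR primers; code, direction,
    sequence)."""
    return bundled_data("irap_primers.tsv")


# ---------------------------------------------------------------------------
# primer-site scanning
# ---------------------------------------------------------------------------

def _allowed_table(primer: str) -> np.ndarray:
    """(len, 256) bool lookup: which genome byte satisfies each primer base."""
    tab = np.zeros((len(primer), 256), dtype=bool)
    for i, ch in enumerate(primer):
        if ch not in _IUPAC:
            raise ValueError(f"primer contains non-IUPAC character {ch!r}")
        for b in _IUPAC[ch]:
            tab[i, ord(b)] = True
    return tab


def _scan(seq_bytes: np.ndarray, primer: str, max_mismatches: int,
          protect: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Start positions (0-based) and mismatch counts of windows matching
    ``primer`` with ≤ max_mismatches and zero mismatches at ``protect``
    offsets."""
    m = len(primer)
    n = seq_bytes.size
    if n < m:
        return np.array([], dtype=int), np.array([], dtype=int)
    tab = _allowed_table(primer)
    nwin = n - m + 1
    mism = np.zeros(nwin, dtype=np.int16)
    hard = np.zeros(nwin, dtype=bool)
    protect_set = set(protect)
    for j in range(m):
        bad = ~tab[j][seq_bytes[j:j + nwin]]
        mism += bad
        if j in protect_set:
            hard |= bad
    ok = (mism <= max_mismatches) & ~hard
    pos = np.nonzero(ok)[0]
    return pos, mism[pos]


def find_primer_sites(genome: Genome, primer: str, max_mismatches: int = 1,
                      three_prime_protect: int = 3,
                      enforce_length: bool = True) -> list[PrimerSite]:
    """All annealing sites of ``primer`` on both strands.

    A window matches when it has at most ``max_mismatches`` mismatches and
    none within the ``three_prime_protect`` 3'-terminal bases (extension
    cannot start from a mismatched 3' end).  IUPAC degenerate primer bases
    match their full nucleotide set.  The reported position is the genome
    coordinate of the primer's 3' end.
    """
    primer = primer.upper()
    m = len(primer)
    if enforce_length and not 18 <= m <= 25:
        raise ValueError("primer length must be within 18-25 nt")
    for ch in primer:
        if ch not in _IUPAC:
            raise ValueError(f"primer contains non-IUPAC character {ch!r}")
    sites: list[PrimerSite] = []
    rc = revcomp(primer)
    for chrom in genome:
        sb = np.frombuffer(genome.sequences[chrom].encode(), dtype=np.uint8)
        # + strand: 3' end at window end
        pos, mm = _scan(sb, primer, max_mismatches,
                        protect=range(m - three_prime_protect, m))
        sites += [PrimerSite(chrom, int(p) + m, "+", int(x), m)
                  for p, x in zip(pos, mm)]
        # - strand: genome matches revcomp(primer); primer 3' end at window start
        pos, mm = _scan(sb, rc, max_mismatches,
                        protect=range(0, three_prime_protect))
        sites += [PrimerSite(chrom, int(p) + 1, "-", int(x), m)
                  for p, x in zip(pos, mm)]
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


# ---------------------------------------------------------------------------
# amplicons
# ---------------------------------------------------------------------------

def predict_amplicons(sites: Sequence[PrimerSite],
                      min_len: int = DEFAULT_MIN_AMPLICON,
                      max_len: int = DEFAULT_MAX_AMPLICON) -> list[Amplicon]:
    """Every facing (+, −) site pair with a product length within
    [min_len, max_len].

    The product is the inclusive span between the two primer 5' ends (the
    ends of the double-stranded PCR product).
    """
    out: list[Amplicon] = []
    by_chrom: dict[str, tuple[list[PrimerSite], list[PrimerSite]]] = {}
    for s in sites:
        fwd, rev = by_chrom.setdefault(s.chrom, ([], []))
        (fwd if s.strand == "+" else rev).append(s)
    for chrom, (fwd, rev) in sorted(by_chrom.items()):
        fwd.sort(key=lambda s: s.position)
        rev.sort(key=lambda s: s.position)
        rpos = np.array([r.position for r in rev], dtype=int)
        for f in fwd:
            start = f.five_prime
            lo = np.searchsorted(rpos, f.position + 1)
            for r in rev[lo:]:
                end = r.five_prime
                length = end - start + 1
                if length < min_len:
                    continue
                if length > max_len:
                    break
                out.append(Amplicon(chrom=chrom, start=start, end=end,
                                    forward_site=f, reverse_site=r))
    return out


# ---------------------------------------------------------------------------
# band matrix
# ---------------------------------------------------------------------------

def band_matrix(amplicons_by_accession: Mapping[str, Sequence[Amplicon | int]],
                size_tolerance: float = 0.02) -> pd.DataFrame:
    """Pool amplicon sizes across accessions into gel-like band bins and
    score presence/absence.

    Two product lengths co-migrate (same band) when consecutive pooled
    lengths differ by at most ``size_tolerance`` (fractional; 2% approximates
    agarose resolution).  Bands are labelled by their median length.
    """
    if len(amplicons_by_accession) < 2:
        raise ValueError("need at least 2 accessions")
    lengths: dict[str, list[int]] = {
        acc: sorted(a.length if isinstance(a, Amplicon) else int(a)
                    for a in amps)
        for acc, amps in amplicons_by_accession.items()}
    pooled = sorted({(ln) for lst in lengths.values() for ln in lst})
    bins: list[list[int]] = []
    for ln in pooled:
        if bins and ln - bins[-1][-1] <= size_tolerance * bins[-1][-1]:
            bins[-1].append(ln)
        else:
            bins.append([ln])
    labels = [f"band_{int(np.median(b))}bp" for b in bins]
    edge_of: dict[int, int] = {}
    for bi, b in enumerate(bins):
        for ln in b:
            edge_of[ln] = bi
    accs = list(amplicons_by_accession)
    mat = np.zeros((len(accs), len(bins)), dtype=int)
    for ai, acc in enumerate(accs):
        for ln in lengths[acc]:
            mat[ai, edge_of[ln]] = 1
    return pd.DataFrame(mat, index=accs, columns=labels)


def polymorphic_bands(matrix: pd.DataFrame) -> list[str]:
    """Columns that vary across accessions."""
    return [c for c in matrix.columns if 0 < matrix[c].sum() < len(matrix)]


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def pca(matrix: pd.DataFrame, n_components: int | None = None,
        ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the (column-centered) band matrix; returns accession scores on
    the leading components and the explained-variance fractions."""
    X = matrix.to_numpy(dtype=float)
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 accessions and 2 bands")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant matrix: no variance to decompose")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=matrix.index, columns=cols),
            model.explained_variance_ratio_)
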