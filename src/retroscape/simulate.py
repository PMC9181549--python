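"""Synthetic genomes, reads and marker populations with known truth.

The generator emulates a repeat-rich plant genome: full-length LTR
retrotransposons of known lineage and insertion age (both LTRs identical at
insertion, diverging under a Kimura two-parameter substitution process at a
fixed per-site rate), target-site duplications, optional nesting, decoy solo
LTRs and truncated fragments, gene intervals, primer binding sites, short
single-end sequencing reads, and admixed dominant-marker populations.

Every operation is deterministic given its seed; all randomness flows through
``numpy.random.Generator`` objects derived from ``SeedSequence`` spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Genome, GffRecord, Interval, revcomp

DEFAULT_RATE = 2e-8          # substitutions / site / year, per LTR
DEFAULT_TS_TV_RATIO = 2.0    # transition:transversion ratio of the mutation process
DEFAULT_TSD_LENGTH = 5       # bp, within the canonical 4-6 range

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
# transition partner: A<->G (0<->2), C<->T (1<->3)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOP_CODONS]


def _encode(seq: str) -> np.ndarray:
    arr = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _decode(rng.choice(4, size=length, p=p).astype(np.uint8))


# ---------------------------------------------------------------------------
# K2P mutation process
# ---------------------------------------------------------------------------

def mutate_k2p(seq: str, expected_divergence: float,
               ts_tv_ratio: float = DEFAULT_TS_TV_RATIO,
               seed: int | np.random.Generator = 0) -> str:
    """Evolve ``seq`` under a Kimura two-parameter process.

    ``expected_divergence`` is the branch length in expected substitutions per
    site (multiple hits included), so the K2P distance estimator applied to
    input vs. output is consistent for it.  Site categories are drawn from the
    exact K2P transition-probability matrix at that branch length.
    """
    if expected_divergence < 0:
        raise ValueError("expected_divergence must be >= 0")
    if ts_tv_ratio <= 0:
        raise ValueError("ts_tv_ratio must be > 0")
    if expected_divergence == 0 or not seq:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = expected_divergence
    # instantaneous rates: alpha (transition), beta (each of two transversions)
    beta = d / (2.0 * (ts_tv_ratio + 1.0))
    alpha = ts_tv_ratio * 2.0 * beta
    e4b = math.exp(-4.0 * beta)
    e2ab = math.exp(-2.0 * (alpha + beta))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 * (1.0 - e4b)          # two transversion targets
    arr = _encode(seq).copy()
    u = rng.random(arr.size)
    ts_mask = u < p_ts
    tv1_mask = (~ts_mask) & (u < p_ts + p_tv_each)
    tv2_mask = (~ts_mask) & (~tv1_mask) & (u < p_ts + 2 * p_tv_each)
    arr[ts_mask] = _TRANSITION[arr[ts_mask]]
    arr[tv1_mask] = _TRANSVERSIONS[arr[tv1_mask], 0]
    arr[tv2_mask] = _TRANSVERSIONS[arr[tv2_mask], 1]
    return _decode(arr)


# ---------------------------------------------------------------------------
# lineage templates
# ---------------------------------------------------------------------------

#: canonical Pol domain order per superfamily (GAG/PROT lead in both)
DOMAIN_ORDER = {
    "Copia": ("GAG", "PROT", "INT", "RT", "RH"),
    "Gypsy": ("GAG", "PROT", "RT", "RH", "INT"),
}

#: domain lengths in amino acids (typical magnitudes for plant LTR-REs)
DOMAIN_LENGTH_AA = {"GAG": 150, "PROT": 100, "INT": 250, "RT": 250, "RH": 130}

_LINKER_AA = 20


@dataclass
class LineageTemplate:
    """Consensus sequences for one retrotransposon lineage."""

    lineage_name: str
    superfamily: str  # "Copia" or "Gypsy"
    ltr_consensus: str
    internal_consensus: str
    domain_coords: dict[str, tuple[int, int]]  # 1-based inclusive on internal

    def __post_init__(self):
        if self.superfamily not in DOMAIN_ORDER:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if not 100 <= len(self.ltr_consensus) <= 3000:
            raise ValueError("LTR consensus length must be within [100, 3000]")
        order = [d for d in self.domain_coords]
        expected = [d for d in DOMAIN_ORDER[self.superfamily] if d in self.domain_coords]
        starts = [self.domain_coords[d][0] for d in expected]
        if sorted(starts) != starts or order != expected:
            raise ValueError("domain order inconsistent with superfamily")
        for dom, (s, e) in self.domain_coords.items():
            if not (1 <= s <= e <= len(self.internal_consensus)):
                raise ValueError(f"domain {dom} outside internal consensus")

    @property
    def element_length(self) -> int:
        return 2 * len(self.ltr_consensus) + len(self.internal_consensus)

    def domain_peptide(self, domain: str) -> str:
        from Bio.Seq import Seq
        s, e = self.domain_coords[domain]
        return str(Seq(self.internal_consensus[s - 1:e]).translate())


def _random_orf(n_aa: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_aa))


def make_template(lineage_name: str, superfamily: str, seed: int,
                  ltr_length: int = 1000, utr_length: int = 300) -> LineageTemplate:
    """Build a deterministic random consensus for one lineage."""
    rng = np.random.default_rng(seed)
    ltr = "TG" + random_sequence(ltr_length - 4, rng) + "CA"
    parts: list[str] = [random_sequence(utr_length, rng)]
    coords: dict[str, tuple[int, int]] = {}
    pos = utr_length
    for dom in DOMAIN_ORDER[superfamily]:
        orf = _random_orf(DOMAIN_LENGTH_AA[dom], rng)
        coords[dom] = (pos + 1, pos + len(orf))
        parts.append(orf)
        pos += len(orf)
        linker = _random_orf(_LINKER_AA, rng)
        parts.append(linker)
        pos += len(linker)
    parts.append(random_sequence(utr_length, rng))
    internal = "".join(parts)
    return LineageTemplate(lineage_name=lineage_name, superfamily=superfamily,
                           ltr_consensus=ltr, internal_consensus=internal,
                           domain_coords=coords)


_DEFAULT_LINEAGES = [
    ("Copia/Angela", "Copia", 101),
    ("Copia/SIRE", "Copia", 102),
    ("Gypsy/Chromovirus-Tekay", "Gypsy", 103),
    ("Gypsy/Tat-Retand", "Gypsy", 104),
    ("Copia/Ale", "Copia", 105),
    ("Gypsy/Athila", "Gypsy", 106),
]


def default_templates(n: int = 4, ltr_length: int = 1000) -> list[LineageTemplate]:
    """The stock lineage set (most abundant Copia/Gypsy lineages first)."""
    return [make_template(name, sf, seed, ltr_length=ltr_length)
            for name, sf, seed in _DEFAULT_LINEAGES[:n]]


# ---------------------------------------------------------------------------
# element simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth for one simulated insertion (1-based inclusive coords)."""

    element_id: str
    lineage_name: str
    chrom: str | None
    start: int
    end: int
    ltr5: tuple[int, int]    # genomically left LTR
    ltr3: tuple[int, int]    # genomically right LTR
    true_age: float          # MYA
    strand: str = "+"
    tsd: str | None = None
    autonomous: bool = True
    nested_in: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def simulate_element(template: LineageTemplate, age_mya: float,
                     rate: float = DEFAULT_RATE,
                     seed: int | np.random.SeedSequence = 0,
                     ts_tv_ratio: float = DEFAULT_TS_TV_RATIO,
                     ) -> tuple[str, TruthRecord]:
    """One element aged ``age_mya``: both LTRs (identical at insertion) and the
    internal region each accumulate ``rate * age_mya * 1e6`` expected
    substitutions per site, so the expected inter-LTR K2P distance is
    ``2 * rate * age_mya * 1e6``.
    """
    if age_mya < 0:
        raise ValueError("age_mya must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    r5, r3, ri = [np.random.default_rng(s) for s in ss.spawn(3)]
    d = rate * age_mya * 1e6
    ltr5 = mutate_k2p(template.ltr_consensus, d, ts_tv_ratio, r5)
    ltr3 = mutate_k2p(template.ltr_consensus, d, ts_tv_ratio, r3)
    internal = mutate_k2p(template.internal_consensus, d, ts_tv_ratio, ri)
    seq = ltr5 + internal + ltr3
    L, Li = len(ltr5), len(internal)
    rec = TruthRecord(element_id="", lineage_name=template.lineage_name,
                      chrom=None, start=1, end=len(seq),
                      ltr5=(1, L), ltr3=(L + Li + 1, len(seq)),
                      true_age=age_mya)
    return seq, rec


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """A simulated chromosome plus complete placement truth."""

    genome: Genome
    elements: list[TruthRecord]
    genes: list[Interval] = field(default_factory=list)
    decoys: list[Interval] = field(default_factory=list)
    primer_sites: list[tuple[str, int, str]] = field(default_factory=list)  # (chrom, 3' pos, strand)
    background_segments: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def element_fraction(self) -> float:
        """Fraction of genome bp inside true full-length elements (nested bp
        counted once)."""
        total = self.genome.total_length
        covered = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for rec in self.elements:
            by_chrom.setdefault(rec.chrom, []).append((rec.start, rec.end))
        for ivs in by_chrom.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    covered += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            covered += cur_e - cur_s + 1
        return covered / total

    def truth_gff(self) -> list[GffRecord]:
        out = []
        for rec in self.elements:
            attrs = {"ID": rec.element_id, "lineage": rec.lineage_name,
                     "age_mya": f"{rec.true_age:g}"}
            if rec.tsd:
                attrs["tsd"] = rec.tsd
            if rec.nested_in:
                attrs["nested_in"] = rec.nested_in
            out.append(GffRecord(rec.chrom, "retroscape_sim", "LTR_retrotransposon",
                                 rec.start, rec.end, strand=rec.strand,
                                 attributes=attrs))
            for tag, (s, e) in (("ltr5", rec.ltr5), ("ltr3", rec.ltr3)):
                out.append(GffRecord(rec.chrom, "retroscape_sim",
                                     "long_terminal_repeat", s, e,
                                     strand=rec.strand,
                                     attributes={"Parent": rec.element_id,
                                                 "side": tag}))
        return out

    def element_sequences(self) -> dict[str, str]:
        return {rec.element_id: self.genome.fetch(rec.chrom, rec.start, rec.end)
                for rec in self.elements}


def _shift(iv: tuple[int, int], off: int) -> tuple[int, int]:
    return (iv[0] + off, iv[1] + off)


def build_genome(templates: Sequence[LineageTemplate],
                 element_specs: Sequence[tuple[str, float, int]],
                 background_length: int,
                 gene_count: int = 0,
                 primer_sites_spec: Sequence[tuple[str, int]] | None = None,
                 nesting_fraction: float = 0.0,
                 seed: int = 0,
                 gc: float = 0.5,
                 tsd_length: int = DEFAULT_TSD_LENGTH,
                 rate: float = DEFAULT_RATE,
                 n_solo_ltr: int = 0,
                 n_fragments: int = 0,
                 reverse_fraction: float = 0.5,
                 gene_length: int = 2000,
                 chrom_name: str = "chr1") -> SyntheticGenome:
    """Assemble a synthetic chromosome.

    ``element_specs`` is a list of (lineage_name, age_mya, count).  Elements
    are inserted at well-separated random points of an i.i.d. background with
    ``tsd_length``-bp target-site duplications; a ``nesting_fraction`` of them
    is inserted inside a previously placed element's internal region.  Decoy
    solo LTRs and truncated fragments can be added; genes and primer binding
    sites are placed in element-free background and reported with exact
    coordinates.
    """
    if not 0.0 <= nesting_fraction <= 1.0:
        raise ValueError("nesting_fraction must be in [0, 1]")
    if not 4 <= tsd_length <= 6:
        raise ValueError("tsd_length must be in [4, 6]")
    by_name = {t.lineage_name: t for t in templates}
    ss = np.random.SeedSequence(seed)
    ss_bg, ss_elem, ss_place, ss_decoy, ss_gene, ss_primer = ss.spawn(6)
    rng_place = np.random.default_rng(ss_place)
    rng_decoy = np.random.default_rng(ss_decoy)

    background = random_sequence(background_length, np.random.default_rng(ss_bg), gc)

    # --- simulate element payloads -------------------------------------
    payloads: list[tuple[str, TruthRecord]] = []
    elem_seeds = iter(ss_elem.spawn(sum(c for _, _, c in element_specs) or 1))
    for lineage, age, count in element_specs:
        if count < 0:
            raise ValueError("element counts must be >= 0")
        if lineage not in by_name:
            raise KeyError(f"no template for lineage {lineage!r}")
        for _ in range(count):
            payloads.append(simulate_element(by_name[lineage], age, rate,
                                             next(elem_seeds)))
    n_elem = len(payloads)
    order = rng_place.permutation(n_elem)
    payloads = [payloads[i] for i in order]
    for i, (_, rec) in enumerate(payloads):
        rec.element_id = f"elem{i:04d}"

    n_nested = int(round(nesting_fraction * n_elem)) if n_elem > 1 else 0
    top_payloads = payloads[:n_elem - n_nested]
    nested_payloads = payloads[n_elem - n_nested:]

    # --- nest inner elements inside hosts (payload-level surgery) -------
    final_payloads: list[list] = [[seq, rec, []] for seq, rec in top_payloads]
    for seq_in, rec_in in nested_payloads:
        host_idx = int(rng_place.integers(0, len(final_payloads)))
        host = final_payloads[host_idx]
        host_seq, host_rec = host[0], host[1]
        lo = host_rec.ltr5[1] + 50          # inside host internal region
        hi = host_rec.ltr3[0] - 50 - tsd_length
        if hi <= lo:
            continue
        p = int(rng_place.integers(lo, hi))  # 0-based cut after position p
        tsd = host_seq[p:p + tsd_length]
        insert = seq_in + tsd
        host[0] = host_seq[:p + tsd_length] + insert + host_seq[p + tsd_length:]
        off = p + tsd_length  # inner element-relative offset within host payload
        rec_in.start, rec_in.end = off + 1, off + len(seq_in)
        rec_in.ltr5 = _shift(rec_in.ltr5, off)
        rec_in.ltr3 = _shift(rec_in.ltr3, off)
        rec_in.tsd = tsd
        rec_in.nested_in = host_rec.element_id
        # host 3' LTR shifts right by the insert length
        grow = len(insert)
        host_rec.end += grow
        host_rec.ltr3 = _shift(host_rec.ltr3, grow)
        host[2].append(rec_in)

    # --- decoy payloads --------------------------------------------------
    decoy_payloads: list[tuple[str, str]] = []   # (label, seq)
    for i in range(n_solo_ltr):
        t = by_name[list(by_name)[int(rng_decoy.integers(0, len(by_name)))]]
        age = float(rng_decoy.uniform(0.0, 2.0))
        solo = mutate_k2p(t.ltr_consensus, rate * age * 1e6, seed=rng_decoy)
        decoy_payloads.append((f"solo_ltr{i:03d}", solo))
    for i in range(n_fragments):
        t = by_name[list(by_name)[int(rng_decoy.integers(0, len(by_name)))]]
        age = float(rng_decoy.uniform(0.0, 2.0))
        seq_f, _ = simulate_element(t, age, rate,
                                    np.random.SeedSequence([seed, 7000 + i]))
        frac = float(rng_decoy.uniform(0.3, 0.6))
        keep = int(frac * len(seq_f))
        frag = seq_f[:keep] if rng_decoy.random() < 0.5 else seq_f[-keep:]
        decoy_payloads.append((f"fragment{i:03d}", frag))

    # --- choose insertion points in background coordinates ---------------
    inserts: list[tuple[str, object]] = [("element", h) for h in final_payloads]
    inserts += [("decoy", d) for d in decoy_payloads]
    m = len(inserts)
    min_gap = 300
    if m and background_length < (m + 1) * (min_gap + tsd_length):
        raise ValueError("background too short for requested insertions")
    if m:
        # rejection-free spacing: sort uniform draws, enforce min separation
        room = background_length - (m + 1) * min_gap
        raw = np.sort(rng_place.choice(room, size=m, replace=False))
        points = raw + min_gap * (1 + np.arange(m))
        shuffle = rng_place.permutation(m)
        inserts = [inserts[i] for i in shuffle]
    else:
        points = np.array([], dtype=int)

    # --- assemble final sequence and lift coordinates ---------------------
    pieces: list[str] = []
    elements_out: list[TruthRecord] = []
    decoys_out: list[Interval] = []
    segments: list[tuple[str, int, int]] = []
    cursor = 0            # background consumed (0-based)
    out_len = 0           # final genome length so far

    def emit(piece: str):
        nonlocal out_len
        pieces.append(piece)
        out_len += len(piece)

    for point, (kind, obj) in zip(points, inserts):
        point = int(point)
        seg = background[cursor:point + tsd_length]
        seg_start = out_len + 1
        emit(seg)
        segments.append((chrom_name, seg_start, out_len))
        tsd = background[point:point + tsd_length]
        if kind == "element":
            seq_p, rec, inner = obj
            reverse = rng_place.random() < reverse_fraction
            if reverse:
                seq_final = revcomp(seq_p)
            else:
                seq_final = seq_p
            base = out_len  # 0-based offset of payload start in final genome
            Lp = len(seq_p)

            def lift(iv: tuple[int, int], rev: bool) -> tuple[int, int]:
                if rev:
                    return (base + Lp - iv[1] + 1, base + Lp - iv[0] + 1)
                return (base + iv[0], base + iv[1])

            all_recs = [rec] + inner
            for r in all_recs:
                s, e = lift((r.start, r.end), reverse)
                l5 = lift(r.ltr5, reverse)
                l3 = lift(r.ltr3, reverse)
                if reverse:  # keep ltr5 = genomically left repeat
                    l5, l3 = sorted([l5, l3])
                r.chrom, r.start, r.end = chrom_name, s, e
                r.ltr5, r.ltr3 = l5, l3
                r.strand = "-" if reverse else "+"
                if r.nested_in is None:
                    r.tsd = tsd
                elements_out.append(r)
            emit(seq_final)
            emit(tsd)
        else:
            label, dseq = obj
            s = out_len + 1
            emit(dseq)
            decoys_out.append(Interval(chrom_name, s, out_len, name=label))
            emit(tsd)
        cursor = point + tsd_length
    seg = background[cursor:]
    seg_start = out_len + 1
    emit(seg)
    segments.append((chrom_name, seg_start, out_len))

    genome_seq = "".join(pieces)
    genome = Genome({chrom_name: genome_seq})
    elements_out.sort(key=lambda r: r.start)
    result = SyntheticGenome(genome=genome, elements=elements_out,
                             decoys=decoys_out,
                             background_segments=[s for s in segments
                                                  if s[2] >= s[1]])

    # --- genes in element-free background ---------------------------------
    rng_gene = np.random.default_rng(ss_gene)
    usable = [s for s in result.background_segments
              if s[2] - s[1] + 1 >= gene_length + 2]
    genes: list[Interval] = []
    for i in range(gene_count):
        if not usable:
            raise ValueError("not enough element-free background for genes")
        c, s, e = usable[int(rng_gene.integers(0, len(usable)))]
        gstart = int(rng_gene.integers(s, e - gene_length + 1))
        genes.append(Interval(c, gstart, gstart + gene_length - 1,
                              name=f"gene{i:04d}",
                              strand="+" if rng_gene.random() < 0.5 else "-"))
    result.genes = genes

    # --- primer binding sites (overwrite element-free background) ---------
    if primer_sites_spec:
        rng_p = np.random.default_rng(ss_primer)
        seq_list = list(genome_seq)
        for primer, count in primer_sites_spec:
            planted = plant_primer_sites(seq_list, primer,
                                         result.background_segments, count,
                                         rng_p, chrom_name)
            result.primer_sites.extend(planted)
        genome.sequences[chrom_name] = "".join(seq_list)

    return result


def plant_primer_sites(seq_list: list[str], primer: str,
                       segments: list[tuple[str, int, int]], count: int,
                       rng: np.random.Generator, chrom: str,
                       ) -> list[tuple[str, int, str]]:
    """Overwrite ``count`` element-free positions with the primer sequence
    (random strand); returns (chrom, 3'-end position, strand) per site."""
    m = len(primer)
    placed: list[tuple[str, int, str]] = []
    usable = [s for s in segments if s[2] - s[1] + 1 >= m + 2]
    attempts = 0
    occupied: list[tuple[int, int]] = []
    while len(placed) < count and attempts < 50 * count + 100:
        attempts += 1
        c, s, e = usable[int(rng.integers(0, len(usable)))]
        pos = int(rng.integers(s, e - m + 2))   # 1-based start
        if any(not (pos + m - 1 < a or pos > b) for a, b in occupied):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        word = primer if strand == "+" else revcomp(primer)
        seq_list[pos - 1:pos - 1 + m] = list(word)
        occupied.append((pos, pos + m - 1))
        three_prime = pos + m - 1 if strand == "+" else pos
        placed.append((chrom, three_prime, strand))
    if len(placed) < count:
        raise ValueError("could not place all primer sites")
    return placed


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(genome: Genome, coverage: float, read_length: int = 85,
                   error_rate: float = 0.0, seed: int = 0,
                   reverse_fraction: float = 0.5) -> list[tuple[str, str]]:
    """Uniform single-end reads; ``ceil(coverage * genome_length / read_length)``
    reads with i.i.d. per-base substitution errors."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    chroms = [c for c in genome]
    if any(genome.length(c) < read_length for c in chroms):
        raise ValueError("read_length exceeds a chromosome length")
    rng = np.random.default_rng(seed)
    total = genome.total_length
    n_reads = math.ceil(coverage * total / read_length)
    weights = np.array([genome.length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(chroms), size=n_reads, p=weights)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        c = chroms[chrom_idx[i]]
        L = genome.length(c)
        start = int(rng.integers(0, L - read_length + 1))
        seq = genome.sequences[c][start:start + read_length]
        if error_rate > 0:
            arr = _encode(seq)
            err = rng.random(read_length) < error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                arr = arr.copy()
                arr[err] = (arr[err] + shift) % 4
                seq = _decode(arr)
        if rng.random() < reverse_fraction:
            seq = revcomp(seq)
        reads.append((f"read{i:07d}", seq))
    return reads


# ---------------------------------------------------------------------------
# marker populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationTruth:
    """Generative truth of an admixed dominant-marker population."""

    n_accessions: int
    K_true: int
    allele_freqs: np.ndarray   # (K_true, n_loci) band-presence allele freqs
    Q_true: np.ndarray         # (n_accessions, K_true)

    def __post_init__(self):
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.Q_true = np.asarray(self.Q_true, dtype=float)
        if self.allele_freqs.min() < 0 or self.allele_freqs.max() > 1:
            raise ValueError("allele frequencies must lie in [0, 1]")
        if not np.allclose(self.Q_true.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")

    @property
    def n_loci(self) -> int:
        return self.allele_freqs.shape[1]


def generate_population_truth(n_accessions: int, K_true: int, n_loci: int,
                              fst: float = 0.4, admixture: float = 0.3,
                              seed: int = 0) -> PopulationTruth:
    """Truth for a K_true-subpopulation benchmark collection.

    Band-allele frequencies follow the correlated-frequencies model: each
    subpopulation's frequency at a locus is Beta-distributed around a shared
    ancestral frequency with drift parameter ``fst`` (0.4 by default —
    strongly differentiated subpopulations).  Accessions are split evenly
    across the K_true groups, and each carries an admixed ancestry mass
    m ~ Uniform(0, ``admixture``) spread over all groups, so the collection
    really contains K_true distinguishable subpopulations plus realistic
    gene flow rather than an unstructured Dirichlet cloud.
    """
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    if fst <= 0:
        f = np.tile(p_anc, (K_true, 1))
    else:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        f = rng.beta(a, b, size=(K_true, n_loci))
    groups = np.arange(n_accessions) % K_true
    m = rng.uniform(0.0, admixture, size=n_accessions)
    Q = m[:, None] * rng.dirichlet(np.ones(K_true), size=n_accessions)
    Q[np.arange(n_accessions), groups] += 1.0 - m
    return PopulationTruth(n_accessions=n_accessions, K_true=K_true,
                           allele_freqs=f, Q_true=Q)


def generate_differentiated_truth(n_accessions: int, K_true: int, n_loci: int,
                                  high: float = 0.85, low: float = 0.10,
                                  concentration: float = 30.0,
                                  admixture: float = 0.2,
                                  seed: int = 0) -> PopulationTruth:
    """Strongly differentiated benchmark truth.

    Every locus carries a non-constant high/low band-frequency pattern
    across the K_true subpopulations (frequencies Beta-jittered around
    ``high``/``low``), the diagnostic-locus design for dominant markers: all
    subpopulation pairs then differ at about half the loci by construction,
    instead of merely on average as under the correlated-frequency model.
    Accessions form balanced groups with admixed mass m ~ U(0, ``admixture``).
    """
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    rng = np.random.default_rng(seed)
    if K_true == 1:
        pats = np.ones((1, n_loci), dtype=int)
    else:
        cols = []
        while len(cols) < n_loci:
            p = rng.integers(0, 2, size=K_true)
            if 0 < p.sum() < K_true:
                cols.append(p)
        pats = np.array(cols).T
    mean = np.where(pats == 1, high, low)
    f = rng.beta(mean * concentration, (1.0 - mean) * concentration)
    groups = np.arange(n_accessions) % K_true
    m = rng.uniform(0.0, admixture, size=n_accessions)
    Q = m[:, None] * rng.dirichlet(np.ones(K_true), size=n_accessions)
    Q[np.arange(n_accessions), groups] += 1.0 - m
    return PopulationTruth(n_accessions=n_accessions, K_true=K_true,
                           allele_freqs=f, Q_true=Q)


def simulate_marker_population(truth: PopulationTruth,
                               n_loci: int | None = None,
                               seed: int = 0,
                               accession_ids: Sequence[str] | None = None,
                               ) -> pd.DataFrame:
    """Binary dominant-marker matrix under the admixture model.

    For diploid accession i at locus l the band is present unless **both**
    haplotypes carry the absence allele; each haplotype's subpopulation of
    origin is drawn from Q_i, so
    P(present) = 1 − (Σ_k Q_ik (1 − f_kl))².
    """
    if n_loci is not None and n_loci != truth.n_loci:
        raise ValueError("n_loci disagrees with truth.allele_freqs")
    rng = np.random.default_rng(seed)
    a = truth.Q_true @ (1.0 - truth.allele_freqs)       # P(haplotype lacks band)
    p_present = 1.0 - a ** 2
    y = (rng.random(p_present.shape) < p_present).astype(int)
    if accession_ids is None:
        accession_ids = [f"acc{i:02d}" for i in range(truth.n_accessions)]
    cols = [f"band{j:03d}" for j in range(truth.n_loci)]
    return pd.DataFrame(y, index=list(accession_ids), columns=cols)
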