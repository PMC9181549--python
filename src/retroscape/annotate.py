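"""Superfamily and lineage classification of full-length elements.

Classification rests on two signals:

* **protein domains** — six-frame translation of the element's internal
  region is locally aligned (BLOSUM80) against exemplar peptides of the five
  canonical domains (GAG, PROT, INT, RT, RH) from each lineage; the linear
  order of INT and RT along Pol separates the superfamilies (INT upstream of
  RT → Copia; RT upstream of INT → Gypsy), and the best-scoring consistent
  exemplar sets the lineage;
* **homology rescue** — elements without domain evidence adopt the
  annotation of their closest classified relative when nucleotide similarity
  and coverage pass thresholds.

An element showing all five domains is flagged autonomous.

Exemplar sets are plain FASTA with ``>domain|lineage|superfamily`` headers;
the packaged set is derived from the simulator's lineage templates, and any
public protein-domain database can be converted to the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import revcomp
from .simulate import LineageTemplate

DOMAIN_TYPES = ("GAG", "PROT", "INT", "RT", "RH")
# local BLOSUM80 alignments of unrelated translated frames score ~150 under
# the affine gap costs used here; genuine young-domain hits score >= 700
DEFAULT_MIN_SCORE = 250.0


@dataclass
class ReferenceExemplar:
    domain: str
    lineage: str
    superfamily: str
    peptide: str


@dataclass
class DomainHit:
    domain_type: str
    frame: int                  # ±1, ±2, ±3
    start: int                  # element-internal-region nt coords, 1-based
    end: int
    score: float
    best_lineage: str
    best_superfamily: str


@dataclass
class LineageAnnotation:
    superfamily: str            # Copia / Gypsy / undetermined
    lineage: str                # lineage label or undetermined
    autonomous: bool = False
    evidence: str = "none"      # domain / homology / none
    hits: list[DomainHit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference handling
# ---------------------------------------------------------------------------

def reference_from_templates(templates: Iterable[LineageTemplate],
                             ) -> list[ReferenceExemplar]:
    out = []
    for t in templates:
        for dom in t.domain_coords:
            out.append(ReferenceExemplar(domain=dom, lineage=t.lineage_name,
                                         superfamily=t.superfamily,
                                         peptide=t.domain_peptide(dom)))
    return out


def read_reference_fasta(path: str | Path) -> list[ReferenceExemplar]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"exemplar header {rec.id!r} is not domain|lineage|superfamily")
        out.append(ReferenceExemplar(domain=parts[0], lineage=parts[1],
                                     superfamily=parts[2],
                                     peptide=str(rec.seq)))
    return out


def write_reference_fasta(exemplars: Iterable[ReferenceExemplar],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for ex in exemplars:
            fh.write(f">{ex.domain}|{ex.lineage}|{ex.superfamily}\n"
                     f"{ex.peptide}\n")


# ---------------------------------------------------------------------------
# domain scanning
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM80")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _six_frames(seq: str) -> list[tuple[int, str]]:
    frames = []
    rc = revcomp(seq)
    for off in range(3):
        for sign, s in ((1, seq), (-1, rc)):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            frames.append((sign * (off + 1), str(Seq(sub).translate())))
    return frames


def _nt_interval(frame: int, aa_start: int, aa_end: int, seq_len: int,
                 ) -> tuple[int, int]:
    """Map an aa interval [aa_start, aa_end) on a translation frame back to
    1-based nt coordinates on the forward sequence."""
    off = abs(frame) - 1
    nt_a = off + 3 * aa_start          # 0-based inclusive on frame strand
    nt_b = off + 3 * aa_end - 1
    if frame > 0:
        return (nt_a + 1, nt_b + 1)
    return (seq_len - nt_b, seq_len - nt_a)


def scan_domains(sequence: str, reference: Sequence[ReferenceExemplar],
                 min_score: float = DEFAULT_MIN_SCORE,
                 aligner: Align.PairwiseAligner | None = None,
                 ) -> list[DomainHit]:
    """Best local-alignment hit per domain type over all six reading frames
    of ``sequence`` (normally an element's internal region).

    Alignment uses BLOSUM80 with affine gaps; hits below ``min_score`` are
    dropped ("significance" filtering is a plain score threshold here).
    """
    if not reference:
        raise ValueError("empty reference exemplar set")
    if aligner is None:
        aligner = _make_aligner()
    frames = _six_frames(sequence)
    # replace stop symbols: aligner matrices lack '*'; map to X
    frames = [(f, pep.replace("*", "X")) for f, pep in frames]
    best: dict[str, tuple[float, int, ReferenceExemplar, str]] = {}
    for frame, pep in frames:
        if not pep:
            continue
        for ex in reference:
            try:
                score = aligner.score(pep, ex.peptide)
            except ValueError:
                continue
            cur = best.get(ex.domain)
            if cur is None or score > cur[0]:
                best[ex.domain] = (score, frame, ex, pep)
    hits: list[DomainHit] = []
    for domain, (score, frame, ex, pep) in best.items():
        if score < min_score:
            continue
        aln = aligner.align(pep, ex.peptide)[0]
        q = aln.aligned[0]
        aa_start, aa_end = int(q[0][0]), int(q[-1][1])
        s, e = _nt_interval(frame, aa_start, aa_end, len(sequence))
        hits.append(DomainHit(domain_type=domain, frame=frame, start=s, end=e,
                              score=float(score), best_lineage=ex.lineage,
                              best_superfamily=ex.superfamily))
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(hits: Sequence[DomainHit],
             min_score: float = DEFAULT_MIN_SCORE) -> LineageAnnotation:
    """Superfamily from INT/RT order when both are present (read along the
    element's coding strand), otherwise from a score-weighted vote; lineage
    from the highest-scoring consistent hit; ties → undetermined."""
    hits = [h for h in hits if h.score >= min_score]
    if not hits:
        return LineageAnnotation("undetermined", "undetermined",
                                 autonomous=False, evidence="none")
    by_dom = {h.domain_type: h for h in hits}
    superfamily = None
    if "INT" in by_dom and "RT" in by_dom:
        # orientation: majority frame sign weighted by score
        strand = 1 if sum(np.sign(h.frame) * h.score for h in hits) >= 0 else -1
        int_first = ((by_dom["INT"].start < by_dom["RT"].start)
                     if strand > 0 else
                     (by_dom["INT"].start > by_dom["RT"].start))
        superfamily = "Copia" if int_first else "Gypsy"
    else:
        votes: dict[str, float] = {}
        for h in hits:
            votes[h.best_superfamily] = votes.get(h.best_superfamily, 0.0) + h.score
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            superfamily = "undetermined"
        else:
            superfamily = ranked[0][0]
    lineage_scores: dict[str, float] = {}
    for h in hits:
        if superfamily in ("undetermined", h.best_superfamily):
            lineage_scores[h.best_lineage] = (
                lineage_scores.get(h.best_lineage, 0.0) + h.score)
    if lineage_scores:
        ranked = sorted(lineage_scores.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            lineage = "undetermined"
        else:
            lineage = ranked[0][0]
    else:
        lineage = "undetermined"
    autonomous = all(d in by_dom for d in DOMAIN_TYPES)
    return LineageAnnotation(superfamily=superfamily, lineage=lineage,
                             autonomous=autonomous, evidence="domain",
                             hits=list(hits))


def annotate_elements(sequences: Mapping[str, str],
                      reference: Sequence[ReferenceExemplar],
                      min_score: float = DEFAULT_MIN_SCORE,
                      ) -> dict[str, LineageAnnotation]:
    """Domain-scan and classify each element sequence (full element or
    internal region)."""
    aligner = _make_aligner()
    out: dict[str, LineageAnnotation] = {}
    for eid, seq in sequences.items():
        hits = scan_domains(seq, reference, min_score=min_score,
                            aligner=aligner)
        out[eid] = classify(hits, min_score=min_score)
    return out


# ---------------------------------------------------------------------------
# homology rescue
# ---------------------------------------------------------------------------

def _cigar_identity(cigar: str, query_length: int) -> tuple[float, float]:
    """(percent identity over aligned columns, aligned-column coverage of the
    query) from an extended cigar; indel runs are structural, not mismatch."""
    import re
    match = mismatch = 0
    for n, op in re.findall(r"(\d+)([=XID])", cigar):
        if op == "=":
            match += int(n)
        elif op == "X":
            mismatch += int(n)
    aligned = match + mismatch
    if aligned == 0:
        return 0.0, 0.0
    return 100.0 * match / aligned, aligned / query_length


def homology_rescue(unclassified: Mapping[str, str],
                    classified: Mapping[str, tuple[str, LineageAnnotation]],
                    min_identity: float = 80.0,
                    min_coverage: float = 0.5,
                    ) -> dict[str, LineageAnnotation]:
    """Adopt the annotation of the most similar classified element.

    For each unclassified element the shorter of the two sequences is
    aligned semi-globally into the longer (both orientations); the top hit's
    annotation is adopted when identity (over the shorter sequence) passes
    ``min_identity`` percent and the aligned span covers ``min_coverage`` of
    the shorter sequence.  Elements without a passing hit stay undetermined.
    """
    if not unclassified or not classified:
        raise ValueError("both element sets must be non-empty")
    out: dict[str, LineageAnnotation] = {}
    for uid, useq in unclassified.items():
        best_id = None
        best_ident = -1.0
        best_cov = 0.0
        for cid, (cseq, _ann) in classified.items():
            short, long_ = (useq, cseq) if len(useq) <= len(cseq) else (cseq, useq)
            for query in (short, revcomp(short)):
                res = edlib.align(query, long_, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                ident, cov = _cigar_identity(res["cigar"], len(short))
                if ident > best_ident:
                    best_id, best_ident, best_cov = cid, ident, cov
        if (best_id is not None and best_ident >= min_identity
                and best_cov >= min_coverage):
            src = classified[best_id][1]
            out[uid] = LineageAnnotation(superfamily=src.superfamily,
                                         lineage=src.lineage,
                                         autonomous=False,
                                         evidence="homology")
        else:
            out[uid] = LineageAnnotation("undetermined", "undetermined",
                                         autonomous=False, evidence="none")
    return out


def annotation_table(annotations: Mapping[str, LineageAnnotation]):
    import pandas as pd
    rows = [{"element_id": eid, "superfamily": a.superfamily,
             "lineage": a.lineage, "autonomous": a.autonomous,
             "evidence": a.evidence}
            for eid, a in annotations.items()]
    return pd.DataFrame(rows)
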