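"""Genome-proportion estimation by mapping reads to an element library.

The fraction of reads whose best alignment passes the mapping filters
(length fraction 0.9, similarity 0.8) is taken as the genome proportion of
the library, and per-lineage proportions aggregate reads by the annotation
of their best-hit element.  Reads mapping equally well to elements of more
than one lineage are, by default, reported in a separate ``ambiguous`` row;
a ``random`` tie policy (seeded) mimics single-assignment mappers instead.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ReadAlignment, ReadMapper
from .annotate import LineageAnnotation


def map_reads(reads: Sequence[tuple[str, str]],
              library: Mapping[str, str],
              length_fraction: float = 0.9,
              similarity: float = 0.8) -> list[ReadAlignment | None]:
    """Best passing assignment per read against the element library (None =
    unmapped); equally-scoring alternatives are recorded on the alignment."""
    if not library:
        raise ValueError("element library is empty")
    mapper = ReadMapper(dict(library), length_fraction=length_fraction,
                        similarity=similarity)
    return mapper.map_reads(reads)


def proportions(assignments: Sequence[ReadAlignment | None],
                annotations: Mapping[str, LineageAnnotation | tuple[str, str]],
                tie_policy: str = "ambiguous",
                seed: int = 0) -> pd.DataFrame:
    """Aggregate read assignments into per-lineage genome proportions.

    ``annotations`` maps element id to a LineageAnnotation (or a plain
    (superfamily, lineage) pair).  The proportion denominator is the total
    read count, and rows always include ``unmapped`` (plus ``ambiguous``
    under the default tie policy), so proportions sum to 1 exactly.
    """
    if tie_policy not in ("ambiguous", "random"):
        raise ValueError("tie_policy must be 'ambiguous' or 'random'")
    rng = np.random.default_rng(seed)

    def keys(elem_id: str) -> tuple[str, str]:
        ann = annotations[elem_id]
        if isinstance(ann, tuple):
            return ann
        return (ann.superfamily, ann.lineage)

    counts: dict[tuple[str, str], int] = {}
    n_total = len(assignments)
    for aln in assignments:
        if aln is None:
            key = ("unmapped", "unmapped")
        else:
            candidates = [aln.ref_id] + list(aln.tie_refs)
            lineages = {keys(c) for c in candidates}
            if len(lineages) == 1:
                key = keys(aln.ref_id)
            elif tie_policy == "random":
                key = keys(candidates[int(rng.integers(0, len(candidates)))])
            else:
                key = ("ambiguous", "ambiguous")
        counts[key] = counts.get(key, 0) + 1
    rows = [{"superfamily": sf, "lineage": lin, "reads": c,
             "proportion": c / n_total if n_total else 0.0}
            for (sf, lin), c in sorted(counts.items())]
    df = pd.DataFrame(rows, columns=["superfamily", "lineage", "reads",
                                     "proportion"])
    return df


def superfamily_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per-superfamily totals (sums of the lineage rows)."""
    return (table.groupby("superfamily", as_index=False)[["reads", "proportion"]]
            .sum())


def mapped_fraction(table: pd.DataFrame) -> float:
    """Total genome proportion assigned to the element library."""
    mask = ~table["superfamily"].isin(["unmapped"])
    return float(table.loc[mask, "proportion"].sum())
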