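"""Hierarchical read classification.

Each trimmed read is assigned exactly one RNA class by a fixed cascade:

1. genome search (both strands, up to 2 mismatches) — no hit ⇒ ``unmapped``;
2. miRNA quantifier match in precursor context ⇒ ``miRNA``;
3. ncRNA search (1 mismatch, first best hit) ⇒ that record's class
   (rRNA, tRNA, piRNA, ...);
4. cDNA search (1 mismatch, first best hit) ⇒ ``mRNA``;
5. otherwise ``unknown_genomic`` (genome-mapped but unannotated).

miRNA assignment deliberately precedes the generic ncRNA/cDNA steps so
that the dedicated quantifier, not the one-shot ncRNA mapping, claims the
pipeline's primary analyte. ncRNA multi-mapping is not resolved beyond the
deterministic first best hit; reads hitting the genome only on the minus
strand still count as genome-mapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import align, quantify
from .seqio import READ_CLASSES, ReferenceRepository, SeqRecord

logger = logging.getLogger(__name__)

GENOME_MISMATCHES = 2
ANNOTATION_MISMATCHES = 1


@dataclass(frozen=True)
class ClassAssignment:
    read_id: str
    rna_class: str
    evidence: Optional[align.Hit] = None

    def __post_init__(self) -> None:
        if self.rna_class not in READ_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if (self.evidence is not None) == (
            self.rna_class in ("unknown_genomic", "unmapped")
        ):
            raise ValueError(
                f"evidence must be present iff the class is annotated; got "
                f"{self.rna_class} with evidence={self.evidence!r}"
            )


class ClassifierIndexes:
    """Pre-built alignment indexes over the repository's reference sets."""

    def __init__(self, repo: ReferenceRepository, k: int = 10):
        self.repo = repo
        self.genome = align.build_index(repo.genome, k=k)
        self.precursor = quantify.build_precursor_index(repo, k=k)
        self.ncrna_class = {rec.id: cls for rec, cls in repo.ncrna}
        self.ncrna = (
            align.build_index([rec for rec, _ in repo.ncrna], k=k)
            if repo.ncrna else None
        )
        self.cdna = align.build_index(repo.cdna, k=k) if repo.cdna else None
        self.matures_by_precursor = repo.matures_by_precursor()


def classify_read(
    read: SeqRecord,
    idx: ClassifierIndexes,
    window: quantify.IsomirWindow = quantify.IsomirWindow(),
) -> ClassAssignment:
    seq = read.sequence
    genome_hits = align.find_hits(seq, idx.genome, GENOME_MISMATCHES,
                                  mode="first_best")
    if not genome_hits:
        return ClassAssignment(read.id, "unmapped")

    mature = quantify.assign_read(seq, idx.precursor, idx.matures_by_precursor,
                                  window)
    if mature is not None:
        prec_hits = align.find_hits(seq, idx.precursor, window.max_mismatches,
                                    mode="first_best", strands=("+",))
        return ClassAssignment(read.id, "miRNA", evidence=prec_hits[0])

    if idx.ncrna is not None:
        hits = align.find_hits(seq, idx.ncrna, ANNOTATION_MISMATCHES,
                               mode="first_best")
        if hits:
            return ClassAssignment(
                read.id, idx.ncrna_class[hits[0].reference_id], evidence=hits[0]
            )

    if idx.cdna is not None:
        hits = align.find_hits(seq, idx.cdna, ANNOTATION_MISMATCHES,
                               mode="first_best")
        if hits:
            return ClassAssignment(read.id, "mRNA", evidence=hits[0])

    return ClassAssignment(read.id, "unknown_genomic")


def classify_sample(
    reads: Iterable[SeqRecord],
    repo_or_indexes: ReferenceRepository | ClassifierIndexes,
    window: quantify.IsomirWindow = quantify.IsomirWindow(),
) -> tuple[list[ClassAssignment], dict[str, int]]:
    """Classify every read of one sample.

    Returns the per-read assignments and a class → count row whose values
    sum to the number of input reads (conservation).
    """
    idx = (
        repo_or_indexes
        if isinstance(repo_or_indexes, ClassifierIndexes)
        else ClassifierIndexes(repo_or_indexes)
    )
    assignments = [classify_read(r, idx, window) for r in reads]
    row = {cls: 0 for cls in READ_CLASSES}
    for a in assignments:
        row[a.rna_class] += 1
    assert sum(row.values()) == len(assignments)
    return assignments, row


def class_table(rows: Mapping[str, Mapping[str, int]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute and percent class count tables (samples × classes).

    Columns follow the fixed class vocabulary order; percent rows sum to
    100 per sample; all-zero samples get an all-zero percent row and a
    warning.
    """
    if not rows:
        raise ValueError("class_table requires at least one sample")
    absolute = pd.DataFrame(
        [[row.get(cls, 0) for cls in READ_CLASSES] for row in rows.values()],
        index=list(rows.keys()), columns=list(READ_CLASSES),
    ).astype(int)
    totals = absolute.sum(axis=1)
    for s in totals.index[totals == 0]:
        logger.warning("sample %s has zero trimmed reads", s)
    percent = absolute.div(totals.replace(0, np.nan), axis=0) * 100.0
    percent = percent.fillna(0.0)
    return absolute, percent
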