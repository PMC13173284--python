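"""Mature-miRNA quantification in precursor context with isomiR tolerance.

A read counts toward mature miRNA ``m`` when it aligns, on the sense strand
of ``m``'s precursor and within the configured mismatch budget, inside the
window ``[m.start - upstream_5p, m.end + downstream_3p)`` — i.e. canonical
reads plus isomiRs with small 5'/3' template shifts collapse onto the
canonical mature id. A read admissible for several matures contributes a
single count, to the first best-stratum mature in the aligner's
deterministic order.

RPM normalization divides by the sample's total miRNA-assigned reads (not
total reads), times 10^6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import align
from .seqio import ReferenceRepository, SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IsomirWindow:
    """Tolerance window around the annotated mature interval.

    Defaults (2 nt upstream of the 5' end, 5 nt downstream of the 3' end,
    1 mismatch) follow common quantifier practice for isomiR collapsing.
    """

    upstream_5p: int = 2
    downstream_3p: int = 5
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if min(self.upstream_5p, self.downstream_3p, self.max_mismatches) < 0:
            raise ValueError("isomiR window parameters must be >= 0")


class MetadataError(KeyError):
    """A quantified sample is missing from the experiment sheet."""


def build_precursor_index(repo: ReferenceRepository, k: int = 10) -> align.AlignIndex:
    return align.build_index(repo.precursors, k=k)


def assign_read(
    read_seq: str,
    index: align.AlignIndex,
    matures_by_precursor: Mapping[str, list],
    window: IsomirWindow,
) -> Optional[str]:
    """Return the mature id a read counts toward, or None.

    Hits are taken sense-strand only; within the best stratum the aligner's
    deterministic order (precursor id, position) is scanned and the first
    hit falling inside some mature's isomiR window wins; matures on one
    precursor are tried in annotation order.
    """
    hits = align.find_hits(
        read_seq, index, window.max_mismatches,
        mode="best_stratum_all", strands=("+",),
    )
    L = len(read_seq)
    for hit in hits:  # already in deterministic order
        for m in matures_by_precursor.get(hit.reference_id, ()):
            if hit.position >= m.start - window.upstream_5p \
                    and hit.position + L <= m.end + window.downstream_3p:
                return m.id
    return None


def quantify_sample(
    reads: Iterable[SeqRecord],
    repo: ReferenceRepository,
    window: IsomirWindow = IsomirWindow(),
    index: Optional[align.AlignIndex] = None,
) -> tuple[dict[str, int], dict[str, Optional[str]]]:
    """Count reads per mature miRNA for one sample.

    Returns ``(counts, assignments)``: counts over every annotated mature
    (zeros included), and the per-read mature id (None when unassigned).
    """
    if index is None:
        index = build_precursor_index(repo)
    mbp = repo.matures_by_precursor()
    counts = {m.id: 0 for m in repo.matures}
    assignments: dict[str, Optional[str]] = {}
    for rec in reads:
        mid = assign_read(rec.sequence, index, mbp, window)
        assignments[rec.id] = mid
        if mid is not None:
            counts[mid] += 1
    return counts, assignments


@dataclass
class MiRNACountMatrix:
    """Mature-miRNA × sample raw counts with an RPM view and group metadata.

    ``raw`` and ``rpm`` are feature × sample DataFrames; ``groups`` is a
    sample × grouping-variable DataFrame (may be empty). RPM columns sum to
    10^6 (or are all-NA for samples with zero miRNA reads).
    """

    raw: pd.DataFrame
    rpm: pd.DataFrame
    groups: pd.DataFrame

    def __post_init__(self) -> None:
        totals = self.raw.sum(axis=0)
        for s in self.raw.columns:
            if totals[s] > 0:
                if not np.isclose(self.rpm[s].sum(), 1e6, atol=1e-6):
                    raise ValueError(f"RPM column {s!r} does not sum to 1e6")
            elif not self.rpm[s].isna().all():
                raise ValueError(f"zero-count sample {s!r} must have all-NA RPM")

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample totals of miRNA-assigned reads (the RPM denominator)."""
        return self.raw.sum(axis=0)


def build_matrix(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    groups: Optional[pd.DataFrame] = None,
) -> MiRNACountMatrix:
    """Assemble the count matrix over samples; features never seen are dropped.

    ``groups``, when given, must carry a row per quantified sample (indexed
    by sample id); extra rows are ignored, missing rows raise
    :class:`MetadataError`.
    """
    raw = pd.DataFrame(per_sample_counts).fillna(0).astype(int)
    raw = raw.loc[raw.sum(axis=1) > 0]
    raw = raw.sort_index()
    totals = raw.sum(axis=0)
    rpm = raw / totals.replace(0, np.nan) * 1e6
    for s in totals.index[totals == 0]:
        logger.warning("sample %s has zero miRNA-assigned reads; RPM set to NA", s)
    if groups is None:
        groups = pd.DataFrame(index=list(raw.columns))
    else:
        missing = [s for s in raw.columns if s not in groups.index]
        if missing:
            raise MetadataError(
                f"samples missing from the experiment sheet: {missing}"
            )
        groups = groups.loc[list(raw.columns)]
    return MiRNACountMatrix(raw=raw, rpm=rpm, groups=groups)
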