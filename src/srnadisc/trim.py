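"""Adapter trimming, 3' quality trimming, and length filtering.

Each raw read is processed in three steps:

1. 3' quality trimming with the standard running-sum rule: walking from the
   3' end, accumulate ``cutoff - q``; the read is cut at the position where
   the partial sum is maximal (the BWA/cutadapt algorithm).
2. Adapter removal: the best ungapped occurrence of the 3' adapter is
   searched at every start position, allowing the adapter to run off the 3'
   end of the read (prefix-only overlap) with at least ``min_overlap``
   aligned columns. A candidate is admissible when
   ``errors / overlap <= max_error_rate``. Candidates are ranked by matched
   columns (overlap − errors) descending, then errors ascending, then
   5'-most start — so a genuine full-length adapter occurrence outranks a
   chance 0-error 3-nt overhang, while equal-error ties still resolve to
   the 5'-most (shortest-insert, adapter-read-through-safe) position. The
   read is truncated at the adapter start.
3. Length filter: reads shorter than ``min_length`` (or longer than
   ``max_length`` when set) after trimming are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .seqio import PathLike, SeqRecord, read_seqs, write_seqs


@dataclass
class TrimParams:
    """Trimming parameters, normally taken from the project-details sheet.

    Defaults: 10% adapter error rate, 3 nt minimum overlap, Phred 20 quality
    cutoff, and a 17 nt length floor matching the lower bound of the miRNA
    length range the pipeline targets.
    """

    adapter: str
    max_error_rate: float = 0.1
    min_overlap: int = 3
    quality_cutoff: int = 20
    min_length: int = 17
    max_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must be in [0, 1]")
        if not 1 <= self.min_overlap <= len(self.adapter):
            raise ValueError("min_overlap must be in [1, adapter length]")


@dataclass
class TrimStats:
    input_reads: int = 0
    passed_reads: int = 0
    discarded_short: int = 0
    discarded_long: int = 0
    total_trimmed_length: int = 0

    @property
    def mean_trimmed_length(self) -> float:
        return self.total_trimmed_length / self.passed_reads if self.passed_reads else 0.0

    def as_dict(self) -> dict:
        return {
            "input_reads": self.input_reads,
            "passed_reads": self.passed_reads,
            "discarded_short": self.discarded_short,
            "discarded_long": self.discarded_long,
            "mean_trimmed_length": round(self.mean_trimmed_length, 3),
        }


def quality_trim_index(quality: list[int], cutoff: int) -> int:
    """3' cut index by the running-sum rule; returns the new read length."""
    best = 0
    cut = len(quality)
    s = 0
    for i in range(len(quality) - 1, -1, -1):
        s += cutoff - quality[i]
        if s < 0:
            break
        if s > best:
            best, cut = s, i
    return cut


def find_adapter(seq: str, adapter: str, max_error_rate: float,
                 min_overlap: int) -> Optional[int]:
    """Return the truncation index of the best adapter occurrence, or None."""
    n, m = len(seq), len(adapter)
    best: Optional[tuple[int, int, int]] = None  # (-matches, errors, start)
    for start in range(0, n):
        overlap = min(m, n - start)
        if overlap < min_overlap:
            break
        errors = sum(
            1 for a, b in zip(seq[start : start + overlap], adapter[:overlap])
            if a != b or a == "N" or b == "N"
        )
        if errors > max_error_rate * overlap:
            continue
        key = (-(overlap - errors), errors, start)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def trim_read(read: SeqRecord, params: TrimParams) -> Optional[SeqRecord]:
    """Quality-trim, adapter-trim and length-filter one read.

    Returns the trimmed record, or ``None`` as the discard signal. The
    output sequence is always a prefix of the quality-trimmed read.
    """
    if read.quality is not None and params.quality_cutoff > 0:
        cut = quality_trim_index(read.quality, params.quality_cutoff)
    else:
        cut = len(read.sequence)
    seq = read.sequence[:cut]
    qual = read.quality[:cut] if read.quality is not None else None

    astart = find_adapter(seq, params.adapter, params.max_error_rate,
                          params.min_overlap)
    if astart is not None:
        seq = seq[:astart]
        qual = qual[:astart] if qual is not None else None

    if len(seq) < params.min_length:
        return None
    if params.max_length is not None and len(seq) > params.max_length:
        return None
    return SeqRecord(id=read.id, sequence=seq, quality=qual)


def trim_sample(in_path: PathLike, out_path: PathLike,
                params: TrimParams) -> tuple[Path, TrimStats]:
    """Trim every read of a FASTQ file; conservation:
    ``input = passed + discarded_short + discarded_long``."""
    stats = TrimStats()

    def _gen():
        for read in read_seqs(in_path):
            stats.input_reads += 1
            trimmed = trim_read(read, params)
            if trimmed is None:
                # distinguish short from long for the QC table
                probe = trim_read(
                    read,
                    TrimParams(
                        adapter=params.adapter,
                        max_error_rate=params.max_error_rate,
                        min_overlap=params.min_overlap,
                        quality_cutoff=params.quality_cutoff,
                        min_length=1,
                        max_length=None,
                    ),
                )
                if probe is not None and params.max_length is not None \
                        and len(probe) > params.max_length:
                    stats.discarded_long += 1
                else:
                    stats.discarded_short += 1
                continue
            stats.passed_reads += 1
            stats.total_trimmed_length += len(trimmed)
            yield trimmed

    out = write_seqs(_gen(), out_path, format="fastq")
    return out, stats
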