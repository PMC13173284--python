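"""Ungapped k-mismatch short-read alignment.

Provides bowtie1 ``-v``-style semantics for the hierarchical mapping steps:
ungapped alignment of a short read against a set of references, both
strands, with at most ``max_mismatches`` (0-2) substitutions, reporting
either every hit in the best stratum or a single deterministically chosen
best hit. ``N`` never matches any base, in the read or the reference.

Hits on the reverse strand are reported at the forward-strand coordinate of
the alignment start, so a hit always satisfies
``0 <= position <= len(reference) - len(read)``.

Candidate positions are found by pigeonhole seeding over an exact k-mer
index when the read is long enough (``len >= (max_mismatches + 1) * k``);
shorter reads fall back to a vectorized scan over every offset. Both paths
verify candidates by exact Hamming counting, so results are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .seqio import SeqRecord, reverse_complement

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4


class AlignmentInputError(ValueError):
    """Read contains symbols outside the A/C/G/T/N alphabet."""


@dataclass(frozen=True, order=True)
class Hit:
    """One ungapped alignment of a read against a reference.

    Ordering (reference id, position, strand with ``+`` before ``-``) is the
    deterministic tie-break used by ``first_best`` mode.
    """

    reference_id: str
    position: int
    strand: str  # "+" sorts before "-" lexicographically
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_ENCODE[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise AlignmentInputError(
            f"sequence contains non-ACGTN symbol {exc.args[0]!r}"
        ) from None


class AlignIndex:
    """Exact k-mer position index over both strands of a reference set."""

    def __init__(self, refs: Sequence[SeqRecord], k: int = 10):
        if not refs:
            raise ValueError("cannot build an alignment index on an empty reference set")
        if k < 1:
            raise ValueError("seed length k must be >= 1")
        self.k = k
        # per reference: id, length, encoded forward and reverse-complement
        self.ids: list[str] = []
        self.lengths: list[int] = []
        self.fwd: list[np.ndarray] = []
        self.rev: list[np.ndarray] = []
        self.seeds: dict[str, list[tuple[int, int, int]]] = {}
        for ridx, rec in enumerate(refs):
            self.ids.append(rec.id)
            self.lengths.append(len(rec.sequence))
            self.fwd.append(_encode(rec.sequence))
            self.rev.append(_encode(reverse_complement(rec.sequence)))
            for sidx, seq in ((0, rec.sequence), (1, reverse_complement(rec.sequence))):
                for pos in range(len(seq) - k + 1):
                    kmer = seq[pos : pos + k]
                    if "N" in kmer:
                        continue
                    self.seeds.setdefault(kmer, []).append((ridx, sidx, pos))

    # -- internal -----------------------------------------------------------

    def _mismatch_profile(self, ridx: int, sidx: int, query: np.ndarray) -> np.ndarray:
        """Mismatch counts of ``query`` at every offset of one strand."""
        ref = self.fwd[ridx] if sidx == 0 else self.rev[ridx]
        L = len(query)
        if len(ref) < L:
            return np.empty(0, dtype=np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(ref, L)
        neq = (windows != query) | (windows == _N_CODE) | (query == _N_CODE)
        return neq.sum(axis=1)

    def _verify(self, ridx: int, sidx: int, pos: int, query: np.ndarray,
                budget: int) -> int | None:
        ref = self.fwd[ridx] if sidx == 0 else self.rev[ridx]
        L = len(query)
        if pos < 0 or pos + L > len(ref):
            return None
        window = ref[pos : pos + L]
        mm = int(((window != query) | (window == _N_CODE) | (query == _N_CODE)).sum())
        return mm if mm <= budget else None

    def _candidates(self, query: np.ndarray, read: str, budget: int):
        """Yield verified (ridx, sidx, pos, mm) tuples, possibly with duplicates."""
        L = len(query)
        k = self.k
        if L >= (budget + 1) * k:
            # pigeonhole: with <= budget mismatches, at least one of the
            # budget+1 disjoint seed blocks aligns exactly
            seen: set[tuple[int, int, int]] = set()
            for block in range(budget + 1):
                off = block * k
                kmer = read[off : off + k]
                for ridx, sidx, pos in self.seeds.get(kmer, ()):
                    key = (ridx, sidx, pos - off)
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = self._verify(ridx, sidx, pos - off, query, budget)
                    if mm is not None:
                        yield ridx, sidx, pos - off, mm
        else:
            for ridx in range(len(self.ids)):
                for sidx in (0, 1):
                    profile = self._mismatch_profile(ridx, sidx, query)
                    for pos in np.nonzero(profile <= budget)[0]:
                        yield ridx, sidx, int(pos), int(profile[pos])


def build_index(refs: Sequence[SeqRecord], k: int = 10) -> AlignIndex:
    """Build an :class:`AlignIndex` over both strands of ``refs``."""
    return AlignIndex(refs, k=k)


def find_hits(
    read: str,
    index: AlignIndex,
    max_mismatches: int,
    mode: Literal["best_stratum_all", "first_best"] = "best_stratum_all",
    strands: tuple[str, ...] = ("+", "-"),
) -> list[Hit]:
    """Find ungapped alignments of ``read`` with at most ``max_mismatches``.

    ``best_stratum_all`` returns every hit at the minimal achieved mismatch
    count; ``first_best`` returns exactly one of those, chosen by reference
    id, then position, then ``+`` before ``-``. Returns ``[]`` when nothing
    aligns within budget. ``strands`` restricts the search (sense-only
    quantification passes ``("+",)``); the best stratum is computed over
    allowed strands only.
    """
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be in {0, 1, 2}")
    allowed = {{"+": 0, "-": 1}[s] for s in strands}
    query = _encode(read)
    L = len(query)
    hits: dict[tuple[int, int, int], int] = {}
    for ridx, sidx, pos, mm in index._candidates(query, read, max_mismatches):
        if sidx not in allowed:
            continue
        key = (ridx, sidx, pos)
        if key not in hits or mm < hits[key]:
            hits[key] = mm
    if not hits:
        return []
    best = min(hits.values())
    out = []
    for (ridx, sidx, pos), mm in hits.items():
        if mm != best:
            continue
        if sidx == 0:
            fpos, strand = pos, "+"
        else:
            fpos, strand = index.lengths[ridx] - pos - L, "-"
        out.append(Hit(index.ids[ridx], fpos, strand, mm))
    out.sort()
    if mode == "first_best":
        return out[:1]
    return out
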