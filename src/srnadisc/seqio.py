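"""Sequence I/O and the reference repository.

Reads and writes the formats the pipeline touches (FASTA, FASTQ, gzip
transparency) and assembles the four reference sequence sets — host genome,
mature + precursor miRNAs, class-annotated ncRNA, and cDNA — into a single
validated :class:`ReferenceRepository`.

Conventions:

* coordinates are 0-based, half-open throughout;
* U bases (miRBase-style RNA space) are transcribed to T on load;
* lowercase bases are uppercased; ``N`` never matches any base downstream.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Classes carried by ncRNA reference records (header dialect ``id|class``).
NCRNA_CLASSES = (
    "rRNA",
    "tRNA",
    "piRNA",
    "snRNA",
    "snoRNA",
    "lncRNA",
    "yRNA",
    "other_ncRNA",
)

#: Every class the hierarchical cascade can assign to a read, in the fixed
#: column order used by count tables and plots.
READ_CLASSES = (
    "miRNA",
    *NCRNA_CLASSES,
    "mRNA",
    "unknown_genomic",
    "unmapped",
)

_FASTA_EXT = {".fa", ".fasta"}
_FASTQ_EXT = {".fq", ".fastq"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Unrecognized or unsupported sequence file format."""


class ParseError(ValueError):
    """Malformed record content (carries a line number when known)."""


class RepositoryError(ValueError):
    """Reference repository fails an integrity check."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class SeqRecord:
    """A named sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord requires a non-empty id")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureRecord:
    """A mature miRNA located on its precursor (0-based, half-open)."""

    id: str
    precursor_id: str
    start: int
    end: int
    sequence: str


@dataclass
class ReferenceRepository:
    """The reference sets the hierarchical classification cascade consults.

    ``matures`` carry coordinates on their precursor; the repository
    validates on construction that each interval lies within its precursor
    and spells exactly the mature sequence.
    """

    genome: list[SeqRecord]
    precursors: list[SeqRecord]
    matures: list[MatureRecord]
    ncrna: list[tuple[SeqRecord, str]]
    cdna: list[SeqRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prec = {p.id: p for p in self.precursors}
        for m in self.matures:
            if m.precursor_id not in prec:
                raise RepositoryError(
                    f"mature {m.id!r} references unknown precursor "
                    f"{m.precursor_id!r}"
                )
            pseq = prec[m.precursor_id].sequence
            if not (0 <= m.start < m.end <= len(pseq)):
                raise RepositoryError(
                    f"mature {m.id!r} interval [{m.start}, {m.end}) outside "
                    f"precursor {m.precursor_id!r} of length {len(pseq)}"
                )
            if pseq[m.start : m.end] != m.sequence:
                raise RepositoryError(
                    f"mature {m.id!r} sequence does not match precursor "
                    f"{m.precursor_id!r} at [{m.start}, {m.end})"
                )
        for rec, cls in self.ncrna:
            if cls not in NCRNA_CLASSES:
                raise RepositoryError(
                    f"ncRNA record {rec.id!r} carries unknown class "
                    f"{cls!r}; expected one of {list(NCRNA_CLASSES)}"
                )

    def matures_by_precursor(self) -> dict[str, list[MatureRecord]]:
        out: dict[str, list[MatureRecord]] = {}
        for m in self.matures:
            out.setdefault(m.precursor_id, []).append(m)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: Path, mode: str = "rt") -> IO[str]:
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 keeps outputs byte-identical across reruns
            import io
            raw = gzip.GzipFile(path, mode="wb", mtime=0)
            return io.TextIOWrapper(raw)
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _detect_format(path: Path) -> str:
    suffixes = path.suffixes
    core = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else (
        suffixes[-1] if suffixes else ""
    )
    if core in _FASTA_EXT:
        return "fasta"
    if core in _FASTQ_EXT:
        return "fastq"
    raise FormatError(
        f"cannot infer sequence format from extension {''.join(suffixes) or '<none>'!r} "
        f"of {path.name!r}; expected one of .fa/.fasta/.fq/.fastq(.gz)"
    )


def _iter_fastq(handle: IO[str], name: str) -> Iterator[SeqRecord]:
    # Bio.SeqIO's FASTQ iterator does not report line numbers on malformed
    # input; the 4-line grammar is parsed here so errors can carry them.
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ParseError(
                f"{name}: line {lineno}: expected '@' header, got {header[:30]!r}"
            )
        seq = handle.readline()
        if not seq:
            raise ParseError(f"{name}: line {lineno + 1}: truncated record (missing sequence)")
        lineno += 1
        seq = seq.strip()
        sep = handle.readline()
        if not sep:
            raise ParseError(f"{name}: line {lineno + 1}: truncated record (missing '+' line)")
        lineno += 1
        if not sep.startswith("+"):
            raise ParseError(
                f"{name}: line {lineno}: expected '+' separator, got {sep.rstrip()[:30]!r}"
            )
        qual = handle.readline()
        if not qual:
            raise ParseError(f"{name}: line {lineno + 1}: truncated record (missing quality)")
        lineno += 1
        qual = qual.rstrip("\n")
        if len(qual) != len(seq):
            raise ParseError(
                f"{name}: line {lineno}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        yield SeqRecord(
            id=header[1:].split()[0],
            sequence=_normalize(seq),
            quality=[ord(c) - 33 for c in qual],
        )


def read_seqs(path: PathLike, format: Optional[str] = None) -> Iterator[SeqRecord]:
    """Yield :class:`SeqRecord` from a FASTA/FASTQ file, ``.gz`` transparent.

    The format is inferred from the extension unless ``format`` (``"fasta"``
    or ``"fastq"``) is given. Records preserve file order; bases are
    uppercased and U is transcribed to T.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt not in ("fasta", "fastq"):
        raise FormatError(f"unknown format {fmt!r}")
    with _open_text(path) as handle:
        if fmt == "fasta":
            for rec in _BioSeqIO.parse(handle, "fasta"):
                yield SeqRecord(id=rec.id, sequence=_normalize(str(rec.seq)))
        else:
            yield from _iter_fastq(handle, path.name)


def write_seqs(records: Iterable[SeqRecord], path: PathLike,
               format: Optional[str] = None) -> Path:
    """Write records as FASTA or FASTQ (Phred+33), gzip if path ends ``.gz``."""
    path = Path(path)
    fmt = format or _detect_format(path)
    with _open_text(path, "wt") as out:
        for rec in records:
            if fmt == "fasta":
                out.write(f">{rec.id}\n{rec.sequence}\n")
            else:
                qual = rec.quality if rec.quality is not None else [37] * len(rec)
                out.write(
                    f"@{rec.id}\n{rec.sequence}\n+\n"
                    + "".join(chr(q + 33) for q in qual)
                    + "\n"
                )
    return path


# ---------------------------------------------------------------------------
# repository loading
# ---------------------------------------------------------------------------

#: manifest keys -> repository roles
MANIFEST_ROLES = ("genome", "precursor", "mature", "ncrna", "cdna")


def load_repository(directory: PathLike, manifest: dict[str, str]) -> ReferenceRepository:
    """Load and validate a reference repository from a directory.

    ``manifest`` maps each of the five roles (``genome``, ``precursor``,
    ``mature``, ``ncrna``, ``cdna``) to a FASTA filename inside
    ``directory``. Header dialects: mature records are ``mature_id|precursor_id``;
    ncRNA records are ``id|class`` with class drawn from
    :data:`NCRNA_CLASSES`. Mature coordinates are resolved by exact substring
    search within the named precursor; if the mature occurs more than once
    the 5'-most occurrence is used and a warning is logged.
    """
    directory = Path(directory)
    missing = [r for r in MANIFEST_ROLES if r not in manifest]
    if missing:
        raise RepositoryError(f"manifest missing roles: {missing}")

    def _load(role: str) -> list[SeqRecord]:
        return list(read_seqs(directory / manifest[role]))

    genome = _load("genome")
    precursors = _load("precursor")
    prec_by_id = {p.id: p for p in precursors}

    matures: list[MatureRecord] = []
    for rec in _load("mature"):
        if "|" not in rec.id:
            raise RepositoryError(
                f"mature header {rec.id!r} lacks '|precursor_id' suffix"
            )
        mid, pid = rec.id.split("|", 1)
        prec = prec_by_id.get(pid)
        if prec is None:
            raise RepositoryError(
                f"mature {mid!r} names unknown precursor {pid!r}"
            )
        start = prec.sequence.find(rec.sequence)
        if start < 0:
            raise RepositoryError(
                f"mature {mid!r} not found in precursor {pid!r}"
            )
        if prec.sequence.find(rec.sequence, start + 1) >= 0:
            logger.warning(
                "mature %s occurs more than once in precursor %s; "
                "using the 5'-most occurrence", mid, pid,
            )
        matures.append(
            MatureRecord(mid, pid, start, start + len(rec.sequence), rec.sequence)
        )

    ncrna: list[tuple[SeqRecord, str]] = []
    for rec in _load("ncrna"):
        if "|" not in rec.id:
            raise RepositoryError(
                f"ncRNA header {rec.id!r} lacks '|class' suffix; classes: "
                f"{list(NCRNA_CLASSES)}"
            )
        rid, cls = rec.id.rsplit("|", 1)
        if cls not in NCRNA_CLASSES:
            raise RepositoryError(
                f"ncRNA record {rid!r} has unknown class {cls!r}; expected "
                f"one of {list(NCRNA_CLASSES)}"
            )
        ncrna.append((SeqRecord(id=rid, sequence=rec.sequence), cls))

    return ReferenceRepository(
        genome=genome,
        precursors=precursors,
        matures=matures,
        ncrna=ncrna,
        cdna=_load("cdna"),
    )


def write_repository(repo: ReferenceRepository, directory: PathLike) -> dict[str, str]:
    """Write a repository as five FASTA files; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "genome": "genome.fa",
        "precursor": "precursor.fa",
        "mature": "mature.fa",
        "ncrna": "ncrna.fa",
        "cdna": "cdna.fa",
    }
    write_seqs(repo.genome, directory / manifest["genome"])
    write_seqs(repo.precursors, directory / manifest["precursor"])
    write_seqs(
        (SeqRecord(id=f"{m.id}|{m.precursor_id}", sequence=m.sequence)
         for m in repo.matures),
        directory / manifest["mature"],
    )
    write_seqs(
        (SeqRecord(id=f"{rec.id}|{cls}", sequence=rec.sequence)
         for rec, cls in repo.ncrna),
        directory / manifest["ncrna"],
    )
    write_seqs(repo.cdna, directory / manifest["cdna"])
    return manifest
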