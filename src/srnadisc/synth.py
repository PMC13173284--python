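"""Synthetic fixtures: references, reads with known class composition, and
negative-binomial count matrices with planted differential expression.

The generator emulates the inputs a small RNA-seq discovery experiment
consumes — a host genome with embedded miRNA precursors, class-annotated
ncRNAs and cDNAs, per-sample adapter-carrying FASTQ reads, and a metadata
workbook — while guaranteeing, by construction, that every read classifies
unambiguously: all embedded reference sequences (and their reverse
complements, and the adapter) are kept pairwise Hamming distance > 2 apart
over every window of the minimum read length, so the hierarchical cascade
can recover the planted truth exactly rather than statistically.

Class counts per sample are apportioned from the design fractions by the
largest-remainder method, so truth tables hold exact integers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .seqio import (
    NCRNA_CLASSES,
    READ_CLASSES,
    MatureRecord,
    PathLike,
    ReferenceRepository,
    SeqRecord,
    reverse_complement,
    write_repository,
    write_seqs,
)

_BASES = np.array(list("ACGT"))

#: default 3' adapter (Illumina TruSeq small RNA)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_CLASS_FRACTIONS = {
    "miRNA": 0.6,
    "rRNA": 0.2,
    "mRNA": 0.1,
    "unknown_genomic": 0.05,
    "unmapped": 0.05,
}


class UniquenessError(RuntimeError):
    """Could not keep embedded sequences mutually distinguishable."""


@dataclass
class SyntheticDesign:
    """Parameters of a synthetic two-group small RNA-seq experiment.

    Defaults describe a modest desk-scale discovery study: 4 samples per
    group, 1000 reads per sample dominated by miRNA (60%) with an rRNA,
    mRNA, unannotated-genomic and unmapped remainder, 50 mature miRNAs of
    which 10 are differentially expressed at log2 fold change 2, NB counts
    at mean 100 with dispersion 0.1, reads of 17-25 nt carrying the
    standard small RNA 3' adapter.
    """

    seed: int = 0
    n_samples_per_group: int = 4
    n_reads: int = 1000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    n_mirnas: int = 50
    n_de: int = 10
    logfc: float = 2.0
    dispersion: float = 0.1
    mean_count: float = 100.0
    low_fraction: float = 0.3
    adapter: str = DEFAULT_ADAPTER
    read_length_range: tuple[int, int] = (17, 25)
    n_ncrna_per_class: int = 2
    n_cdna: int = 4
    genome_min_length: int = 5000
    low_quality_tail: int = 0  # nt of Q2 tail appended after the adapter

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        unknown = set(self.class_fractions) - set(READ_CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes in fractions: {sorted(unknown)}")
        if self.n_de > self.n_mirnas:
            raise ValueError("n_de must be <= n_mirnas")
        lo, hi = self.read_length_range
        if not (15 <= lo <= hi <= 50):
            raise ValueError("read lengths must lie within [15, 50]")


def largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n into integer class counts matching fractions exactly."""
    raw = {k: v * n for k, v in fractions.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:short]:
        base[k] += 1
    return base


# ---------------------------------------------------------------------------
# uniqueness bookkeeping
# ---------------------------------------------------------------------------


class _WindowBank:
    """All length-w windows of accepted sequences (and reverse complements).

    A candidate sequence conflicts when any of its windows is within
    Hamming distance ``min_dist - 1`` of a stored window: distance ``>= 3``
    over every shared minimum-length window implies no cross-matching of
    any read at mismatch budget 2.
    """

    def __init__(self, w: int, min_dist: int = 3):
        self.w = w
        self.min_dist = min_dist
        self._rows: list[np.ndarray] = []
        self._bank: Optional[np.ndarray] = None

    @staticmethod
    def _encode(seq: str) -> np.ndarray:
        return np.frombuffer(seq.encode(), dtype=np.uint8)

    def _windows(self, seq: str) -> np.ndarray:
        arr = self._encode(seq)
        if len(arr) < self.w:
            return np.empty((0, self.w), dtype=np.uint8)
        return np.lib.stride_tricks.sliding_window_view(arr, self.w)

    def conflicts(self, seq: str) -> bool:
        if self._bank is None or not len(self._bank):
            return False
        for variant in (seq, reverse_complement(seq)):
            wins = self._windows(variant)
            for chunk_start in range(0, len(wins), 64):
                chunk = wins[chunk_start : chunk_start + 64]
                d = (chunk[:, None, :] != self._bank[None, :, :]).sum(axis=2)
                if (d < self.min_dist).any():
                    return True
        return False

    def add(self, seq: str) -> None:
        for variant in (seq, reverse_complement(seq)):
            wins = self._windows(variant)
            if len(wins):
                self._rows.append(np.ascontiguousarray(wins))
        if self._rows:
            self._bank = np.concatenate(self._rows, axis=0)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _unique_seq(rng: np.random.Generator, length: int, bank: _WindowBank,
                what: str, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if not bank.conflicts(seq):
            bank.add(seq)
            return seq
    raise UniquenessError(
        f"could not draw a {what} of length {length} keeping all embedded "
        f"sequences > {bank.min_dist - 1} mismatches apart at window size "
        f"{bank.w}; reduce the number or length of reference sequences"
    )


# ---------------------------------------------------------------------------
# reference repository
# ---------------------------------------------------------------------------


@dataclass
class SyntheticRepository:
    """A toy repository plus the layout knowledge the read generator needs."""

    repository: ReferenceRepository
    background_intervals: list[tuple[int, int]]  # genome regions with no feature
    bank: _WindowBank


def make_reference_repository(design: SyntheticDesign) -> SyntheticRepository:
    """Build a toy genome embedding every reference sequence verbatim.

    Precursors (each with one annotated mature), ncRNAs (every class) and
    cDNAs are drawn with rejection against the window bank so that all
    embedded sequences — and the adapter — stay pairwise non-matching
    within 2 mismatches at read length. The genome is the concatenation of
    checked random background and the embedded features, with pure
    background intervals recorded for sampling unannotated-genomic reads.
    """
    rng = np.random.default_rng(design.seed)
    w = design.read_length_range[0]
    bank = _WindowBank(w=w)
    bank.add(design.adapter)

    precursors: list[SeqRecord] = []
    matures: list[MatureRecord] = []
    for i in range(design.n_mirnas):
        mlen = int(rng.integers(20, 24))
        plen = int(rng.integers(60, 76))
        pseq = _unique_seq(rng, plen, bank, "precursor")
        start = int(rng.integers(5, plen - mlen - 5))
        pid = f"pre-{i + 1:04d}"
        precursors.append(SeqRecord(id=pid, sequence=pseq))
        matures.append(
            MatureRecord(f"mir-{i + 1:04d}", pid, start, start + mlen,
                         pseq[start : start + mlen])
        )

    ncrna = [
        (SeqRecord(id=f"{cls}-{j + 1}",
                   sequence=_unique_seq(rng, int(rng.integers(60, 91)), bank,
                                        "ncRNA")), cls)
        for cls in NCRNA_CLASSES
        for j in range(design.n_ncrna_per_class)
    ]
    cdna = [
        SeqRecord(id=f"cdna-{j + 1:03d}",
                  sequence=_unique_seq(rng, int(rng.integers(120, 201)), bank,
                                       "cDNA"))
        for j in range(design.n_cdna)
    ]

    features = [p.sequence for p in precursors] + \
        [rec.sequence for rec, _ in ncrna] + [c.sequence for c in cdna]
    feature_len = sum(len(f) for f in features)
    spacer = 40
    bg_needed = max(design.genome_min_length - feature_len,
                    (len(features) + 1) * spacer + 1500)

    # background drawn in checked blocks so no stretch resembles a feature
    blocks: list[str] = []
    remaining = bg_needed
    while remaining > 0:
        blk = min(remaining, 500)
        blocks.append(_unique_seq(rng, blk, bank, "genome background"))
        remaining -= blk
    background = "".join(blocks)

    # interleave: spacer, feature, spacer, feature, ..., large tail
    order = rng.permutation(len(features))
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    bg_cursor = 0

    def _take_bg(k: int) -> str:
        nonlocal bg_cursor
        chunk = background[bg_cursor : bg_cursor + k]
        bg_cursor += k
        return chunk

    n_feat = len(features)
    tail_len = len(background) - spacer * n_feat
    for rank, fi in enumerate(order):
        chunk = _take_bg(spacer)
        intervals.append((pos, pos + len(chunk)))
        parts.append(chunk)
        pos += len(chunk)
        parts.append(features[fi])
        pos += len(features[fi])
    chunk = _take_bg(tail_len)
    intervals.append((pos, pos + len(chunk)))
    parts.append(chunk)
    genome_seq = "".join(parts)

    repo = ReferenceRepository(
        genome=[SeqRecord(id="chr1", sequence=genome_seq)],
        precursors=precursors,
        matures=matures,
        ncrna=ncrna,
        cdna=cdna,
    )
    return SyntheticRepository(repo, intervals, bank)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _mirna_insert(rng: np.random.Generator, srepo: SyntheticRepository,
                  max_len: int) -> tuple[str, str]:
    """A canonical or isomiR read from a random mature window."""
    repo = srepo.repository
    m = repo.matures[int(rng.integers(len(repo.matures)))]
    prec = next(p for p in repo.precursors if p.id == m.precursor_id)
    if rng.random() < 0.7:
        a = b = 0
    else:
        a = int(rng.integers(0, min(2, m.start) + 1))
        b_max = min(5, len(prec) - m.end, max_len - (m.end - m.start) - a)
        b = int(rng.integers(0, max(b_max, 0) + 1))
    if (m.end - m.start) + a + b > max_len:
        a = b = 0
    return prec.sequence[m.start - a : m.end + b], m.id


def _substring(rng: np.random.Generator, seq: str, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, min(hi, len(seq)) + 1))
    start = int(rng.integers(0, len(seq) - length + 1))
    return seq[start : start + length]


def _unmapped_insert(rng: np.random.Generator, genome: str, lo: int, hi: int,
                     max_tries: int = 100) -> str:
    """Random sequence verified by brute force not to hit the genome <= 2 mm."""
    garr = np.frombuffer(genome.encode(), dtype=np.uint8)
    rarr = np.frombuffer(reverse_complement(genome).encode(), dtype=np.uint8)
    for _ in range(max_tries):
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        q = np.frombuffer(seq.encode(), dtype=np.uint8)
        hitting = False
        for strand in (garr, rarr):
            wins = np.lib.stride_tricks.sliding_window_view(strand, len(q))
            if ((wins != q).sum(axis=1) <= 2).any():
                hitting = True
                break
        if not hitting:
            return seq
    raise UniquenessError("could not draw an unmapped read avoiding the genome")


def make_reads(
    design: SyntheticDesign,
    srepo: SyntheticRepository,
    out_dir: PathLike,
    sample_ids: Optional[list[str]] = None,
    gz: bool = True,
) -> pd.DataFrame:
    """Write per-sample FASTQ files with planted class composition.

    Every read is a substring of its source class's reference (a mature
    window substring for miRNA reads) suffixed by the adapter (and an
    optional low-quality tail); unmapped reads are verified against the
    genome by brute force. Returns the truth table with one row per read:
    ``read_id, sample, rna_class, feature``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    repo = srepo.repository
    genome = repo.genome[0].sequence
    lo, hi = design.read_length_range
    if sample_ids is None:
        n = design.n_samples_per_group
        sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    per_class = largest_remainder(design.class_fractions, design.n_reads)
    by_class = {
        cls: [rec for rec, c in repo.ncrna if c == cls] for cls in NCRNA_CLASSES
    }
    usable_bg = [iv for iv in srepo.background_intervals if iv[1] - iv[0] >= hi]

    rows = []
    for sample in sample_ids:
        rng = np.random.default_rng(
            [design.seed, zlib.crc32(sample.encode()) % (2**31)]
        )
        records = []
        ridx = 0
        for cls in READ_CLASSES:
            for _ in range(per_class.get(cls, 0)):
                feature = ""
                if cls == "miRNA":
                    insert, feature = _mirna_insert(rng, srepo, hi)
                elif cls in NCRNA_CLASSES:
                    rec = by_class[cls][int(rng.integers(len(by_class[cls])))]
                    insert, feature = _substring(rng, rec.sequence, lo, hi), rec.id
                elif cls == "mRNA":
                    rec = repo.cdna[int(rng.integers(len(repo.cdna)))]
                    insert, feature = _substring(rng, rec.sequence, lo, hi), rec.id
                elif cls == "unknown_genomic":
                    s, e = usable_bg[int(rng.integers(len(usable_bg)))]
                    insert = _substring(rng, genome[s:e], lo, hi)
                else:  # unmapped
                    insert = _unmapped_insert(rng, genome, lo, hi)
                ridx += 1
                read_id = f"{sample}:{ridx:06d}"
                seq = insert + design.adapter
                qual = [37] * len(seq)
                if design.low_quality_tail:
                    seq += _random_seq(rng, design.low_quality_tail)
                    qual += [2] * design.low_quality_tail
                records.append(SeqRecord(id=read_id, sequence=seq, quality=qual))
                rows.append((read_id, sample, cls, feature))
        order = rng.permutation(len(records))
        suffix = ".fastq.gz" if gz else ".fastq"
        write_seqs((records[i] for i in order), out_dir / f"{sample}{suffix}",
                   format="fastq")
    truth = pd.DataFrame(rows, columns=["read_id", "sample", "rna_class", "feature"])
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth


def truth_class_counts(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-sample true class counts (samples × fixed class vocabulary)."""
    tab = truth.pivot_table(index="sample", columns="rna_class",
                            values="read_id", aggfunc="count", fill_value=0)
    return tab.reindex(columns=list(READ_CLASSES), fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def nb_counts(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def make_count_matrix(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a feature × sample NB count matrix with planted DE.

    The first ``n_de`` features carry a group-B mean multiplied by
    ``2**logfc``; a ``low_fraction`` share of the null features is
    low-abundance (mean < 5) to exercise independent filtering. Returns
    ``(counts, groups, truth_logfc)``.
    """
    rng = np.random.default_rng([design.seed, 7])
    G, nde = design.n_mirnas, design.n_de
    n = design.n_samples_per_group
    samples = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    features = [f"mir-{i + 1:04d}" for i in range(G)]

    n_low = int(round(design.low_fraction * (G - nde)))
    mean_a = np.full(G, design.mean_count)
    if n_low:
        mean_a[G - n_low :] = rng.uniform(0.5, 4.0, size=n_low)
    truth = pd.Series(0.0, index=features, name="true_logfc")
    truth.iloc[:nde] = design.logfc
    mean_b = mean_a * 2.0 ** truth.to_numpy()

    cols = {}
    for j, s in enumerate(samples):
        mu = mean_a if j < n else mean_b
        cols[s] = nb_counts(rng, mu, design.dispersion)
    counts = pd.DataFrame(cols, index=features)
    groups = pd.DataFrame(
        {"group": ["GroupA"] * n + ["GroupB"] * n}, index=samples
    )
    return counts, groups, truth


# ---------------------------------------------------------------------------
# full experiment fixture
# ---------------------------------------------------------------------------


def make_experiment(design: SyntheticDesign, out_dir: PathLike,
                    gz: bool = True) -> dict:
    """Write a complete runnable experiment: repository, reads, workbook, config.

    Returns a dict with the paths of everything written.
    """
    from . import sheet as sheet_mod  # deferred: sheet imports pandas/openpyxl only
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    srepo = make_reference_repository(design)
    repo_dir = out_dir / "repository"
    manifest = write_repository(srepo.repository, repo_dir)
    with open(repo_dir / "manifest.yml", "w") as fh:
        yaml.safe_dump(manifest, fh)

    reads_dir = out_dir / "reads"
    n = design.n_samples_per_group
    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    truth = make_reads(design, srepo, reads_dir, sample_ids, gz=gz)

    suffix = ".fastq.gz" if gz else ".fastq"
    samples = pd.DataFrame(
        {
            "file": [f"reads/{s}{suffix}" for s in sample_ids],
            "group": ["GroupA"] * n + ["GroupB"] * n,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    workbook = out_dir / "experiment.xlsx"
    sheet_mod.write_workbook(
        workbook,
        project={
            "title": "Synthetic small RNA-seq discovery experiment",
            "comments": f"generated fixture, seed {design.seed}",
            "species": "synthetic",
            "adapter": design.adapter,
            "alpha": 0.05,
            "quality_cutoff": 20,
            "min_length": 17,
        },
        samples=samples,
        contrasts=pd.DataFrame(
            [
                {"name": "GroupA_vs_GroupB", "variable": "group",
                 "group_a": "GroupA", "group_b": "GroupB", "blocking": ""}
            ]
        ),
    )

    config = {
        "workbook": "experiment.xlsx",
        "repository": "repository",
        "output": "results",
        "seed": design.seed,
    }
    config_path = out_dir / "config.yml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh)
    return {
        "dir": out_dir,
        "repository": repo_dir,
        "reads": reads_dir,
        "workbook": workbook,
        "config": config_path,
        "truth": truth,
        "srepo": srepo,
    }
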