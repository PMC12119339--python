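"""Readers/writers for the external formats the toolkit touches.

All genomic coordinates are 0-based half-open internally.  SELEX read pools
are fixed-length DNA over the strict {A,C,G,T} alphabet: reads containing any
other character (or of deviant length) are dropped at load time and counted
in a :class:`LoadReport`, because every k-mer statistic downstream assumes a
pure four-letter alphabet.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("coopselex")

DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC degeneracy alphabet, symbol -> set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
#: frozenset of bases -> IUPAC symbol (inverse of IUPAC).
IUPAC_INV = {frozenset(v): k for k, v in IUPAC.items()}


def configure_logging(verbosity: int = 0) -> None:
    """Route package logging to stderr; verbosity 0=warning, 1=info, 2=debug."""
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbosity, 2)]
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Read pools
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    n_retained: int = 0
    n_dropped_alphabet: int = 0
    n_dropped_length: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_alphabet + self.n_dropped_length


@dataclass
class ReadPool:
    """A SELEX cycle: fixed-length reads plus the cycle index."""

    reads: list[str]
    cycle: int = 0
    label: str = ""
    load_report: LoadReport | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("empty read pool")
        lengths = {len(r) for r in self.reads}
        if len(lengths) != 1:
            raise ValueError(f"reads of unequal length: {sorted(lengths)}")

    @property
    def read_length(self) -> int:
        return len(self.reads[0])

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def encoded(self) -> np.ndarray:
        """Reads as an (n, L) uint8 matrix with A,C,G,T -> 0..3."""
        buf = np.frombuffer("".join(self.reads).encode(), dtype=np.uint8)
        codes = np.zeros(256, dtype=np.uint8)
        codes[ord("C")] = 1
        codes[ord("G")] = 2
        codes[ord("T")] = 3
        return codes[buf].reshape(self.n_reads, self.read_length)


def _clean_reads(raw: list[str], length: int | None) -> tuple[list[str], LoadReport]:
    report = LoadReport()
    kept: list[str] = []
    for r in raw:
        r = r.strip().upper()
        if not r:
            continue
        if any(c not in DNA for c in r):
            report.n_dropped_alphabet += 1
            continue
        if length is None:
            length = len(r)
        if len(r) != length:
            report.n_dropped_length += 1
            continue
        kept.append(r)
    report.n_retained = len(kept)
    return kept, report


def read_pool(path, format: str = "txt", cycle: int = 0, label: str = "") -> ReadPool:
    """Load a read pool from FASTA/FASTQ or one-read-per-line text.

    The first retained read defines the expected length; shorter/longer reads
    (sequencing artefacts) and reads with non-ACGT characters are dropped and
    tallied in the pool's ``load_report``.
    """
    if format in ("fasta", "fastq"):
        raw = [str(rec.seq) for rec in SeqIO.parse(str(path), format)]
    elif format == "txt":
        with open(path) as fh:
            raw = fh.readlines()
    else:
        raise ValueError(f"unknown read format: {format!r}")
    kept, report = _clean_reads(raw, None)
    if not kept:
        raise ValueError(f"no valid reads retained from {path}")
    if report.n_dropped:
        logger.info("read_pool(%s): dropped %d reads (%d alphabet, %d length)",
                    path, report.n_dropped, report.n_dropped_alphabet,
                    report.n_dropped_length)
    return ReadPool(kept, cycle=cycle, label=label or str(path), load_report=report)


def write_pool(pool: ReadPool, path, format: str = "txt") -> None:
    with open(path, "w") as fh:
        if format == "txt":
            fh.write("\n".join(pool.reads) + "\n")
        elif format == "fasta":
            for i, r in enumerate(pool.reads):
                fh.write(f">read{i} cycle={pool.cycle}\n{r}\n")
        else:
            raise ValueError(f"unknown read format: {format!r}")


# ---------------------------------------------------------------------------
# Motifs (position count matrices)
# ---------------------------------------------------------------------------

@dataclass
class Motif:
    """A 4xL position count matrix (rows A,C,G,T), counts as reals.

    Counts are stored as reals because background-corrected counts can be
    fractional.  The frequency view normalises each column to sum to 1.
    """

    counts: np.ndarray
    name: str = ""
    seed: str | None = None
    multinomial_level: int | None = None
    motif_class: str | None = None  # monomer|composite|spacing|control

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("count matrix must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError("motif must have at least one column")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every column needs a positive count sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def log_odds(self, background=None, pseudocount: float = 1.0) -> np.ndarray:
        """Natural-log odds matrix vs a background base composition."""
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        c = self.counts + pseudocount
        freq = c / c.sum(axis=0, keepdims=True)
        return np.log(freq / background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in np.argmax(self.counts, axis=0))

    def reverse_complement(self) -> "Motif":
        return Motif(self.counts[::-1, ::-1].copy(), name=self.name + "_rc",
                     seed=None, multinomial_level=self.multinomial_level,
                     motif_class=self.motif_class)


def read_count_matrix(path, name: str | None = None) -> Motif:
    """Read a 4-row count matrix; plain tab-separated and JASPAR bracket
    dialects are auto-detected, with labelled (``A ...``) or positional rows."""
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = None
    if lines and lines[0].startswith(">"):
        header = lines[0][1:].strip()
        lines = lines[1:]
    positional = 0
    for lineno, ln in enumerate(lines, start=1):
        tokens = ln.replace("[", " ").replace("]", " ").split()
        if not tokens:
            continue
        if tokens[0].upper() in ("A", "C", "G", "T") and not _is_number(tokens[0]):
            base = tokens[0].upper()
            vals = tokens[1:]
        else:
            base = DNA[positional]
            positional += 1
            vals = tokens
        try:
            rows[base] = [float(v) for v in vals]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed count row: {ln!r}") from exc
        order.append(base)
    if sorted(order) != ["A", "C", "G", "T"]:
        raise ValueError(f"{path}: expected exactly 4 rows A,C,G,T, got {order}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: row-length mismatch: {sorted(lengths)}")
    counts = np.array([rows[b] for b in DNA], dtype=float)
    return Motif(counts, name=name or header or str(path))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_count_matrix(motif: Motif, path) -> None:
    """Write the labelled tab-separated dialect (6 significant digits)."""
    with open(path, "w") as fh:
        if motif.name:
            fh.write(f">{motif.name}\n")
        for b, row in zip(DNA, motif.counts):
            fh.write(b + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Regions and conservation tracks
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Intervals (sequence id, start, end), 0-based half-open, optional label."""

    intervals: list[tuple]  # (chrom, start, end[, label])

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv[1] >= iv[2]:
                raise ValueError(f"start >= end in interval {iv}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def covered_positions(self, chrom: str) -> set[int]:
        out: set[int] = set()
        for iv in self.intervals:
            if iv[0] == chrom:
                out.update(range(iv[1], iv[2]))
        return out

    def chroms(self) -> set[str]:
        return {iv[0] for iv in self.intervals}


def read_regions(path) -> RegionSet:
    """Read BED3/BED4 (0-based half-open); malformed lines reported with number."""
    intervals = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if len(parts) >= 4:
                intervals.append((chrom, start, end, parts[3]))
            else:
                intervals.append((chrom, start, end))
    return RegionSet(intervals)


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fh.write("\t".join(str(x) for x in iv) + "\n")


@dataclass
class ConservationTrack:
    """Per-base signed conservation scores (phyloP-like) plus an optional
    constrained-base mask.  Scores are keyed by (sequence id, position)."""

    scores: dict[str, dict[int, float]]
    constrained_mask: RegionSet | None = None
    score_threshold: float | None = None

    def score(self, chrom: str, pos: int, default: float = 0.0) -> float:
        return self.scores.get(chrom, {}).get(pos, default)

    def mean_score(self, chrom: str, start: int, end: int) -> float:
        """Average score over [start, end); undefined bases contribute 0."""
        d = self.scores.get(chrom, {})
        return sum(d.get(p, 0.0) for p in range(start, end)) / max(end - start, 1)

    def overlaps_mask(self, chrom: str, start: int, end: int) -> bool:
        if self.constrained_mask is None:
            return True
        for iv in self.constrained_mask:
            if iv[0] == chrom and iv[1] < end and start < iv[2]:
                return True
        return False


def read_conservation(scores_path, mask_path=None,
                      score_threshold: float | None = None) -> ConservationTrack:
    """Read a bedGraph of per-base scores (+ optional constrained-base BED).

    Overlapping bedGraph intervals are rejected, naming the offending line.
    """
    scores: dict[str, dict[int, float]] = {}
    with open(scores_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{scores_path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start >= end:
                raise ValueError(f"{scores_path}:{lineno}: start >= end")
            d = scores.setdefault(chrom, {})
            for pos in range(start, end):
                if pos in d:
                    raise ValueError(
                        f"{scores_path}:{lineno}: overlapping bedGraph interval at "
                        f"{chrom}:{pos}")
                d[pos] = value
    mask = read_regions(mask_path) if mask_path is not None else None
    return ConservationTrack(scores, constrained_mask=mask,
                             score_threshold=score_threshold)


def read_fasta(path) -> dict[str, str]:
    """Load genomic sequences as a name -> uppercase string dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
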