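"""Readers and writers for the external formats the pipeline touches.

All interval arithmetic uses 0-based half-open coordinates (BED convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "ContactMap",
    "PWM",
    "read_peaks",
    "write_peaks",
    "extract_sequences",
    "read_signal",
    "read_contacts",
    "read_pwms",
    "write_feature_table",
    "read_feature_table",
]

_VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    summit: int | None = None  # optional narrowPeak summit offset

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.start}-{self.end}"


class SignalTrack:
    """Per-base signal for one chromatin landscape in one cell type.

    Backed by sorted non-overlapping piecewise-constant records; lookups
    outside covered regions return 0.
    """

    def __init__(self, cell_type: str, assay: str):
        self.cell_type = cell_type
        self.assay = assay
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}

    @classmethod
    def from_records(
        cls,
        cell_type: str,
        assay: str,
        records: Iterable[tuple[str, int, int, float]],
    ) -> "SignalTrack":
        track = cls(cell_type, assay)
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if value < 0:
                raise ValueError(
                    f"negative signal value {value} at {chrom}:{start}-{end}"
                )
            if end <= start:
                raise ValueError(f"invalid record {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping records on {chrom} near position {starts[i + 1]}"
                )
            track._starts[chrom] = starts
            track._ends[chrom] = ends
            track._values[chrom] = np.array([r[2] for r in recs], dtype=float)
        return track

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0."""
        if end <= start:
            raise ValueError("end must exceed start")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._starts:
            return out
        starts, ends, vals = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = vals[i]
        return out

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values(chrom, pos, pos + 1)[0])


class ContactMap:
    """Sparse symmetric bin-level contact counts for one cell type."""

    def __init__(self, cell_type: str, resolution: int = 5000):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.cell_type = cell_type
        self.resolution = resolution
        self._entries: dict[tuple[str, int, int], float] = {}

    def set(self, chrom: str, bin_i: int, bin_j: int, count: float) -> None:
        res = self.resolution
        if bin_i % res or bin_j % res:
            raise ValueError(
                f"bin starts ({bin_i}, {bin_j}) must be multiples of resolution {res}"
            )
        if count < 0:
            raise ValueError("contact count must be non-negative")
        for key in ((chrom, bin_i, bin_j), (chrom, bin_j, bin_i)):
            existing = self._entries.get(key)
            if existing is not None and existing != count:
                raise ValueError(
                    f"conflicting counts for {key}: {existing} vs {count}"
                )
            self._entries[key] = count

    def get(self, chrom: str, bin_i: int, bin_j: int) -> float:
        return self._entries.get((chrom, bin_i, bin_j), 0.0)

    def partners(self, chrom: str, bin_start: int) -> tuple[np.ndarray, np.ndarray]:
        """All partner bin starts and counts for one bin (self-contact excluded),
        sorted by bin start."""
        items = sorted(
            (j, c)
            for (c_chrom, i, j), c in self._entries.items()
            if c_chrom == chrom and i == bin_start and j != bin_start
        )
        bins = np.array([j for j, _ in items], dtype=np.int64)
        counts = np.array([c for _, c in items], dtype=float)
        return bins, counts

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


@dataclass
class PWM:
    """Position weight matrix; rows ordered A, C, G, T."""

    id: str
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("PWM weights must be a 4 x w matrix")
        if self.weights.shape[1] < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PWM weights must be finite")

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def to_log_odds(self, background: float = 0.25, pseudocount: float = 0.01) -> "PWM":
        """Convert a count/frequency matrix to log-odds against a uniform background."""
        counts = self.weights + pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        return PWM(self.id, np.log2(probs / background))


def read_peaks(path: str | os.PathLike, dialect: str = "BED") -> list[GenomicInterval]:
    """Read a BED3+ or narrowPeak file into intervals, preserving file order."""
    if dialect not in ("BED", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else "."
            summit = None
            if dialect == "narrowPeak" and len(fields) >= 10:
                s = int(fields[9])
                summit = s if s >= 0 else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, summit)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_peaks(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def extract_sequences(
    genome: str | os.PathLike, intervals: Sequence[GenomicInterval]
) -> list[str]:
    """Extract uppercase sequences for intervals from an indexed FASTA."""
    from pyfaidx import Fasta

    seqs: list[str] = []
    with Fasta(str(genome), as_raw=True, sequence_always_upper=True) as fasta:
        for iv in intervals:
            if iv.chrom not in fasta:
                raise KeyError(f"chromosome {iv.chrom!r} missing from {genome}")
            if iv.end > len(fasta[iv.chrom]):
                raise IndexError(
                    f"interval {iv} exceeds {iv.chrom} length {len(fasta[iv.chrom])}"
                )
            seqs.append(str(fasta[iv.chrom][iv.start : iv.end]))
    return seqs


def read_signal(path: str | os.PathLike, cell_type: str, assay: str) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            records.append(
                (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            )
    return SignalTrack.from_records(cell_type, assay, records)


def read_contacts(
    path: str | os.PathLike, resolution: int = 5000, cell_type: str = ""
) -> ContactMap:
    """Read whitespace-separated triplet text (chrom bin_i bin_j count)."""
    cmap = ContactMap(cell_type or os.path.basename(str(path)), resolution)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            try:
                cmap.set(fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return cmap


def read_pwms(path: str | os.PathLike, log_odds: bool = False) -> list[PWM]:
    """Read a JASPAR-format text file (>id header, A/C/G/T rows).

    Accepts both the bracketed dialect (``A [ 1 2 3 ]``) and bare number rows.
    With ``log_odds=True`` the matrices are converted from counts to log-odds
    scores against a uniform background.
    """
    pwms: list[PWM] = []
    current_id: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal current_id, rows
        if current_id is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise ParseError(
                f"{path}: motif {current_id!r} must have exactly A/C/G/T rows, "
                f"got {sorted(rows)}"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ParseError(f"{path}: motif {current_id!r} has unequal row lengths")
        pwm = PWM(current_id, np.array([rows[b] for b in "ACGT"], dtype=float))
        pwms.append(pwm.to_log_odds() if log_odds else pwm)
        current_id, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
                continue
            if current_id is None:
                raise ParseError(f"{path}: matrix row before any > header")
            parts = line.replace("[", " ").replace("]", " ").split()
            base = parts[0].upper()
            if base in "ACGT" and not _is_number(parts[0]):
                numbers = parts[1:]
            else:
                base = "ACGT"[len(rows)] if len(rows) < 4 else "?"
                numbers = parts
            if base in rows:
                raise ParseError(f"{path}: duplicate {base} row in {current_id!r}")
            rows[base] = [float(x) for x in numbers]
    flush()
    return pwms


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_feature_table(table, path: str | os.PathLike) -> None:
    """Write a FeatureTable as TSV; round-trips losslessly with read_feature_table."""
    table.validate()
    df = table.data.copy()
    if table.labels is not None:
        df.insert(0, "label", table.labels)
    df.to_csv(path, sep="\t", index=True, index_label="peak_id")


def read_feature_table(path: str | os.PathLike):
    import pandas as pd

    from .feature_gen import FeatureTable

    df = pd.read_csv(path, sep="\t", index_col="peak_id")
    df.index.name = None
    labels = None
    if "label" in df.columns:
        labels = df.pop("label")
    return FeatureTable(df, labels=labels)
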