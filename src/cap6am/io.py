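"""Readers and writers for the formats the pipeline touches.

All genomic coordinates are 0-based, half-open.  BED ingestion is native;
any 1-based table must be converted at the boundary.  Readers reject
malformed records with the offending line number — nothing is silently
coerced.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "TSSRecord",
    "EndCountTrack",
    "PeakRecord",
    "read_tss_bed",
    "write_tss_bed",
    "merge_tss_catalogs",
    "read_end_counts",
    "write_end_counts",
    "read_narrowpeak",
    "write_narrowpeak",
    "nearest_tss",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """A malformed record in an input file (message carries the line number)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TSSRecord:
    """One annotated transcription start site.

    ``pos`` is the 0-based coordinate of the first transcribed base.
    ``gene_id``/``tss_id`` come from the BED name field, written as
    ``gene|tss`` (BED6 has a single name slot).
    """

    chrom: str
    pos: int
    strand: str
    gene_id: str
    tss_id: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.strand, self.gene_id)


@dataclass
class EndCountTrack:
    """Per-position read 5'-end counts for one sample.

    ``counts`` maps ``(chrom, strand)`` to a pair of parallel arrays
    ``(positions, values)`` with positions sorted ascending, which makes
    window sums a pair of ``searchsorted`` calls.  ``library_size`` is the
    sample-level total of emitted read ends and is *not* required to equal
    the sum of stored counts (tracks may be region-restricted, and the
    per-position duplicate cap does not renormalize the library).
    """

    sample_id: str = ""
    role: str = "ip"
    library_size: int = 0
    counts: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict, library_size: int,
                     sample_id: str = "", role: str = "ip") -> "EndCountTrack":
        """Build from a ``{(chrom, strand, pos): count}`` mapping."""
        grouped: dict = {}
        for (chrom, strand, pos), c in mapping.items():
            grouped.setdefault((chrom, strand), []).append((pos, c))
        counts = {}
        for key, pairs in grouped.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            val = np.array([c for _, c in pairs], dtype=np.int64)
            counts[key] = (pos, val)
        return cls(sample_id=sample_id, role=role,
                   library_size=int(library_size), counts=counts)

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Sum of counts on (chrom, strand) within [start, end)."""
        arr = self.counts.get((chrom, strand))
        if arr is None:
            return 0
        pos, val = arr
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(val[lo:hi].sum())

    def total_stored(self) -> int:
        return int(sum(int(v.sum()) for _, v in self.counts.values()))

    def iter_entries(self):
        for (chrom, strand), (pos, val) in sorted(self.counts.items()):
            for p, c in zip(pos.tolist(), val.tolist()):
                yield chrom, int(p), strand, int(c)


@dataclass
class PeakRecord:
    """An ingested external-caller peak (ENCODE narrowPeak semantics)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    fold_enrichment: float = 0.0
    q_value: float = 1.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak span must satisfy start < end "
                             f"({self.start} >= {self.end})")


# ---------------------------------------------------------------------------
# BED6 TSS catalogs
# ---------------------------------------------------------------------------

def read_tss_bed(path, source: str = "") -> list[TSSRecord]:
    """Read a BED6 TSS catalog (one single-base interval per TSS).

    The BED name field is split on ``|`` into gene and TSS identifiers;
    a name without a delimiter is used for both.
    """
    records = []
    label = source or Path(path).stem
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 BED columns, "
                    f"got {len(fields)}")
            chrom, start, _end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', "
                    f"got {strand!r}")
            try:
                pos = int(start)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer start {start!r}") from exc
            if pos < 0:
                raise FormatError(f"{path}:{lineno}: negative start {pos}")
            gene_id, _, tss_id = name.partition("|")
            records.append(TSSRecord(chrom=chrom, pos=pos, strand=strand,
                                     gene_id=gene_id, tss_id=tss_id or name,
                                     source=label))
    return records


def write_tss_bed(records: Iterable[TSSRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t"
                     f"{r.gene_id}|{r.tss_id}\t0\t{r.strand}\n")


def merge_tss_catalogs(catalogs: Sequence[Sequence[TSSRecord]]) -> list[TSSRecord]:
    """Union of catalogs with exact-duplicate collapse.

    Duplicates on (chrom, pos, strand, gene_id) are collapsed into one
    record whose ``source`` concatenates the contributing catalog labels.
    Near-duplicate TSSs (±1-2 bp) are retained as alternatives.
    """
    if not catalogs:
        raise ValueError("need at least one catalog to merge")
    merged: dict[tuple, TSSRecord] = {}
    for catalog in catalogs:
        for rec in catalog:
            prev = merged.get(rec.key)
            if prev is None:
                merged[rec.key] = rec
            else:
                sources = list(dict.fromkeys(
                    s for s in (*prev.source.split(","), rec.source) if s))
                merged[rec.key] = replace(prev, source=",".join(sources))
    return sorted(merged.values(),
                  key=lambda r: (r.chrom, r.pos, r.strand, r.gene_id))


# ---------------------------------------------------------------------------
# End-count tracks (TSV dialect: header then chrom  pos0  strand  count)
# ---------------------------------------------------------------------------

def write_end_counts(track: EndCountTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_size={track.library_size}\n")
        if track.sample_id:
            fh.write(f"#sample_id={track.sample_id}\n")
        fh.write(f"#role={track.role}\n")
        for chrom, pos, strand, count in track.iter_entries():
            fh.write(f"{chrom}\t{pos}\t{strand}\t{count}\n")


def read_end_counts(path) -> EndCountTrack:
    library_size = None
    sample_id = ""
    role = "ip"
    mapping: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "library_size":
                    library_size = int(value)
                elif key == "sample_id":
                    sample_id = value
                elif key == "role":
                    role = value
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, pos_s, strand, count_s = fields
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: bad strand {strand!r}")
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer field") from exc
            if count < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative count {count}")
            mapping[(chrom, strand, pos)] = count
    if library_size is None:
        raise FormatError(
            f"{path}: missing required header '#library_size=<int>'")
    return EndCountTrack.from_mapping(mapping, library_size,
                                      sample_id=sample_id, role=role)


# ---------------------------------------------------------------------------
# ENCODE narrowPeak (BED6+4)
# ---------------------------------------------------------------------------

def read_narrowpeak(path) -> list[PeakRecord]:
    """Read ENCODE narrowPeak.  signalValue -> fold_enrichment; the qValue
    column (-log10) is converted to a linear q; point source -1 -> absent."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, "
                    f"got {len(fields)}")
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            signal, qlog, summit = fields[6], fields[8], fields[9]
            try:
                start_i, end_i = int(start), int(end)
                signal_f, qlog_f, summit_i = float(signal), float(qlog), int(summit)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed field") from exc
            q = 1.0 if qlog_f < 0 else 10.0 ** (-qlog_f)
            peaks.append(PeakRecord(
                chrom=chrom, start=start_i, end=end_i, name=name,
                fold_enrichment=signal_f, q_value=min(q, 1.0),
                summit_offset=None if summit_i == -1 else summit_i))
    return peaks


def write_narrowpeak(peaks: Iterable[PeakRecord], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            qlog = 1000.0 if p.q_value <= 0 else -np.log10(p.q_value)
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                     f"{p.fold_enrichment:g}\t-1\t{qlog:g}\t{summit}\n")


# ---------------------------------------------------------------------------
# Nearest-TSS index
# ---------------------------------------------------------------------------

class _ChromIndex:
    __slots__ = ("positions", "records")

    def __init__(self, records: list[TSSRecord]):
        records = sorted(records, key=lambda r: (r.pos, r.strand, r.gene_id))
        self.records = records
        self.positions = [r.pos for r in records]


def _signed_distance(tss: TSSRecord, pos: int) -> int:
    """Distance from the TSS to ``pos`` in the transcription direction
    (downstream positive)."""
    return pos - tss.pos if tss.strand == "+" else tss.pos - pos


def nearest_tss(chrom: str, pos: int, catalog: Sequence[TSSRecord],
                strand: str | None = None):
    """Nearest TSS to a genomic point; returns ``(record, signed_distance)``.

    The distance sign follows the matched TSS's transcription direction
    (downstream positive).  Ties on absolute distance go to the 5'-most
    candidate (smallest coordinate on '+', largest on '-'; across strands,
    the smaller coordinate, then '+').  Returns ``None`` when the
    chromosome (or strand) has no TSS.
    """
    candidates = [r for r in catalog
                  if r.chrom == chrom and (strand is None or r.strand == strand)]
    if not candidates:
        return None
    index = _ChromIndex(candidates)
    i = bisect.bisect_left(index.positions, pos)
    # The minimal |pos - r.pos| is attained at the sorted neighbors i-1 / i.
    dmin = min(abs(pos - index.positions[j])
               for j in (i - 1, i) if 0 <= j < len(index.positions))
    ties: list[TSSRecord] = []
    for target in {pos - dmin, pos + dmin}:
        lo = bisect.bisect_left(index.positions, target)
        hi = bisect.bisect_right(index.positions, target)
        ties.extend(index.records[lo:hi])
    best = min(ties, key=lambda r: (
        r.pos if r.strand == "+" else -r.pos, r.strand != "+", r.gene_id))
    return best, _signed_distance(best, pos)


# ---------------------------------------------------------------------------
# FASTA and plain tables
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                sequences[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before header")
                sequences[name].append(line.upper())
    return {k: "".join(v) for k, v in sequences.items()}


def write_table(df, path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_table(path):
    import pandas as pd
    return pd.read_csv(path, sep="\t", index_col=0)
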