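"""Readers, writers and in-memory containers for the formats the pipeline touches.

All internal coordinates are 0-based half-open. BED and bedGraph are native;
refFlat (which is also 0-based half-open for txStart/txEnd and exon bounds)
is normalized on read. The minus-strand TSS is the last base of the
half-open transcript span, ``tx_end - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "TranscriptModel",
    "TssAnchor",
    "StrandedCounts",
    "ScoreTrack",
    "read_gene_models",
    "nonredundant_tss",
    "read_chrom_sizes",
    "read_stranded_counts",
    "read_bed_intervals",
    "fragment_centers",
    "write_calls",
    "read_calls",
    "bam_to_stranded_counts",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript: identifiers, span, strand and exon structure.

    The transcription start site (``tss``) is derived from the span:
    ``tx_start`` on the plus strand, ``tx_end - 1`` on the minus strand.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"{self.transcript_id}: tx_start ({self.tx_start}) must be < tx_end ({self.tx_end})"
            )
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.transcript_id}: exon [{s},{e}) outside transcript span")
            if s <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            out.append((e0, s1))
        return tuple(out)


@dataclass(frozen=True)
class TssAnchor:
    """A non-redundant annotated TSS position with its contributing transcripts."""

    chrom: str
    strand: str
    pos: int
    gene_name: str
    transcript_ids: tuple[str, ...]


class StrandedCounts:
    """Sparse per-base 5'-end read counts keyed by (chrom, strand).

    Parameters
    ----------
    genome_lengths
        Chromosome name -> length in bp. Positions must lie below the
        length of their chromosome.
    total_aligned
        Library depth used for background thresholding. Defaults to the
        sum of loaded counts but may be overridden (the loaded subset of
        a track can be smaller than the library).
    """

    def __init__(self, genome_lengths: Mapping[str, int], total_aligned: int | None = None):
        self.genome_lengths = dict(genome_lengths)
        self._counts: dict[tuple[str, str], dict[int, int]] = {}
        self._total_override = total_aligned

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        if n < 0:
            raise ValueError("counts must be non-negative")
        if strand not in STRANDS:
            raise ValueError(f"bad strand {strand!r}")
        length = self.genome_lengths.get(chrom)
        if length is not None and not (0 <= pos < length):
            raise ValueError(f"position {chrom}:{pos} outside chromosome length {length}")
        if n == 0:
            return
        d = self._counts.setdefault((chrom, strand), {})
        d[pos] = d.get(pos, 0) + n

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self._counts.get((chrom, strand), {}).get(pos, 0)

    def window_array(self, chrom: str, start: int, end: int, strand: str | None = None) -> np.ndarray:
        """Dense count vector over [start, end) on one strand (or both summed)."""
        out = np.zeros(max(end - start, 0), dtype=np.int64)
        strands = STRANDS if strand is None else (strand,)
        for st in strands:
            d = self._counts.get((chrom, st))
            if not d:
                continue
            if len(d) < (end - start):
                for pos, n in d.items():
                    if start <= pos < end:
                        out[pos - start] += n
            else:
                for off in range(end - start):
                    n = d.get(start + off)
                    if n:
                        out[off] += n
        return out

    def positions(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted positions and their counts for one (chrom, strand)."""
        d = self._counts.get((chrom, strand), {})
        if not d:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        pos = np.array(sorted(d), dtype=np.int64)
        return pos, np.array([d[p] for p in pos], dtype=np.int64)

    def keys(self) -> Iterator[tuple[str, str]]:
        return iter(self._counts)

    @property
    def sum(self) -> int:
        return sum(sum(d.values()) for d in self._counts.values())

    @property
    def total_aligned(self) -> int:
        return self._total_override if self._total_override is not None else self.sum

    @total_aligned.setter
    def total_aligned(self, value: int) -> None:
        self._total_override = int(value)

    @property
    def stranded_positions(self) -> int:
        """Number of (position, strand) pairs in the genome: 2 x summed lengths."""
        return 2 * sum(self.genome_lengths.values())


class ScoreTrack:
    """Sparse per-base numeric values, optionally stranded.

    A generic carrier for fragment-center tracks, ChIP/MNase/FAIRE coverage
    and similar per-base scores.
    """

    def __init__(self, genome_lengths: Mapping[str, int] | None = None, stranded: bool = False):
        self.genome_lengths = dict(genome_lengths or {})
        self.stranded = stranded
        self._values: dict[tuple[str, str | None], dict[int, float]] = {}

    def _key(self, chrom: str, strand: str | None) -> tuple[str, str | None]:
        if self.stranded:
            if strand not in STRANDS:
                raise ValueError("stranded track requires strand '+' or '-'")
            return (chrom, strand)
        return (chrom, None)

    def add(self, chrom: str, pos: int, value: float, strand: str | None = None) -> None:
        if not math.isfinite(value):
            raise ValueError("values must be finite")
        length = self.genome_lengths.get(chrom)
        if length is not None and not (0 <= pos < length):
            raise ValueError(f"position {chrom}:{pos} outside chromosome length {length}")
        d = self._values.setdefault(self._key(chrom, strand), {})
        d[pos] = d.get(pos, 0.0) + value

    def get(self, chrom: str, pos: int, strand: str | None = None) -> float:
        return self._values.get(self._key(chrom, strand), {}).get(pos, 0.0)

    def window_array(self, chrom: str, start: int, end: int, strand: str | None = None) -> np.ndarray:
        out = np.zeros(max(end - start, 0), dtype=float)
        keys = [(chrom, s) for s in STRANDS] if (self.stranded and strand is None) else [self._key(chrom, strand)]
        for key in keys:
            d = self._values.get(key)
            if not d:
                continue
            for pos, v in d.items():
                if start <= pos < end:
                    out[pos - start] += v
        return out

    @property
    def sum(self) -> float:
        return sum(sum(d.values()) for d in self._values.values())


# ---------------------------------------------------------------------------
# annotation


def _parse_int(tok: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed {what}: {tok!r}") from None


def read_gene_models(path: str, dialect: str = "refFlat") -> list[TranscriptModel]:
    """Parse transcript models from refFlat (11-column) or BED12.

    Coordinates are normalized to 0-based half-open. Malformed lines raise
    ``ValueError`` naming the offending line number.
    """
    if dialect not in ("refFlat", "bed12"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'refFlat' or 'bed12')")
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            if dialect == "refFlat":
                if len(toks) < 11:
                    raise ValueError(f"{path}:{lineno}: refFlat needs 11 columns, got {len(toks)}")
                gene_name, transcript_id, chrom, strand = toks[0], toks[1], toks[2], toks[3]
                tx_start = _parse_int(toks[4], path, lineno, "txStart")
                tx_end = _parse_int(toks[5], path, lineno, "txEnd")
                starts = [_parse_int(t, path, lineno, "exonStart") for t in toks[9].rstrip(",").split(",") if t]
                ends = [_parse_int(t, path, lineno, "exonEnd") for t in toks[10].rstrip(",").split(",") if t]
                if len(starts) != len(ends):
                    raise ValueError(f"{path}:{lineno}: exonStarts/exonEnds length mismatch")
                exons = tuple(zip(starts, ends))
            else:  # bed12
                if len(toks) < 12:
                    raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(toks)}")
                chrom, transcript_id, strand = toks[0], toks[3], toks[5]
                tx_start = _parse_int(toks[1], path, lineno, "chromStart")
                tx_end = _parse_int(toks[2], path, lineno, "chromEnd")
                n_blocks = _parse_int(toks[9], path, lineno, "blockCount")
                sizes = [_parse_int(t, path, lineno, "blockSize") for t in toks[10].rstrip(",").split(",") if t]
                offs = [_parse_int(t, path, lineno, "blockStart") for t in toks[11].rstrip(",").split(",") if t]
                if len(sizes) != n_blocks or len(offs) != n_blocks:
                    raise ValueError(f"{path}:{lineno}: block count mismatch")
                exons = tuple((tx_start + o, tx_start + o + s) for o, s in zip(offs, sizes))
                gene_name = transcript_id
            try:
                models.append(
                    TranscriptModel(transcript_id, gene_name, chrom, strand, tx_start, tx_end, exons)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return models


def nonredundant_tss(models: Iterable[TranscriptModel]) -> list[TssAnchor]:
    """Collapse mRNA ("NM_") transcript TSSs to unique (chrom, strand, pos) anchors.

    Non-mRNA accessions (NR_, XR_, ...) do not contribute. Anchors are
    sorted by (chrom, pos).
    """
    grouped: dict[tuple[str, str, int], list[TranscriptModel]] = {}
    for m in models:
        if not m.transcript_id.startswith("NM_"):
            continue
        grouped.setdefault((m.chrom, m.strand, m.tss), []).append(m)
    anchors = [
        TssAnchor(
            chrom=chrom,
            strand=strand,
            pos=pos,
            gene_name=members[0].gene_name,
            transcript_ids=tuple(m.transcript_id for m in members),
        )
        for (chrom, strand, pos), members in grouped.items()
    ]
    anchors.sort(key=lambda a: (a.chrom, a.pos, a.strand))
    return anchors


# ---------------------------------------------------------------------------
# tracks


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column chrom-sizes table (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name length'")
            sizes[toks[0]] = _parse_int(toks[1], path, lineno, "length")
    return sizes


def _read_bedgraph_into(counts: StrandedCounts, path: str, strand: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom = toks[0]
            start = _parse_int(toks[1], path, lineno, "start")
            end = _parse_int(toks[2], path, lineno, "end")
            value = float(toks[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value}")
            if value != int(value):
                raise ValueError(f"{path}:{lineno}: non-integer count {value}")
            length = counts.genome_lengths.get(chrom)
            if length is not None and end > length:
                raise ValueError(f"{path}:{lineno}: interval end {end} beyond {chrom} length {length}")
            n = int(value)
            if n:
                for pos in range(start, end):
                    counts.add(chrom, strand, pos, n)


def read_stranded_counts(
    plus_path: str,
    minus_path: str,
    genome: Mapping[str, int],
    total_aligned: int | None = None,
) -> StrandedCounts:
    """Materialize a plus/minus bedGraph pair of per-base 5'-end counts."""
    counts = StrandedCounts(genome, total_aligned=total_aligned)
    _read_bedgraph_into(counts, plus_path, "+")
    _read_bedgraph_into(counts, minus_path, "-")
    return counts


def read_score_bedgraph(path: str, genome: Mapping[str, int] | None = None) -> ScoreTrack:
    """Unstranded per-base scores from a bedGraph (values need not be integral)."""
    track = ScoreTrack(genome, stranded=False)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            start = _parse_int(toks[1], path, lineno, "start")
            end = _parse_int(toks[2], path, lineno, "end")
            value = float(toks[3])
            for pos in range(start, end):
                track.add(toks[0], pos, value)
    return track


def read_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    """Minimal BED3+ interval reader (CpG islands, motif occurrences, ...)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs at least 3 columns")
            out.append((toks[0], _parse_int(toks[1], path, lineno, "start"), _parse_int(toks[2], path, lineno, "end")))
    return out


def fragment_centers(
    reads: Iterable[tuple[str, str, int]],
    fragment_length: int,
    genome_lengths: Mapping[str, int] | None = None,
) -> ScoreTrack:
    """Extend each read 3'-ward to ``fragment_length`` and deposit one count at the center.

    The center of an even-length fragment is the lower-median base
    (floor of the midpoint). Fragments running off a chromosome edge are
    clipped to bounds before centering, so every read contributes exactly
    one center. Output is unstranded.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    lengths = dict(genome_lengths or {})
    track = ScoreTrack(lengths, stranded=False)
    for chrom, strand, five_prime in reads:
        if strand == "+":
            start, end = five_prime, five_prime + fragment_length
        elif strand == "-":
            start, end = five_prime - fragment_length + 1, five_prime + 1
        else:
            raise ValueError(f"bad strand {strand!r}")
        start = max(start, 0)
        length = lengths.get(chrom)
        if length is not None:
            end = min(end, length)
        if end <= start:  # fully off-contig read; keep its single center in bounds
            center = min(max(five_prime, 0), (length - 1) if length else five_prime)
        else:
            center = (start + end - 1) // 2
        track.add(chrom, center, 1.0)
    return track


# ---------------------------------------------------------------------------
# call I/O


def write_calls(callset, path: str) -> None:
    """Write a CallSet as BED6 plus a 7th column carrying the uncapped count.

    Name is ``class:gene_name``; score is the 5'-end count at the called
    base capped at 1000 for BED validity. Sorted by (chrom, start, class).
    """
    rows = []
    for call in callset.all_calls():
        rows.append(
            (
                call.chrom,
                call.pos,
                call.pos + 1,
                f"{call.klass}:{call.gene_name}",
                min(call.count, 1000),
                call.strand,
                call.count,
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[3].split(":")[0]))
    with open(path, "w") as fh:
        fh.write("# datsscan calls: chrom start end class:gene score strand count\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_calls(path: str) -> list[dict]:
    """Re-parse a write_calls BED into dicts (chrom, pos, strand, klass, gene_name, count)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            klass, gene_name = toks[3].split(":", 1)
            out.append(
                {
                    "chrom": toks[0],
                    "pos": int(toks[1]),
                    "strand": toks[5],
                    "klass": klass,
                    "gene_name": gene_name,
                    "count": int(toks[6]),
                }
            )
    return out


def bam_to_stranded_counts(bam_path: str, genome: Mapping[str, int] | None = None) -> StrandedCounts:
    """Extract read 5'-end counts per strand from an alignment.

    A thin pre-step only: for a plus-strand alignment the 5' end is
    ``reference_start``; for minus, ``reference_end - 1``. Unmapped and
    secondary/supplementary records are skipped.
    """
    import pysam

    with pysam.AlignmentFile(bam_path) as bam:
        lengths = genome or {name: length for name, length in zip(bam.references, bam.lengths)}
        counts = StrandedCounts(lengths)
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_reverse:
                counts.add(read.reference_name, "-", read.reference_end - 1)
            else:
                counts.add(read.reference_name, "+", read.reference_start)
    return counts
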