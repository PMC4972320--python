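"""Annotation-guided TSS calling from stranded single-base 5'-end counts.

The caller works promoter by promoter. A 2000-nt search window is centered
on each non-redundant annotated mRNA TSS; overlapping windows of the same
gene are merged, overlapping windows of different genes are split at the
midpoint between their nearest annotated TSSs. Within a window the gene
TSS is the better of two candidates — the window-wide argmax of the
gene-strand 5'-end counts, and the argmax within the densest 200-nt bin
(bins slide every 10 nt) — judged by proximity to the nearest annotated
TSS. Antisense TSSs are then called on the opposite strand as plain
argmaxes in fixed search spaces: 1-1000 nt upstream (uaTSS, divergent
transcription) and 1-2000 nt downstream (daTSS, convergent transcription)
of the called gene TSS. Every call requires the count at the called base
to meet the read threshold.

Two decoy filters guard daTSS calls: a daTSS is dropped if gene-strand
signal 1-1000 nt upstream of it (in its own transcriptional orientation)
reaches 10% of the linked gene-TSS count — the geometry of a uaTSS paired
with an uncalled gene TSS — or if an annotated TSS on its own strand lies
within 1000 nt, marking it as a potential gene TSS. uaTSS calls are not
filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .background import select_threshold
from .genome_io import StrandedCounts, TranscriptModel, TssAnchor, nonredundant_tss

__all__ = [
    "PipelineConfig",
    "SearchWindow",
    "TssCall",
    "CallSet",
    "build_search_windows",
    "best_bin_candidate",
    "call_gene_tss",
    "call_antisense_tss",
    "filter_datss",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

GENE = "gene"
UATSS = "uaTSS"
DATSS = "daTSS"

_OPPOSITE = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class PipelineConfig:
    """Calling constants.

    ``read_threshold=None`` selects the threshold from the Poisson
    background model (library depth over stranded genome positions);
    an integer overrides it (the published working value is 5).
    """

    gene_window_flank: int = 1000
    ua_search: int = 1000
    da_search: int = 2000
    bin_width: int = 200
    bin_stride: int = 10
    read_threshold: int | None = None
    da_filter_dist: int = 1000
    da_filter_frac: float = 0.10
    anno_tss_dist: int = 1000
    max_expected_fp: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gene_window_flank", "ua_search", "da_search", "bin_width", "bin_stride", "da_filter_dist", "anno_tss_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.da_filter_frac <= 1):
            raise ValueError("da_filter_frac must be in (0, 1]")


@dataclass
class SearchWindow:
    """Merged per-gene calling interval with its member annotated TSSs."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_name: str
    member_tss: list[int]
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty window [{self.start},{self.end}) for {self.gene_name}")


@dataclass(frozen=True)
class TssCall:
    """One called TSS of class gene, uaTSS or daTSS."""

    klass: str
    chrom: str
    strand: str
    pos: int
    count: int
    gene_name: str
    linked_gene_pos: int | None = None

    @property
    def distance(self) -> int | None:
        if self.linked_gene_pos is None:
            return None
        return abs(self.pos - self.linked_gene_pos)


@dataclass
class CallSet:
    """Called TSSs of the three classes with gene <-> antisense linkage."""

    gene_calls: list[TssCall] = field(default_factory=list)
    ua_calls: list[TssCall] = field(default_factory=list)
    da_calls: list[TssCall] = field(default_factory=list)
    dropped_da: list[tuple[TssCall, str]] = field(default_factory=list)
    read_threshold: int | None = None

    def all_calls(self) -> list[TssCall]:
        return [*self.gene_calls, *self.ua_calls, *self.da_calls]

    @property
    def n_genes(self) -> int:
        return len(self.gene_calls)

    @property
    def median_da_distance(self) -> float | None:
        if not self.da_calls:
            return None
        return float(median(c.distance for c in self.da_calls))

    @property
    def median_ua_distance(self) -> float | None:
        if not self.ua_calls:
            return None
        return float(median(c.distance for c in self.ua_calls))

    def genes_with(self, klass: str) -> set[str]:
        calls = {UATSS: self.ua_calls, DATSS: self.da_calls, GENE: self.gene_calls}[klass]
        return {c.gene_name for c in calls}

    def summary(self) -> dict:
        n = self.n_genes
        return {
            "n_gene_tss": n,
            "n_uaTSS": len(self.ua_calls),
            "n_daTSS": len(self.da_calls),
            "pct_uaTSS": 100.0 * len(self.ua_calls) / n if n else float("nan"),
            "pct_daTSS": 100.0 * len(self.da_calls) / n if n else float("nan"),
            "n_both": len(self.genes_with(UATSS) & self.genes_with(DATSS)),
            "median_ua_distance": self.median_ua_distance,
            "median_da_distance": self.median_da_distance,
            "n_dropped_daTSS": len(self.dropped_da),
            "read_threshold": self.read_threshold,
        }


# ---------------------------------------------------------------------------
# windows


def build_search_windows(
    anchors: Sequence[TssAnchor],
    config: PipelineConfig,
    genome_lengths: Mapping[str, int] | None = None,
) -> list[SearchWindow]:
    """Seed, merge and boundary-resolve per-gene search windows.

    Each anchor seeds ``[tss - flank, tss + flank)``. Same-gene overlapping
    windows are unioned; different-gene overlaps are cut at the midpoint
    between the nearest pair of member TSSs. Windows are clipped to
    chromosome bounds; a window emptied by truncation is dropped (logged).
    """
    lengths = dict(genome_lengths or {})
    flank = config.gene_window_flank

    seeds: list[SearchWindow] = []
    for a in anchors:
        start = max(a.pos - flank, 0)
        end = a.pos + flank
        limit = lengths.get(a.chrom)
        if limit is not None:
            end = min(end, limit)
        if start >= end:
            logger.warning("anchor %s:%d (%s) has empty window after clipping", a.chrom, a.pos, a.gene_name)
            continue
        seeds.append(
            SearchWindow(a.chrom, a.strand, start, end, a.gene_name, [a.pos], list(a.transcript_ids))
        )

    # pass 1: union overlapping windows of the same gene (same chrom+strand+name)
    seeds.sort(key=lambda w: (w.chrom, w.start, w.end))
    by_gene: dict[tuple[str, str, str], list[SearchWindow]] = {}
    for w in seeds:
        by_gene.setdefault((w.chrom, w.strand, w.gene_name), []).append(w)
    merged: list[SearchWindow] = []
    for group in by_gene.values():
        current = group[0]
        for w in group[1:]:
            if w.start < current.end:
                current.end = max(current.end, w.end)
                current.member_tss.extend(w.member_tss)
                current.transcript_ids.extend(w.transcript_ids)
            else:
                merged.append(current)
                current = w
        merged.append(current)
    for w in merged:
        w.member_tss.sort()

    # pass 2: cut different-gene overlaps at the midpoint of the nearest TSS pair
    merged.sort(key=lambda w: (w.chrom, w.start, w.end, w.gene_name))
    resolved: list[SearchWindow] = []
    for w in merged:
        while resolved and resolved[-1].chrom == w.chrom and w.start < resolved[-1].end:
            prev = resolved[-1]
            left_tss = max(prev.member_tss)
            right_tss = min(w.member_tss)
            mid = (left_tss + right_tss) // 2
            new_prev_end = min(prev.end, mid)
            new_start = max(w.start, mid)
            if new_prev_end <= prev.start:
                logger.warning("window for %s emptied by overlap with %s; dropped", prev.gene_name, w.gene_name)
                resolved.pop()
                continue
            prev.end = new_prev_end
            w.start = new_start
            if w.start >= w.end:
                logger.warning("window for %s emptied by overlap with %s; dropped", w.gene_name, prev.gene_name)
                w = None
            break
        if w is not None:
            if any(not (w.start <= t < w.end) for t in w.member_tss):
                logger.warning("window for %s no longer covers all member TSSs after resolution", w.gene_name)
            resolved.append(w)
    return resolved


# ---------------------------------------------------------------------------
# gene-TSS calling


def _argmax_position(
    positions: np.ndarray, counts: np.ndarray, reference_tss: Sequence[int]
) -> int:
    """Argmax over sparse positions; ties go to the position nearest an
    annotated TSS, then to the smallest coordinate."""
    best = counts.max()
    tied = positions[counts == best]
    if len(tied) == 1:
        return int(tied[0])
    ref = np.asarray(reference_tss)
    dist = np.abs(tied[:, None] - ref[None, :]).min(axis=1)
    tied = tied[dist == dist.min()]
    return int(tied.min())


def best_bin_candidate(
    window: SearchWindow, counts: StrandedCounts, config: PipelineConfig
) -> int | None:
    """Densest-bin candidate: position of maximum count inside the 200-nt bin
    (slid every 10 nt, fully inside the window) with the largest summed
    gene-strand count. Bin ties go to the leftmost bin; position ties to the
    smallest coordinate. ``None`` if the window carries no signal.

    A window shorter than one bin is evaluated as a single truncated bin.
    """
    arr = counts.window_array(window.chrom, window.start, window.end, window.strand)
    if arr.sum() == 0:
        return None
    width = min(config.bin_width, len(arr))
    csum = np.concatenate(([0], np.cumsum(arr)))
    starts = np.arange(0, len(arr) - width + 1, config.bin_stride)
    sums = csum[starts + width] - csum[starts]
    if sums.max() == 0:
        # signal exists but only in the trailing stretch no full bin covers
        return None
    bin_off = int(starts[int(np.argmax(sums))])  # np.argmax takes the first max
    seg = arr[bin_off : bin_off + width]
    return window.start + bin_off + int(np.argmax(seg))


def call_gene_tss(
    window: SearchWindow, counts: StrandedCounts, config: PipelineConfig
) -> TssCall | None:
    """Two-candidate gene-TSS call.

    Candidate A is the window-wide argmax of gene-strand counts; candidate B
    the densest-bin argmax. The one closer to the nearest member annotated
    TSS wins (tie -> A). ``None`` if no position reaches the read threshold.
    """
    threshold = config.read_threshold
    if threshold is None:
        raise ValueError("read_threshold must be resolved before calling (see run_pipeline)")
    arr = counts.window_array(window.chrom, window.start, window.end, window.strand)
    if arr.size == 0 or arr.max() < threshold:
        return None
    nz = np.nonzero(arr)[0]
    cand_a = _argmax_position(nz + window.start, arr[nz], window.member_tss)
    cand_b = best_bin_candidate(window, counts, config)
    ref = np.asarray(window.member_tss)
    dist_a = np.abs(cand_a - ref).min()
    dist_b = np.abs(cand_b - ref).min() if cand_b is not None else np.inf
    pos = cand_a if dist_a <= dist_b else cand_b
    return TssCall(
        klass=GENE,
        chrom=window.chrom,
        strand=window.strand,
        pos=int(pos),
        count=int(arr[pos - window.start]),
        gene_name=window.gene_name,
    )


# ---------------------------------------------------------------------------
# antisense calling


def _antisense_region(gene_pos: int, gene_strand: str, mode: str, config: PipelineConfig) -> tuple[int, int]:
    """Half-open genomic interval 1..N nt upstream/downstream of the gene TSS
    in gene orientation (the search itself is on the opposite strand)."""
    span = config.ua_search if mode == "upstream" else config.da_search
    if mode not in ("upstream", "downstream"):
        raise ValueError(f"unknown mode {mode!r}")
    if (gene_strand == "+") == (mode == "upstream"):
        return gene_pos - span, gene_pos  # positions gene_pos-span .. gene_pos-1
    return gene_pos + 1, gene_pos + 1 + span


def call_antisense_tss(
    gene_call: TssCall,
    counts: StrandedCounts,
    mode: str,
    config: PipelineConfig,
) -> TssCall | None:
    """Argmax antisense call in the upstream (uaTSS) or downstream (daTSS)
    search space; ties go to the position nearest the gene TSS, then the
    smallest coordinate. ``None`` below threshold."""
    threshold = config.read_threshold
    if threshold is None:
        raise ValueError("read_threshold must be resolved before calling")
    start, end = _antisense_region(gene_call.pos, gene_call.strand, mode, config)
    start = max(start, 0)
    limit = counts.genome_lengths.get(gene_call.chrom)
    if limit is not None:
        end = min(end, limit)
    if end <= start:
        return None
    strand = _OPPOSITE[gene_call.strand]
    arr = counts.window_array(gene_call.chrom, start, end, strand)
    if arr.size == 0 or arr.max() < threshold:
        return None
    nz = np.nonzero(arr)[0]
    pos = _argmax_position(nz + start, arr[nz], [gene_call.pos])
    return TssCall(
        klass=UATSS if mode == "upstream" else DATSS,
        chrom=gene_call.chrom,
        strand=strand,
        pos=pos,
        count=int(arr[pos - start]),
        gene_name=gene_call.gene_name,
        linked_gene_pos=gene_call.pos,
    )


def filter_datss(
    da_call: TssCall,
    gene_call: TssCall,
    counts: StrandedCounts,
    anchors: Sequence[TssAnchor],
    config: PipelineConfig,
) -> tuple[bool, str | None]:
    """Decoy filters for a daTSS call. Returns ``(keep, reason)``.

    Filter 1 ("hidden-gene-uaTSS"): gene-strand signal 1..1000 nt upstream
    of the daTSS, in the daTSS's own transcriptional orientation, at >= 10%
    of the gene-TSS count — the daTSS looks like a uaTSS of an uncalled
    gene TSS. Filter 2 ("potential-gene-TSS"): an annotated TSS on the
    daTSS's strand within +/-1000 nt.
    """
    # filter 1: upstream of the daTSS in its own orientation
    if da_call.strand == "+":
        region = (da_call.pos - config.da_filter_dist, da_call.pos)
    else:
        region = (da_call.pos + 1, da_call.pos + 1 + config.da_filter_dist)
    start = max(region[0], 0)
    limit = counts.genome_lengths.get(da_call.chrom)
    end = min(region[1], limit) if limit is not None else region[1]
    if end > start:
        arr = counts.window_array(da_call.chrom, start, end, gene_call.strand)
        if arr.size and arr.max() >= config.da_filter_frac * gene_call.count:
            return False, "hidden-gene-uaTSS"
    # filter 2: annotated TSS on the daTSS strand nearby (unsigned distance)
    for a in anchors:
        if (
            a.chrom == da_call.chrom
            and a.strand == da_call.strand
            and abs(a.pos - da_call.pos) <= config.anno_tss_dist
        ):
            return False, "potential-gene-TSS"
    return True, None


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(
    models: Iterable[TranscriptModel],
    counts: StrandedCounts,
    config: PipelineConfig | None = None,
) -> CallSet:
    """Full caller: anchors -> windows -> gene TSSs -> ua/daTSSs -> daTSS filters.

    If the config leaves ``read_threshold`` unset it is selected from the
    Poisson background model using the library depth and stranded genome
    size carried by ``counts``.
    """
    config = config or PipelineConfig()
    if config.read_threshold is None:
        model = select_threshold(
            counts.total_aligned, max(counts.stranded_positions, 1), config.max_expected_fp
        )
        config = PipelineConfig(**{**config.__dict__, "read_threshold": model.selected_k})
        logger.info("selected read threshold %d (expected FP %.3g)", model.selected_k, model.expected_fp)

    anchors = nonredundant_tss(models)
    windows = build_search_windows(anchors, config, counts.genome_lengths)

    callset = CallSet(read_threshold=config.read_threshold)
    seen_genes: set[str] = set()
    for window in windows:
        gene_call = call_gene_tss(window, counts, config)
        if gene_call is None:
            continue
        if gene_call.gene_name in seen_genes:
            # multiple resolved windows can share a gene name (distant loci); keep each
            pass
        seen_genes.add(gene_call.gene_name)
        callset.gene_calls.append(gene_call)
        ua = call_antisense_tss(gene_call, counts, "upstream", config)
        if ua is not None:
            callset.ua_calls.append(ua)
        da = call_antisense_tss(gene_call, counts, "downstream", config)
        if da is not None:
            keep, reason = filter_datss(da, gene_call, counts, anchors, config)
            if keep:
                callset.da_calls.append(da)
            else:
                logger.info("daTSS %s:%d (%s) dropped: %s", da.chrom, da.pos, da.gene_name, reason)
                callset.dropped_da.append((da, reason))
    return callset
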