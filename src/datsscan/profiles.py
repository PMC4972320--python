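"""TSS-anchored signal matrices and promoter-architecture summaries.

Heatmap-style matrices use 40-bp bins over anchor-centered windows; average
(metagene) profiles use 10-bp bins. Offsets are anchor-relative with the
anchor base at offset 0 and a half-open window ``[-flank, +flank)``;
minus-strand anchors are flipped so downstream is rightward. Antisense
(uaTSS/daTSS-centered) profiles can be mapped back onto gene-TSS
coordinates by reflecting about the antisense TSS and shifting by the
median gene-TSS distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import CallSet, DATSS, UATSS, TssCall
from .genome_io import ScoreTrack, StrandedCounts

__all__ = [
    "MatrixSpec",
    "BinnedMatrix",
    "Anchor",
    "binned_matrix",
    "metaprofile",
    "distance_histogram",
    "quartile_profiles",
    "reflect_and_shift",
    "base_composition",
    "cpg_edge_distances",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class Anchor:
    """A matrix row anchor: a strand-oriented genomic base, optionally
    carrying a distance used for sorting (e.g. gene TSS - daTSS distance)."""

    chrom: str
    strand: str
    pos: int
    distance: float | None = None


@dataclass(frozen=True)
class MatrixSpec:
    flank: int = 1000
    heatmap_bin: int = 40
    profile_bin: int = 10
    orient: bool = True
    sort_key: str = "position"
    same_strand: bool = True  # for stranded signal: anchor strand vs opposite

    def __post_init__(self) -> None:
        if self.flank % self.heatmap_bin or self.flank % self.profile_bin:
            raise ValueError("flank must be divisible by both bin sizes")
        if self.sort_key not in ("position", "distance"):
            raise ValueError(f"unknown sort key {self.sort_key!r}")


@dataclass
class BinnedMatrix:
    """anchors x bins signal matrix with bin edges in anchor-relative offsets."""

    anchors: list[Anchor]
    bin_edges: np.ndarray  # length n_bins + 1, offsets
    values: np.ndarray  # (n_anchors, n_bins)
    signal_name: str = ""
    spec: MatrixSpec | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{int(a)}:{int(b)}" for a, b in zip(self.bin_edges[:-1], self.bin_edges[1:])]
        idx = [f"{a.chrom}:{a.pos}({a.strand})" for a in self.anchors]
        return pd.DataFrame(self.values, index=idx, columns=cols)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _as_anchors(anchors: Iterable) -> list[Anchor]:
    out = []
    for a in anchors:
        if isinstance(a, Anchor):
            out.append(a)
        elif isinstance(a, TssCall):
            out.append(Anchor(a.chrom, a.strand, a.pos, a.distance))
        else:
            chrom, strand, pos, *rest = a
            out.append(Anchor(chrom, strand, int(pos), rest[0] if rest else None))
    return out


def _anchor_window(anchor: Anchor, signal, spec: MatrixSpec, bin_width: int) -> np.ndarray:
    """Per-bin signal mass in [-flank, +flank) around one anchor, oriented.

    Oriented offset o of genomic base x is x - pos for a plus anchor and
    pos - x for a flipped minus anchor, so the minus window covering
    offsets [-flank, flank) is the genomic span [pos-flank+1, pos+flank+1).
    """
    flip = spec.orient and anchor.strand == "-"
    if flip:
        start = anchor.pos - spec.flank + 1
        end = anchor.pos + spec.flank + 1
    else:
        start = anchor.pos - spec.flank
        end = anchor.pos + spec.flank
    c_start = max(start, 0)
    limit = getattr(signal, "genome_lengths", {}).get(anchor.chrom)
    c_end = min(end, limit) if limit is not None else end
    base = np.zeros(2 * spec.flank, dtype=float)
    if c_end > c_start:
        if isinstance(signal, StrandedCounts):
            strand = anchor.strand if spec.same_strand else ("-" if anchor.strand == "+" else "+")
            seg = signal.window_array(anchor.chrom, c_start, c_end, strand).astype(float)
        else:
            strand = None
            if getattr(signal, "stranded", False):
                strand = anchor.strand if spec.same_strand else ("-" if anchor.strand == "+" else "+")
            seg = np.asarray(signal.window_array(anchor.chrom, c_start, c_end, strand), dtype=float)
        base[c_start - start : c_end - start] = seg
    if flip:
        base = base[::-1]
    return base.reshape(-1, bin_width).sum(axis=1)


def _sorted_anchors(anchors: list[Anchor], sort_key: str) -> list[Anchor]:
    if sort_key == "distance":
        missing = [a for a in anchors if a.distance is None]
        if missing:
            raise ValueError("distance sort requires a distance on every anchor")
        return sorted(anchors, key=lambda a: (a.distance, a.chrom, a.pos))
    return sorted(anchors, key=lambda a: (a.chrom, a.pos))


def binned_matrix(anchors: Iterable, signal, spec: MatrixSpec | None = None, signal_name: str = "") -> BinnedMatrix:
    """Anchor-centered binned signal matrix (heatmap bins by default).

    Each cell holds the signal mass overlapping that bin of that anchor's
    window; windows running off a chromosome edge contribute zeros there.
    Rows are ordered by the spec's sort key.
    """
    spec = spec or MatrixSpec()
    ordered = _sorted_anchors(_as_anchors(anchors), spec.sort_key)
    n_bins = 2 * spec.flank // spec.heatmap_bin
    values = np.zeros((len(ordered), n_bins), dtype=float)
    for i, anchor in enumerate(ordered):
        values[i] = _anchor_window(anchor, signal, spec, spec.heatmap_bin)
    edges = np.arange(-spec.flank, spec.flank + 1, spec.heatmap_bin)
    return BinnedMatrix(ordered, edges, values, signal_name=signal_name, spec=spec)


def metaprofile(anchors: Iterable, signal, spec: MatrixSpec | None = None) -> np.ndarray:
    """Average per-bin signal across anchors (profile bins, default 10 bp)."""
    spec = spec or MatrixSpec()
    ordered = _as_anchors(anchors)
    if not ordered:
        raise ValueError("metaprofile requires at least one anchor")
    total = np.zeros(2 * spec.flank // spec.profile_bin, dtype=float)
    for anchor in ordered:
        total += _anchor_window(anchor, signal, spec, spec.profile_bin)
    return total / len(ordered)


def distance_histogram(callset: CallSet, klass: str, bin: int = 50) -> pd.Series:
    """Histogram of gene-relative antisense distances.

    uaTSS distances are reported negative (upstream of the gene TSS),
    daTSS distances positive (downstream); index gives bin left edges.
    """
    if klass == UATSS:
        dists = [-c.distance for c in callset.ua_calls]
    elif klass == DATSS:
        dists = [c.distance for c in callset.da_calls]
    else:
        raise ValueError(f"unknown class {klass!r}")
    if not dists:
        return pd.Series(dtype=int)
    lo = int(np.floor(min(dists) / bin)) * bin
    hi = int(np.floor(max(dists) / bin)) * bin + bin
    edges = np.arange(lo, hi + 1, bin)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.Series(counts, index=edges[:-1], name=f"{klass}_distance")


def quartile_profiles(callset: CallSet, signal, spec: MatrixSpec | None = None) -> list[np.ndarray]:
    """Gene-TSS-anchored metaprofiles for daTSS-bearing genes split into
    four equal-size groups by ascending gene TSS - daTSS distance.

    With n not divisible by 4 the remainder goes to the earliest quartiles
    (n=5 -> sizes 2,1,1,1). Ties in distance keep (chrom, pos) order.
    """
    calls = sorted(callset.da_calls, key=lambda c: (c.distance, c.chrom, c.pos))
    if len(calls) < 4:
        raise ValueError("quartile_profiles requires at least 4 daTSS calls")
    n = len(calls)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    profiles = []
    idx = 0
    for size in sizes:
        group = calls[idx : idx + size]
        idx += size
        anchors = [Anchor(c.chrom, _gene_strand(c), c.linked_gene_pos) for c in group]
        profiles.append(metaprofile(anchors, signal, spec))
    return profiles


def _gene_strand(antisense_call: TssCall) -> str:
    return "-" if antisense_call.strand == "+" else "+"


def reflect_and_shift(profile: np.ndarray, median_distance: float, direction: str, bin_width: int = 10) -> np.ndarray:
    """Map an antisense-TSS-centered profile onto gene-TSS coordinates.

    The offset axis is reflected about the antisense TSS (x -> -x) and then
    translated downstream by the median gene TSS - daTSS distance
    (``direction='downstream'``) or upstream by the median uaTSS distance
    (``'upstream'``). The shift is rounded to whole bins; positions leaving
    the window are dropped (zeros enter from the other side). Applying the
    same transform twice is the identity on the overlapping support.
    """
    if direction not in ("upstream", "downstream"):
        raise ValueError(f"unknown direction {direction!r}")
    shift_bins = int(round(median_distance / bin_width))
    if direction == "upstream":
        shift_bins = -shift_bins
    reflected = np.asarray(profile)[::-1]
    out = np.zeros_like(reflected)
    n = len(reflected)
    if shift_bins >= 0:
        out[shift_bins:] = reflected[: n - shift_bins]
    else:
        out[: n + shift_bins] = reflected[-shift_bins:]
    return out


def base_composition(genome, anchors: Iterable, flank: int = 1000) -> pd.DataFrame:
    """Per-offset A/C/G/T fractions over strand-oriented anchor windows.

    ``genome`` is a mapping chrom -> sequence (a ``pyfaidx.Fasta`` works).
    Minus-strand windows are reverse-complemented so offsets read in the
    direction of transcription. N (or off-contig) positions are excluded
    from the denominator; an ``n_total`` column reports coverage.
    """
    offsets = np.arange(-flank, flank)
    counts = {b: np.zeros(2 * flank, dtype=np.int64) for b in "ACGTN"}
    totals = np.zeros(2 * flank, dtype=np.int64)
    for anchor in _as_anchors(anchors):
        seq_obj = genome[anchor.chrom]
        contig = str(seq_obj[:]) if not isinstance(seq_obj, str) else seq_obj
        if anchor.strand == "-":
            start, end = anchor.pos - flank + 1, anchor.pos + flank + 1
        else:
            start, end = anchor.pos - flank, anchor.pos + flank
        c_start, c_end = max(start, 0), min(end, len(contig))
        window = ["N"] * (2 * flank)
        if c_end > c_start:
            window[c_start - start : c_end - start] = list(contig[c_start:c_end].upper())
        if anchor.strand == "-":
            window = list("".join(window).translate(_COMP)[::-1])
        for i, b in enumerate(window):
            key = b if b in "ACGT" else "N"
            counts[key][i] += 1
            if key != "N":
                totals[i] += 1
    data = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in "ACGT":
            data[b] = np.where(totals > 0, counts[b] / np.maximum(totals, 1), np.nan)
    data["n_total"] = totals
    data["N"] = counts["N"]
    return pd.DataFrame(data, index=pd.Index(offsets, name="offset"))


def cpg_edge_distances(
    callset: CallSet,
    cpg_islands: Sequence[tuple[str, int, int]],
    max_dist: int = 250,
) -> tuple[pd.Series, float]:
    """Distance from each daTSS to the downstream edge of its promoter CpG island.

    Only daTSSs whose linked gene TSS lies inside an island are scored. The
    downstream edge is the island end for plus-strand genes and the island
    start for minus-strand genes (gene orientation). Returns per-daTSS
    distances and the fraction within ``max_dist`` bp.
    """
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in sorted(cpg_islands):
        ivs = merged.setdefault(chrom, [])
        if ivs and s <= ivs[-1][1]:
            ivs[-1] = (ivs[-1][0], max(ivs[-1][1], e))
        else:
            ivs.append((s, e))
    dists = {}
    for call in callset.da_calls:
        gene_pos = call.linked_gene_pos
        island = None
        for s, e in merged.get(call.chrom, []):
            if s <= gene_pos < e:
                island = (s, e)
                break
        if island is None:
            continue
        edge = island[1] if _gene_strand(call) == "+" else island[0]
        dists[f"{call.chrom}:{call.pos}"] = abs(call.pos - edge)
    series = pd.Series(dists, dtype=float, name="cpg_edge_distance")
    frac = float((series <= max_dist).mean()) if len(series) else float("nan")
    return series, frac
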