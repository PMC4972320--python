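"""Synthetic promoter landscapes with planted gene/ua/da TSSs and decoys.

The generator emulates the statistical structure the caller assumes: well
separated two-exon gene models on a single synthetic chromosome, stranded
single-base 5'-end counts with a sharp spike at every planted TSS,
uniform Poisson background, and — at a configurable fraction of
daTSS-bearing genes — a planted sense-strand "hidden gene" decoy upstream
of the daTSS that the hidden-gene filter must remove. Per-class mean read
totals default to the observed Start-seq averages (776 / 467 / 276 reads
at gene TSSs, uaTSSs and daTSSs) and class prevalences to 53% uaTSS, 28%
daTSS with a positively associated joint law (both at ~17.5% of genes).

Everything is driven by one seed: identical config + seed reproduces the
annotation, the truth and the counts byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import CallSet, DATSS, GENE, UATSS
from .genome_io import StrandedCounts, TranscriptModel

__all__ = [
    "SyntheticConfig",
    "GeneTruth",
    "TruthSet",
    "simulate_genome",
    "simulate_counts",
    "evaluate_recovery",
    "write_truth",
    "read_truth",
    "write_refflat",
    "write_counts_bedgraphs",
]

CHROM = "chrS"
_TX_LEN = 5000  # synthetic transcript span: 200-bp first exon, intron, 200-bp last exon
_MARGIN = 6000
_SPREAD = 5  # positional half-width of the 5'-end spike
_SPREAD_PEAK = 0.6  # probability mass at the exact planted base
_SPREAD_DECAY = 0.5  # geometric decay of the remaining mass over offsets 1..5


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    chrom_length: int = 10_000_000
    n_genes: int = 500
    min_gene_spacing: int = 10_000
    p_ua: float = 0.53
    p_da: float = 0.28
    p_both: float = 0.1747  # > p_ua * p_da: positive ua/da association
    mean_gene: float = 776.0
    mean_ua: float = 467.0
    mean_da: float = 276.0
    dispersion: float = 2.0  # negative-binomial size parameter
    background_rate: float = 1e-5  # expected reads per stranded base
    decoy_fraction: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.p_ua, self.p_da, self.p_both):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_both > min(self.p_ua, self.p_da) or self.p_ua + self.p_da - self.p_both > 1:
            raise ValueError("inconsistent joint (ua, da) law")
        if min(self.mean_gene, self.mean_ua, self.mean_da) <= 0:
            raise ValueError("class means must be positive")
        if self.min_gene_spacing * self.n_genes >= self.chrom_length - 2 * _MARGIN:
            raise ValueError("cannot pack n_genes at min_gene_spacing into chrom_length")


@dataclass
class GeneTruth:
    """Planted architecture of one synthetic gene."""

    gene_name: str
    chrom: str
    strand: str
    tss: int
    ua_pos: int | None = None
    da_pos: int | None = None
    decoy_pos: int | None = None  # sense-strand hidden-gene spike (daTSS genes only)
    total_gene: int = 0
    total_ua: int = 0
    total_da: int = 0
    decoy_count: int = 0

    @property
    def is_decoy(self) -> bool:
        return self.decoy_pos is not None


@dataclass
class TruthSet:
    config: SyntheticConfig
    genes: list[GeneTruth] = field(default_factory=list)

    def planted(self, klass: str, include_decoy_da: bool = False) -> list[tuple[str, int]]:
        """(strand, position) of planted TSSs of one class.

        Antisense classes sit on the strand opposite the gene. daTSSs at
        decoy genes are excluded by default: the decoy construction makes
        them indistinguishable from mis-called uaTSSs, so the filters are
        expected to remove them.
        """
        out = []
        for g in self.genes:
            anti = "-" if g.strand == "+" else "+"
            if klass == GENE:
                out.append((g.strand, g.tss))
            elif klass == UATSS and g.ua_pos is not None:
                out.append((anti, g.ua_pos))
            elif klass == DATSS and g.da_pos is not None:
                if include_decoy_da or not g.is_decoy:
                    out.append((anti, g.da_pos))
        return out


def _gene_model(name: str, strand: str, tss: int) -> TranscriptModel:
    if strand == "+":
        tx_start, tx_end = tss, tss + _TX_LEN
    else:
        tx_start, tx_end = tss - _TX_LEN + 1, tss + 1
    exons = ((tx_start, tx_start + 200), (tx_end - 200, tx_end))
    return TranscriptModel(f"NM_{name}", name, CHROM, strand, tx_start, tx_end, exons)


def simulate_genome(config: SyntheticConfig) -> tuple[list[TranscriptModel], TruthSet]:
    """Lay out gene models and plant the promoter architecture.

    Gene TSSs occupy evenly sized slots with jitter, guaranteeing the
    minimum spacing; strands are a seeded coin. ua/da presence follows the
    joint four-category law; ua distances are uniform on [1, 1000] and da
    distances uniform on [1, 2000] excluding the first 5 nt (the spike
    half-width, so a planted daTSS is never self-shadowed by the gene-TSS
    read spread under the hidden-gene filter). Decoy genes additionally
    plant a sense-strand spike 1-1000 nt upstream of the daTSS in the
    daTSS's orientation.
    """
    rng = np.random.default_rng([config.seed, 0])
    usable = config.chrom_length - 2 * _MARGIN
    slot = usable // config.n_genes
    jitter_max = slot - config.min_gene_spacing
    if jitter_max < 0:
        raise ValueError("cannot pack n_genes at min_gene_spacing into chrom_length")

    p_ua_only = config.p_ua - config.p_both
    p_da_only = config.p_da - config.p_both
    p_neither = 1.0 - p_ua_only - p_da_only - config.p_both
    cat_p = [config.p_both, p_ua_only, p_da_only, p_neither]

    models: list[TranscriptModel] = []
    truth = TruthSet(config=config)
    for i in range(config.n_genes):
        tss = _MARGIN + i * slot + int(rng.integers(0, jitter_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"G{i:04d}"
        models.append(_gene_model(name, strand, tss))
        g = GeneTruth(gene_name=name, chrom=CHROM, strand=strand, tss=tss)
        cat = rng.choice(4, p=cat_p)
        has_ua = cat in (0, 1)
        has_da = cat in (0, 2)
        sign = 1 if strand == "+" else -1
        if has_ua:
            g.ua_pos = tss - sign * int(rng.integers(1, 1001))
        if has_da:
            d = int(rng.integers(_SPREAD + 1, 2001))
            g.da_pos = tss + sign * d
            if rng.random() < config.decoy_fraction:
                g.decoy_pos = g.da_pos + sign * int(rng.integers(1, 1001))
        truth.genes.append(g)
    return models, truth


def _spread_weights() -> np.ndarray:
    offs = np.arange(-_SPREAD, _SPREAD + 1)
    w = _SPREAD_DECAY ** np.abs(offs).astype(float)
    w[_SPREAD] = 0.0
    w *= (1.0 - _SPREAD_PEAK) / w.sum()
    w[_SPREAD] = _SPREAD_PEAK
    return w


def _deposit(counts: StrandedCounts, rng, chrom: str, strand: str, pos: int, total: int) -> None:
    if total <= 0:
        return
    alloc = rng.multinomial(total, _spread_weights())
    for off, n in zip(range(-_SPREAD, _SPREAD + 1), alloc):
        if n:
            counts.add(chrom, strand, pos + off, int(n))


def _nb(rng, mean: float, size: float) -> int:
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def simulate_counts(truth: TruthSet, config: SyntheticConfig | None = None) -> StrandedCounts:
    """Draw stranded 5'-end counts for a planted truth set.

    Per-TSS totals are negative binomial (configured class mean,
    dispersion) spread over +/-5 nt with 60% of the mass on the exact
    base; decoy genes get a sense-strand spike of ceil(10% of the gene
    total); background is per-base Poisson on both strands. Realized
    totals are written back onto the truth records.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    counts = StrandedCounts({CHROM: config.chrom_length})
    for g in truth.genes:
        anti = "-" if g.strand == "+" else "+"
        sign = 1 if g.strand == "+" else -1
        g.total_gene = _nb(rng, config.mean_gene, config.dispersion)
        _deposit(counts, rng, g.chrom, g.strand, g.tss, g.total_gene)
        if g.ua_pos is not None:
            g.total_ua = _nb(rng, config.mean_ua, config.dispersion)
            _deposit(counts, rng, g.chrom, anti, g.ua_pos, g.total_ua)
        if g.da_pos is not None:
            g.total_da = _nb(rng, config.mean_da, config.dispersion)
            _deposit(counts, rng, g.chrom, anti, g.da_pos, g.total_da)
        if g.decoy_pos is not None:
            g.decoy_count = math.ceil(0.1 * g.total_gene)
            if g.decoy_count:
                counts.add(g.chrom, g.strand, g.decoy_pos, g.decoy_count)
    # uniform Poisson background, sparse draw: number of events then positions
    n_bg = int(rng.poisson(config.background_rate * 2 * config.chrom_length))
    if n_bg:
        positions = rng.integers(0, config.chrom_length, size=n_bg)
        strands = rng.integers(0, 2, size=n_bg)
        for pos, s in zip(positions, strands):
            counts.add(CHROM, "+" if s == 0 else "-", int(pos))
    return counts


# ---------------------------------------------------------------------------
# evaluation


def _greedy_match(
    called: list[tuple[str, int]], planted: list[tuple[str, int]], tol: int
) -> list[tuple[int, int, int]]:
    """One-to-one greedy matching by distance; returns (call_idx, planted_idx, |delta|)."""
    pairs = []
    for i, (cs, cp) in enumerate(called):
        for j, (ps, pp) in enumerate(planted):
            if cs == ps and abs(cp - pp) <= tol:
                pairs.append((abs(cp - pp), i, j))
    pairs.sort()
    used_c: set[int] = set()
    used_p: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if i in used_c or j in used_p:
            continue
        used_c.add(i)
        used_p.add(j)
        matches.append((i, j, d))
    return matches


def evaluate_recovery(truth: TruthSet, callset: CallSet, tolerance: int = 0) -> dict:
    """Score a call set against the planted truth.

    Per class: precision, recall and the positional-error distribution of
    matched calls (one-to-one greedy matching by distance at
    ``+/- tolerance`` nt, strands must agree). The filter confusion table
    counts planted decoys whose daTSS was dropped (correct removals) and
    dropped daTSS calls matching a planted non-decoy daTSS (wrong
    removals).
    """
    out: dict = {"tolerance": tolerance, "classes": {}}
    by_class = {GENE: callset.gene_calls, UATSS: callset.ua_calls, DATSS: callset.da_calls}
    for klass, calls in by_class.items():
        called = [(c.strand, c.pos) for c in calls]
        planted = truth.planted(klass)
        matches = _greedy_match(called, planted, tolerance)
        n_match = len(matches)
        out["classes"][klass] = {
            "n_called": len(called),
            "n_planted": len(planted),
            "n_matched": n_match,
            "precision": n_match / len(called) if called else float("nan"),
            "recall": n_match / len(planted) if planted else float("nan"),
            "position_errors": sorted(d for _, _, d in matches),
        }
    decoy_genes = {g.gene_name for g in truth.genes if g.is_decoy}
    dropped = callset.dropped_da
    decoys_removed = sum(1 for call, _ in dropped if call.gene_name in decoy_genes)
    true_da = truth.planted(DATSS)
    wrong = _greedy_match([(c.strand, c.pos) for c, _ in dropped], true_da, tolerance)
    decoys_surviving = sum(1 for c in callset.da_calls if c.gene_name in decoy_genes)
    out["filter_confusion"] = {
        "n_decoys": len(decoy_genes),
        "decoys_removed": decoys_removed,
        "decoys_surviving": decoys_surviving,
        "true_daTSS_removed": len(wrong),
    }
    return out


# ---------------------------------------------------------------------------
# text serialization (all deliverable formats are plain text)


def write_refflat(models: Sequence[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            cds = m.tx_start  # non-coding placeholder: cdsStart == cdsEnd
            fh.write(
                "\t".join(
                    [
                        m.gene_name,
                        m.transcript_id,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(cds),
                        str(cds),
                        str(len(m.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def write_counts_bedgraphs(counts: StrandedCounts, out_prefix: str) -> tuple[str, str]:
    paths = (f"{out_prefix}.plus.bedGraph", f"{out_prefix}.minus.bedGraph")
    for strand, path in zip(("+", "-"), paths):
        with open(path, "w") as fh:
            for chrom in sorted(counts.genome_lengths):
                pos, vals = counts.positions(chrom, strand)
                for p, v in zip(pos, vals):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{v}\n")
    return paths


def write_truth(truth: TruthSet, path: str) -> None:
    rows = [
        {
            "gene_name": g.gene_name,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "ua_pos": g.ua_pos,
            "da_pos": g.da_pos,
            "decoy_pos": g.decoy_pos,
            "total_gene": g.total_gene,
            "total_ua": g.total_ua,
            "total_da": g.total_da,
            "decoy_count": g.decoy_count,
        }
        for g in truth.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str, config: SyntheticConfig | None = None) -> TruthSet:
    df = pd.read_csv(path, sep="\t")
    truth = TruthSet(config=config or SyntheticConfig())
    for _, r in df.iterrows():
        truth.genes.append(
            GeneTruth(
                gene_name=str(r["gene_name"]),
                chrom=str(r["chrom"]),
                strand=str(r["strand"]),
                tss=int(r["tss"]),
                ua_pos=None if pd.isna(r["ua_pos"]) else int(r["ua_pos"]),
                da_pos=None if pd.isna(r["da_pos"]) else int(r["da_pos"]),
                decoy_pos=None if pd.isna(r["decoy_pos"]) else int(r["decoy_pos"]),
                total_gene=int(r["total_gene"]),
                total_ua=int(r["total_ua"]),
                total_da=int(r["total_da"]),
                decoy_count=int(r["decoy_count"]),
            )
        )
    return truth
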