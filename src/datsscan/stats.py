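"""Inferential layer: co-occurrence, shifted-control enrichment, correlation,
expression-group comparisons, intron-overlap shuffles and cross-dataset
support.

P-values are reported raw (no multiple-testing correction), matching the
convention for single planned contrasts. The rank-sum test is the
two-sided Mann-Whitney/Wilcoxon with normal approximation, continuity and
tie correction; Fisher's exact test is two-sided by the
probability-mass-at-most-observed rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .calling import CallSet, DATSS, GENE, UATSS, TssCall
from .genome_io import StrandedCounts, TranscriptModel

__all__ = [
    "AnalysisConfig",
    "cooccurrence_test",
    "positional_enrichment",
    "count_correlation",
    "expression_comparison",
    "intron_overlap",
    "cross_support",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Window sizes, shifts and tolerances for the statistical queries.

    ``shift`` defaults to the call set's median gene TSS - daTSS distance
    when built via :meth:`for_callset` (the published value is 507 nt).
    """

    enrich_window: int = 100
    shift: int = 507
    cpg_edge_max: int = 250
    support_tol: int = 10
    shuffle_iters: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrich_window % 2:
            raise ValueError("enrich_window must be even")
        if self.shuffle_iters < 1:
            raise ValueError("shuffle_iters must be >= 1")

    @classmethod
    def for_callset(cls, callset: CallSet, **overrides) -> "AnalysisConfig":
        med = callset.median_da_distance
        if med is not None and "shift" not in overrides:
            overrides["shift"] = int(round(med))
        return cls(**overrides)


# ---------------------------------------------------------------------------


def cooccurrence_test(n_genes: int, n_ua: int, n_da: int, n_both: int):
    """Two-sided Fisher's exact test for uaTSS/daTSS co-occurrence across genes.

    Returns the 2x2 table ``[[both, ua_only], [da_only, neither]]``, the
    sample odds ratio and the exact two-sided p-value.
    """
    if n_both > min(n_ua, n_da):
        raise ValueError("n_both cannot exceed either margin")
    if n_ua + n_da - n_both > n_genes:
        raise ValueError("margins exceed the number of genes")
    table = np.array(
        [[n_both, n_ua - n_both], [n_da - n_both, n_genes - n_ua - n_da + n_both]],
        dtype=np.int64,
    )
    res = sps.fisher_exact(table, alternative="two-sided")
    return table, float(res[0]), float(res[1])


def _window_mass(signal, chrom: str, center: int, half: int) -> float:
    start = max(center - half, 0)
    limit = getattr(signal, "genome_lengths", {}).get(chrom)
    end = center + half
    if limit is not None:
        end = min(end, limit)
    if end <= start:
        return 0.0
    return float(signal.window_array(chrom, start, end).sum())


def positional_enrichment(
    signal,
    da_calls: Sequence[TssCall],
    genes_without_da: Sequence[TssCall],
    config: AnalysisConfig | None = None,
):
    """Signal enrichment at daTSSs against shifted-control promoter windows.

    Group 1 is the signal mass in a 100-bp window centered on each daTSS;
    group 2 the mass in a 100-bp window placed downstream of the gene TSS
    (in gene orientation) by the median observed gene TSS - daTSS distance,
    at genes lacking a daTSS. Returns the two samples, the Mann-Whitney U
    statistic and the two-sided p-value.
    """
    config = config or AnalysisConfig()
    if not len(da_calls) or not len(genes_without_da):
        raise ValueError("both groups must be non-empty")
    half = config.enrich_window // 2
    group1 = np.array([_window_mass(signal, c.chrom, c.pos, half) for c in da_calls])
    centers = [
        (g.chrom, g.pos + config.shift if g.strand == "+" else g.pos - config.shift)
        for g in genes_without_da
    ]
    group2 = np.array([_window_mass(signal, chrom, center, half) for chrom, center in centers])
    stat, p = sps.mannwhitneyu(group1, group2, alternative="two-sided", method="asymptotic")
    return group1, group2, float(stat), float(p)


def count_correlation(callset: CallSet, min_n: int = 3):
    """Spearman correlation between gene-TSS and daTSS 5'-end counts.

    Restricted to genes with a daTSS and no uaTSS, removing any influence
    of upstream antisense transcription on the pairing.
    """
    ua_genes = callset.genes_with(UATSS)
    gene_count = {c.gene_name: c.count for c in callset.gene_calls}
    pairs = [
        (gene_count[c.gene_name], c.count)
        for c in callset.da_calls
        if c.gene_name not in ua_genes and c.gene_name in gene_count
    ]
    if len(pairs) < min_n:
        raise ValueError(f"need at least {min_n} (gene, daTSS) pairs, got {len(pairs)}")
    x, y = zip(*pairs)
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), len(pairs)


def expression_comparison(
    expression: Mapping[str, float],
    callset: CallSet,
    grouping: str,
):
    """Compare expression (e.g. FPKM) between promoter-architecture groups.

    Groupings: ``da_vs_noda_without_ua`` (genes with vs without a daTSS,
    restricted to genes without uaTSSs), ``ua_only_vs_da_only`` and
    ``ua_vs_noua_without_da``. Returns group sizes, rank-sum p and
    two-sample Kolmogorov-Smirnov p.
    """
    ua = callset.genes_with(UATSS)
    da = callset.genes_with(DATSS)
    genes = callset.genes_with(GENE)
    if grouping == "da_vs_noda_without_ua":
        g1 = (genes - ua) & da
        g2 = genes - ua - da
    elif grouping == "ua_only_vs_da_only":
        g1 = ua - da
        g2 = da - ua
    elif grouping == "ua_vs_noua_without_da":
        g1 = (genes - da) & ua
        g2 = genes - da - ua
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    v1 = np.array([expression[g] for g in sorted(g1) if g in expression])
    v2 = np.array([expression[g] for g in sorted(g2) if g in expression])
    if not len(v1) or not len(v2):
        raise ValueError("a group is empty after restriction")
    _, p_rank = sps.mannwhitneyu(v1, v2, alternative="two-sided", method="asymptotic")
    _, p_ks = sps.ks_2samp(v1, v2)
    return (len(v1), len(v2)), float(p_rank), float(p_ks)


# ---------------------------------------------------------------------------
# intron overlap


def _is_intronic(pos: int, chrom: str, models: Sequence[TranscriptModel]) -> bool:
    for m in models:
        if m.chrom != chrom or not (m.tx_start <= pos < m.tx_end):
            continue
        if any(s <= pos < e for s, e in m.introns):
            return True
    return False


def intron_overlap(
    da_calls: Sequence[TssCall],
    models: Sequence[TranscriptModel],
    genome_lengths: Mapping[str, int],
    config: AnalysisConfig | None = None,
):
    """Observed intronic fraction of daTSSs versus randomly placed gene models.

    A daTSS is intronic if it falls within some transcript's span outside
    that transcript's exons (any overlapping transcript counts). The null
    re-places every transcript uniformly at random on its own chromosome,
    preserving length and internal exon offsets, and recomputes the
    fraction; the generator is seeded, so runs are reproducible.
    """
    config = config or AnalysisConfig()
    if not len(da_calls):
        raise ValueError("no daTSS calls")
    observed = float(np.mean([_is_intronic(c.pos, c.chrom, models) for c in da_calls]))
    rng = np.random.default_rng(config.seed)
    fractions = []
    for _ in range(config.shuffle_iters):
        shuffled = []
        for m in models:
            span = m.tx_end - m.tx_start
            limit = genome_lengths.get(m.chrom, m.tx_end)
            hi = max(limit - span, 1)
            new_start = int(rng.integers(0, hi))
            shift = new_start - m.tx_start
            shuffled.append(
                TranscriptModel(
                    m.transcript_id,
                    m.gene_name,
                    m.chrom,
                    m.strand,
                    new_start,
                    new_start + span,
                    tuple((s + shift, e + shift) for s, e in m.exons),
                )
            )
        fractions.append(float(np.mean([_is_intronic(c.pos, c.chrom, shuffled) for c in da_calls])))
    return observed, float(np.mean(fractions)), fractions


def cross_support(
    calls: Sequence[TssCall],
    other_signal: StrandedCounts,
    config: AnalysisConfig | None = None,
):
    """Partition calls by presence of independent same-strand signal nearby.

    A call is supported iff any nonzero same-strand count of the other
    dataset (e.g. GRO-cap 5' ends) lies within +/- ``support_tol`` nt of
    the called base. Enlarging the tolerance never shrinks the supported
    set.
    """
    config = config or AnalysisConfig()
    tol = config.support_tol
    supported, unsupported = [], []
    for c in calls:
        arr = other_signal.window_array(c.chrom, max(c.pos - tol, 0), c.pos + tol + 1, c.strand)
        (supported if arr.sum() > 0 else unsupported).append(c)
    return {
        "supported": supported,
        "unsupported": unsupported,
        "n_supported": len(supported),
        "n_unsupported": len(unsupported),
        "frac_supported": len(supported) / len(calls) if calls else float("nan"),
    }
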