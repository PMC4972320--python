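"""Poisson-background read threshold for single-base TSS calling.

Reads are modelled as falling uniformly over every (position, strand) pair
of the genome, so per-position counts are Poisson with rate
``lambda = total_reads / (2 * genome_length)``. The calling threshold is the
smallest per-base count ``k`` whose genome-wide expected number of
background exceedances ``N * P(X >= k)`` falls below a bound (default:
fewer than one expected false-positive position).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["ThresholdModel", "poisson_upper_tail", "expected_false_positives", "select_threshold"]


@dataclass(frozen=True)
class ThresholdModel:
    """A selected read threshold and the background model that produced it."""

    total_reads: int
    stranded_positions: int
    max_expected_fp: float
    selected_k: int

    @property
    def lambda_per_pos(self) -> float:
        return self.total_reads / self.stranded_positions

    @property
    def expected_fp(self) -> float:
        """Expected background positions at or above the selected threshold."""
        return expected_false_positives(self.selected_k, self.total_reads, self.stranded_positions)

    def table(self, k_max: int | None = None) -> list[tuple[int, float]]:
        """(k, expected false positives) rows for k = 1 .. selected_k + 2."""
        top = k_max if k_max is not None else self.selected_k + 2
        return [
            (k, expected_false_positives(k, self.total_reads, self.stranded_positions))
            for k in range(1, top + 1)
        ]


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), via the survival function P(X > k-1)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def expected_false_positives(k: int, total_reads: int, stranded_positions: int) -> float:
    """Expected number of stranded positions reaching count >= k by chance."""
    if stranded_positions < 1:
        raise ValueError("stranded_positions must be >= 1")
    lam = total_reads / stranded_positions
    return stranded_positions * poisson_upper_tail(k, lam)


def select_threshold(
    total_reads: int,
    stranded_positions: int,
    max_expected_fp: float = 1.0,
) -> ThresholdModel:
    """Smallest k >= 1 whose expected false-positive count is below the bound.

    The Poisson upper tail decreases to zero in k, so a threshold always
    exists; for an empty library k = 1.
    """
    if stranded_positions < 1:
        raise ValueError("stranded_positions must be >= 1")

    def ok(k: int) -> bool:
        return expected_false_positives(k, total_reads, stranded_positions) < max_expected_fp

    # exponential then binary search: the expected-FP curve is decreasing in k
    hi = 1
    while not ok(hi):
        hi *= 2
    lo = hi // 2  # every k <= lo failed (or lo == 0)
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    k = hi
    return ThresholdModel(
        total_reads=total_reads,
        stranded_positions=stranded_positions,
        max_expected_fp=max_expected_fp,
        selected_k=k,
    )
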