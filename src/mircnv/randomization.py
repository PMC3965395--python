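"""Monte Carlo null distribution of the hits statistic.

Null hypothesis: each CNV keeps its observed length but its position is
uniform over the chromosome, the CNV lying wholly within ``[1, G]``;
placements are mutually independent, so simulated CNVs may overlap one
another.  Each realization re-places every CNV of one type on one
chromosome and recomputes the hits statistic (same definition as
:func:`mircnv.overlap.count_hits`); the histogram of hit counts over ``N``
realizations is the empirical null, and the upper-tail p-value for an
observed count ``h`` is the fraction of realizations with ``hits >= h``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mircnv.io import MirnaGene
from mircnv.overlap import OVERLAP_MODES

DEFAULT_REALIZATIONS = 1_000_000

# realizations x CNVs processed per vectorized chunk; bounds peak memory
_CHUNK_CELLS = 4_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one Monte Carlo run."""

    n_realizations: int = DEFAULT_REALIZATIONS
    seed: int | None = None
    overlap_mode: str = "any"

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.overlap_mode not in OVERLAP_MODES:
            raise ValueError(f"unknown overlap mode {self.overlap_mode!r}")


@dataclass
class NullDistribution:
    """Distribution of the hits statistic under random CNV placement.

    ``counts`` maps a hit count to the number of realizations attaining it
    (``source='monte_carlo'``) or to its exact probability
    (``source='exact'``).
    """

    counts: Mapping[int, float]
    n_realizations: int
    source: str = "monte_carlo"
    chrom: str | None = None
    cnv_type: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.source == "monte_carlo":
            total = sum(self.counts.values())
            if total != self.n_realizations:
                raise ValueError(
                    f"histogram mass {total} != n_realizations {self.n_realizations}"
                )
        elif self.source == "exact":
            if abs(sum(self.counts.values()) - 1.0) > 1e-12:
                raise ValueError("exact pmf does not sum to 1 within 1e-12")
        else:
            raise ValueError(f"unknown source {self.source!r}")

    def pmf(self) -> dict[int, float]:
        """Normalized probability mass function over hit counts."""
        if self.source == "exact":
            return dict(self.counts)
        n = self.n_realizations
        return {k: v / n for k, v in self.counts.items()}

    def mean(self) -> float:
        return sum(k * p for k, p in self.pmf().items())

    def tail_probability(self, k: int) -> float:
        """P(hits >= k) under this null."""
        return sum(p for h, p in self.pmf().items() if h >= k)


def place_random(
    cnv_lengths: Sequence[int], chrom_length: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Place each CNV uniformly at random, wholly inside the chromosome.

    For a CNV of length ``L`` the start is uniform on ``{1, ..., G-L+1}``;
    placements are independent and may overlap.  Returns closed intervals
    ``(start, end)``.
    """
    intervals = []
    for i, L in enumerate(cnv_lengths):
        if L < 1:
            raise ValueError(f"CNV #{i}: length must be >= 1, got {L}")
        if L > chrom_length:
            raise ValueError(
                f"CNV #{i}: length {L} exceeds chromosome length {chrom_length}"
            )
        start = int(rng.integers(1, chrom_length - L + 2))
        intervals.append((start, start + L - 1))
    return intervals


def _hit_counts_for_starts(
    starts: np.ndarray,
    L: int,
    gene_starts_sorted: np.ndarray,
    gene_ends_sorted: np.ndarray,
    gene_starts: np.ndarray,
    gene_ends: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Number of genes hit by a CNV of length L at each start (vectorized)."""
    ends = starts + (L - 1)
    if mode == "any":
        # genes with g_start <= end minus genes with g_end < start
        return np.searchsorted(gene_starts_sorted, ends, side="right") - np.searchsorted(
            gene_ends_sorted, starts, side="left"
        )
    counts = np.zeros(starts.shape, dtype=np.int64)
    for gs, ge in zip(gene_starts, gene_ends):
        counts += (starts <= gs) & (ends >= ge)
    return counts


def simulate_null(
    genes: Sequence[MirnaGene],
    cnv_lengths: Sequence[int],
    chrom_length: int,
    config: SimulationConfig,
    chrom: str | None = None,
    cnv_type: str | None = None,
) -> NullDistribution:
    """Monte Carlo histogram of the hits statistic under random placement.

    Deterministic for a fixed ``config.seed``.  With no genes on the
    chromosome every realization yields zero hits.
    """
    for i, L in enumerate(cnv_lengths):
        if L < 1 or L > chrom_length:
            raise ValueError(
                f"CNV #{i}: length {L} outside [1, {chrom_length}] for this chromosome"
            )
    n = config.n_realizations
    rng = np.random.default_rng(config.seed)
    gene_starts = np.asarray([g.start for g in genes], dtype=np.int64)
    gene_ends = np.asarray([g.end for g in genes], dtype=np.int64)
    gene_starts_sorted = np.sort(gene_starts)
    gene_ends_sorted = np.sort(gene_ends)

    if not genes or not cnv_lengths:
        return NullDistribution(
            counts={0: n}, n_realizations=n, source="monte_carlo",
            chrom=chrom, cnv_type=cnv_type, seed=config.seed,
        )

    chunk = max(1, _CHUNK_CELLS // max(1, len(cnv_lengths)))
    histogram: dict[int, int] = {}
    done = 0
    while done < n:
        m = min(chunk, n - done)
        total = np.zeros(m, dtype=np.int64)
        for L in cnv_lengths:
            starts = rng.integers(1, chrom_length - L + 2, size=m)
            total += _hit_counts_for_starts(
                starts, L, gene_starts_sorted, gene_ends_sorted,
                gene_starts, gene_ends, config.overlap_mode,
            )
        values, freq = np.unique(total, return_counts=True)
        for v, f in zip(values.tolist(), freq.tolist()):
            histogram[v] = histogram.get(v, 0) + f
        done += m
    return NullDistribution(
        counts=histogram, n_realizations=n, source="monte_carlo",
        chrom=chrom, cnv_type=cnv_type, seed=config.seed,
    )


def empirical_pvalue(
    null: NullDistribution, observed_hits: int, add_one: bool = False
) -> float:
    """Upper-tail p-value: fraction of null mass at or above the observed hits.

    The plain proportion ``r/N`` is returned by default; ``add_one`` applies
    the ``(r+1)/(N+1)`` correction that guarantees a positive p-value (only
    meaningful for Monte Carlo nulls).
    """
    if observed_hits < 0:
        raise ValueError("observed_hits must be >= 0")
    if null.source == "exact" or not add_one:
        p = null.tail_probability(observed_hits)
        return min(1.0, p)
    r = sum(v for h, v in null.counts.items() if h >= observed_hits)
    return (r + 1) / (null.n_realizations + 1)
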