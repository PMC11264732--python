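"""Read-level candidate ctDNA scoring against discovered regions.

A read is a candidate when it is completely contained in a region and its
read methylation density (methylated CpG calls / total CpG calls) is strictly
above ``hyper_min`` (hyper direction) or strictly below ``hypo_max`` (hypo).
Per-region candidate counts are CPM-normalized by the sample's total mapped
read count; the scalar score is the mean of the per-region CPM values over
all regions (zero-count regions included).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .methylio import GenomicRegion, MethRead

__all__ = [
    "CtCandiScore",
    "rmd",
    "is_candidate",
    "count_candidates",
    "cpm_normalize",
    "score_sample",
]

logger = logging.getLogger(__name__)

HYPER_MIN_RMD = 0.6
HYPO_MAX_RMD = 0.3


@dataclass
class CtCandiScore:
    """Per-region candidate counts for one sample plus the scalar mean."""

    raw_counts: np.ndarray
    cpm: np.ndarray
    total_mapped_reads: int
    sample_id: str = ""

    @property
    def ctcandi(self) -> float:
        """Mean of the per-region CPM values over all regions."""
        return float(self.cpm.mean())


def rmd(read: MethRead, min_calls: int = 1) -> float | None:
    """Read methylation density; None when the read has < ``min_calls`` calls."""
    n = read.n_calls
    if n < max(min_calls, 1):
        return None
    return read.n_methylated / n


def _passes_rmd(
    read: MethRead, direction: str, hyper_min: float, hypo_max: float, min_calls: int
) -> bool:
    density = rmd(read, min_calls)
    if density is None:
        return False
    if direction == "hyper":
        return density > hyper_min
    return density < hypo_max


def is_candidate(
    read: MethRead,
    region: GenomicRegion,
    direction: str = "hyper",
    hyper_min: float = HYPER_MIN_RMD,
    hypo_max: float = HYPO_MAX_RMD,
    min_calls: int = 1,
) -> bool:
    """Containment (region.start <= read.start and read.end <= region.end)
    plus the strict RMD threshold for the given direction."""
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be hyper|hypo, got {direction!r}")
    if read.chrom != region.chrom or not region.contains(read.start, read.end):
        return False
    return _passes_rmd(read, direction, hyper_min, hypo_max, min_calls)


def _check_regions(regions: Sequence[GenomicRegion]) -> dict[str, tuple[list[int], list[int], list[int]]]:
    """Group regions per chromosome; error on overlap; return sorted lookup."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
    lookup = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        for (s1, e1, _), (s2, _, _) in zip(triples, triples[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"regions overlap on {chrom}: ..-{e1} and {s2}-.."
                )
        starts = [t[0] for t in triples]
        ends = [t[1] for t in triples]
        idxs = [t[2] for t in triples]
        lookup[chrom] = (starts, ends, idxs)
    return lookup


def count_candidates(
    reads: Sequence[MethRead],
    regions: Sequence[GenomicRegion],
    direction: str = "hyper",
    hyper_min: float = HYPER_MIN_RMD,
    hypo_max: float = HYPO_MAX_RMD,
    min_calls: int = 1,
) -> np.ndarray:
    """Raw candidate counts per region (aligned with ``regions``).

    Regions must be non-overlapping; a read can therefore be contained in at
    most one region, found by bisection on the region starts.  Each contained
    read with a passing RMD contributes exactly 1 to that region.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be hyper|hypo, got {direction!r}")
    lookup = _check_regions(regions)
    counts = np.zeros(len(regions), dtype=np.int64)
    min_calls = max(min_calls, 1)
    for read in reads:
        if read.n_calls < min_calls:
            continue
        entry = lookup.get(read.chrom)
        if entry is None:
            continue
        starts, ends, idxs = entry
        j = bisect_right(starts, read.start) - 1  # rightmost region starting <= read.start
        if j < 0 or read.end > ends[j]:
            continue
        if _passes_rmd(read, direction, hyper_min, hypo_max, min_calls):
            counts[idxs[j]] += 1
    return counts


def cpm_normalize(raw_count, total_mapped_reads: int):
    """counts per million mapped reads: raw * 1e6 / total."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return np.asarray(raw_count, dtype=float) * 1e6 / total_mapped_reads


def score_sample(
    reads: Sequence[MethRead],
    regions: Sequence[GenomicRegion],
    total_mapped_reads: int | None = None,
    direction: str = "hyper",
    hyper_min: float = HYPER_MIN_RMD,
    hypo_max: float = HYPO_MAX_RMD,
    min_calls: int = 1,
    sample_id: str = "",
) -> CtCandiScore:
    """Score one sample's reads: per-region CPM counts and their mean.

    ``total_mapped_reads`` defaults to ``len(reads)`` when not supplied from
    sample metadata; the value used is logged.
    """
    if len(regions) == 0:
        raise ValueError("region list must be non-empty")
    if total_mapped_reads is None:
        total_mapped_reads = len(reads)
        logger.info(
            "sample %s: total_mapped_reads not supplied, using len(reads)=%d",
            sample_id, total_mapped_reads,
        )
    read_len_max = max((r.end - r.start + 1 for r in reads), default=0)
    n_short = sum(1 for r in regions if r.end - r.start + 1 < read_len_max)
    if n_short:
        logger.debug(
            "%d/%d regions are shorter than the longest read (%d bp) and can "
            "only collect shorter fragments", n_short, len(regions), read_len_max,
        )
    raw = count_candidates(reads, regions, direction, hyper_min, hypo_max, min_calls)
    cpm = cpm_normalize(raw, total_mapped_reads)
    return CtCandiScore(raw, cpm, total_mapped_reads, sample_id)
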