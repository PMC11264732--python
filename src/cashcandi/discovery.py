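"""Differential CpG calling and merging into candidate regions.

The pipeline: per-CpG beta values from strand-collapsed counts -> missingness
filter -> per-CpG two-sided rank-sum test (tumor vs normal tissue) with
Benjamini-Hochberg adjustment -> beta-threshold filters (effect size and a
healthy-plasma background cap) -> merge surviving CpGs within ``2 * flank``
bp into fragments -> drop fragments with fewer than ``min_cpgs`` members ->
the span from the first to the last member CpG is the final region.

Hypermethylated ("hyper") discovery keeps CpGs with
``mean beta_tumor - mean beta_normal > delta_min`` and
``mean beta_plasma < plasma_thresh``; "hypo" mirrors both conditions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylio import GenomicRegion

__all__ = [
    "DiscoveryParams",
    "BetaMatrix",
    "CaSHRegion",
    "DiscoveryResult",
    "compute_beta",
    "build_beta_matrix",
    "missingness_filter",
    "rank_sum_test",
    "bh_fdr",
    "call_differential_cpgs",
    "merge_to_fragments",
    "filter_fragments",
    "finalize_regions",
    "discover",
    "evaluate_recovery",
]

logger = logging.getLogger(__name__)

GROUP_TUMOR = "tumor_tissue"
GROUP_NORMAL = "normal_tissue"
GROUP_PLASMA = "healthy_plasma"
DISCOVERY_GROUPS = (GROUP_TUMOR, GROUP_NORMAL, GROUP_PLASMA)


@dataclass(frozen=True)
class DiscoveryParams:
    """All thresholds of the discovery pipeline (defaults as published)."""

    direction: str = "hyper"
    delta_min: float = 0.3
    plasma_thresh: float | None = None  # None -> 0.05 (hyper) / 0.95 (hypo)
    fdr_max: float = 0.05
    flank: int = 75
    min_cpgs: int = 10
    min_coverage: int = 5
    max_missing_frac: float = 0.5
    plasma_mode: str = "mean"  # "mean" or "all" (every sample must pass)

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper|hypo, got {self.direction!r}")
        if self.plasma_mode not in ("mean", "all"):
            raise ValueError(f"plasma_mode must be mean|all, got {self.plasma_mode!r}")

    @property
    def resolved_plasma_thresh(self) -> float:
        if self.plasma_thresh is not None:
            return self.plasma_thresh
        return 0.05 if self.direction == "hyper" else 0.95


@dataclass
class BetaMatrix:
    """CpG x sample beta values plus a sample -> group mapping.

    ``beta`` is indexed by a ``(chrom, pos)`` MultiIndex, one column per
    sample, NaN for missing (coverage below the floor).
    """

    beta: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self):
        missing = [s for s in self.beta.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("beta values must lie in [0, 1]")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.beta.columns if self.groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        cols = self.samples_of(group)
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return self.beta[cols]


@dataclass(frozen=True)
class CaSHRegion:
    """A merged differential region spanning its first to last member CpG."""

    chrom: str
    start: int
    end: int
    members: tuple[int, ...]
    direction: str = "hyper"

    def __post_init__(self):
        if not self.members:
            raise ValueError("region needs at least one member CpG")
        if self.start != self.members[0] or self.end != self.members[-1]:
            raise ValueError("region boundaries must equal first/last member CpG")

    @property
    def n_cpgs(self) -> int:
        return len(self.members)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# beta computation and filtering
# ---------------------------------------------------------------------------


def compute_beta(meth, unmeth, min_coverage: int = 5):
    """beta = m / (m + u) where coverage >= min_coverage, else NaN.

    Accepts scalars or numpy arrays.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("counts must be non-negative")
    total = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total >= max(min_coverage, 1), meth / total, np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def build_beta_matrix(
    count_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    min_coverage: int = 5,
) -> BetaMatrix:
    """Outer-join per-sample strand-collapsed count tables into a BetaMatrix.

    ``count_tables`` maps sample id -> DataFrame with columns
    ``chrom, pos, meth, unmeth`` (already strand-collapsed).
    """
    cols = {}
    for sample, table in count_tables.items():
        beta = compute_beta(
            table["meth"].to_numpy(), table["unmeth"].to_numpy(), min_coverage
        )
        idx = pd.MultiIndex.from_arrays(
            [table["chrom"], table["pos"]], names=["chrom", "pos"]
        )
        cols[sample] = pd.Series(beta, index=idx)
    beta = pd.DataFrame(cols).sort_index()
    return BetaMatrix(beta, dict(groups))


def missingness_filter(matrix: BetaMatrix, max_missing_frac: float = 0.5) -> BetaMatrix:
    """Drop CpG rows missing in more than ``max_missing_frac`` of any group.

    The fraction is evaluated separately within every discovery group present
    (tumor, normal, healthy plasma); "more than" is strict, so a row missing
    in exactly half of a group is kept.
    """
    present = [g for g in DISCOVERY_GROUPS if matrix.samples_of(g)]
    if not present:
        raise ValueError("matrix contains no discovery-group samples")
    keep = pd.Series(True, index=matrix.beta.index)
    for group in present:
        sub = matrix.group_values(group)
        frac = sub.isna().sum(axis=1) / sub.shape[1]
        keep &= frac <= max_missing_frac
    return BetaMatrix(matrix.beta.loc[keep], dict(matrix.groups))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 12


@lru_cache(maxsize=64)
def _exact_u_null(n1: int, n2: int) -> np.ndarray:
    """Null counts of the rank-sum U statistic over all C(n1+n2, n1) splits."""
    n = n1 + n2
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    base = n1 * (n1 + 1) // 2
    for combo in itertools.combinations(range(1, n + 1), n1):
        counts[sum(combo) - base] += 1
    return counts


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when ``n1 + n2 <= 12`` and the pooled values carry no
    ties; otherwise the normal approximation with tie and continuity
    correction.  Degenerate pooled samples (all values identical) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n1, n2 = x.size, y.size
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= _EXACT_MAX_N and not has_ties:
        ranks = stats.rankdata(pooled)
        u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        null = _exact_u_null(n1, n2)
        mu = n1 * n2 / 2
        dev = abs(u1 - mu)
        us = np.arange(null.size)
        p = null[np.abs(us - mu) >= dev - 1e-9].sum() / null.sum()
        return float(p)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return float(min(1.0, res.pvalue))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# differential CpG calling
# ---------------------------------------------------------------------------


def call_differential_cpgs(
    matrix: BetaMatrix, params: DiscoveryParams
) -> pd.DataFrame:
    """Per-CpG differential test plus beta-threshold filters.

    BH adjustment runs over *all* rows of the (already missingness-filtered)
    matrix, before the beta filters, so q-values do not depend on the plasma
    filter.  Returns the retained CpGs as a DataFrame with columns
    ``chrom, pos, delta_beta, plasma_beta, p_value, q_value, direction``.
    """
    for group in (GROUP_TUMOR, GROUP_NORMAL, GROUP_PLASMA):
        if not matrix.samples_of(group):
            raise ValueError(f"required group {group!r} has no samples")
    tumor = matrix.group_values(GROUP_TUMOR).to_numpy(dtype=float)
    normal = matrix.group_values(GROUP_NORMAL).to_numpy(dtype=float)
    plasma = matrix.group_values(GROUP_PLASMA).to_numpy(dtype=float)

    n_rows = tumor.shape[0]
    p_values = np.ones(n_rows)
    for i in range(n_rows):
        t = tumor[i][~np.isnan(tumor[i])]
        n = normal[i][~np.isnan(normal[i])]
        if t.size == 0 or n.size == 0:
            p_values[i] = 1.0
            continue
        p_values[i] = rank_sum_test(t, n)
    q_values = bh_fdr(p_values)

    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(tumor, axis=1)
        mean_n = np.nanmean(normal, axis=1)
        mean_p = np.nanmean(plasma, axis=1)

    if params.direction == "hyper":
        delta = mean_t - mean_n
    else:
        delta = mean_n - mean_t
    thresh = params.resolved_plasma_thresh
    if params.plasma_mode == "mean":
        plasma_ok = (
            mean_p < thresh if params.direction == "hyper" else mean_p > thresh
        )
    else:  # every non-missing plasma sample must pass
        if params.direction == "hyper":
            plasma_ok = np.nanmax(np.where(np.isnan(plasma), -np.inf, plasma), axis=1) < thresh
        else:
            plasma_ok = np.nanmin(np.where(np.isnan(plasma), np.inf, plasma), axis=1) > thresh

    keep = (delta > params.delta_min) & plasma_ok & (q_values < params.fdr_max)
    keep &= ~np.isnan(delta) & ~np.isnan(mean_p)

    idx = matrix.beta.index
    out = pd.DataFrame(
        {
            "chrom": idx.get_level_values("chrom"),
            "pos": idx.get_level_values("pos"),
            "delta_beta": delta,
            "plasma_beta": mean_p,
            "p_value": p_values,
            "q_value": q_values,
            "direction": params.direction,
        }
    )
    out = out.loc[keep].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# merging into regions
# ---------------------------------------------------------------------------


def merge_to_fragments(positions: Sequence[int], flank: int = 75) -> list[list[int]]:
    """Chain sorted CpG positions whose +/- ``flank`` expansions overlap.

    Equivalently, consecutive CpGs with a gap <= ``2 * flank`` join one
    fragment (touching closed intervals chain, so a gap of exactly
    ``2 * flank`` merges).  Positions must be strictly increasing.
    """
    pos = list(positions)
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("positions must be strictly increasing")
    if not pos:
        return []
    fragments = [[pos[0]]]
    for p in pos[1:]:
        if p - fragments[-1][-1] <= 2 * flank:
            fragments[-1].append(p)
        else:
            fragments.append([p])
    return fragments


def filter_fragments(
    fragments: Iterable[Sequence[int]], min_cpgs: int = 10
) -> list[list[int]]:
    """Keep fragments with at least ``min_cpgs`` member CpGs."""
    return [list(f) for f in fragments if len(f) >= min_cpgs]


def finalize_regions(
    fragments_by_chrom: Mapping[str, Iterable[Sequence[int]]],
    direction: str = "hyper",
) -> list[CaSHRegion]:
    """First/last member CpG of each fragment become the region boundaries."""
    regions = []
    for chrom in sorted(fragments_by_chrom):
        for frag in fragments_by_chrom[chrom]:
            members = tuple(frag)
            regions.append(
                CaSHRegion(chrom, members[0], members[-1], members, direction)
            )
    return regions


@dataclass
class DiscoveryResult:
    regions: list[CaSHRegion]
    differential_cpgs: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def discover(
    tumor_counts: Mapping[str, pd.DataFrame],
    normal_counts: Mapping[str, pd.DataFrame],
    plasma_counts: Mapping[str, pd.DataFrame],
    params: DiscoveryParams = DiscoveryParams(),
) -> DiscoveryResult:
    """Full discovery pipeline from strand-collapsed count tables to regions."""
    if not tumor_counts or not normal_counts or not plasma_counts:
        raise ValueError("tumor, normal and plasma groups must be non-empty")
    groups = {}
    tables = {}
    for mapping, group in (
        (tumor_counts, GROUP_TUMOR),
        (normal_counts, GROUP_NORMAL),
        (plasma_counts, GROUP_PLASMA),
    ):
        for sample, table in mapping.items():
            if sample in tables:
                raise ValueError(f"duplicate sample id {sample!r}")
            tables[sample] = table
            groups[sample] = group

    matrix = build_beta_matrix(tables, groups, params.min_coverage)
    n_sites = matrix.beta.shape[0]
    matrix = missingness_filter(matrix, params.max_missing_frac)
    n_covered = matrix.beta.shape[0]

    diff = call_differential_cpgs(matrix, params)
    n_diff = len(diff)

    fragments_by_chrom: dict[str, list[list[int]]] = {}
    n_fragments = 0
    n_filtered = 0
    for chrom, sub in diff.groupby("chrom", sort=True):
        frags = merge_to_fragments(sub["pos"].tolist(), params.flank)
        n_fragments += len(frags)
        kept = filter_fragments(frags, params.min_cpgs)
        n_filtered += len(kept)
        if kept:
            fragments_by_chrom[str(chrom)] = kept
    regions = finalize_regions(fragments_by_chrom, params.direction)

    stage_counts = {
        "cpgs_total": n_sites,
        "cpgs_after_missingness": n_covered,
        "differential_cpgs": n_diff,
        "fragments": n_fragments,
        "fragments_after_min_cpgs": n_filtered,
        "regions": len(regions),
    }
    logger.info(
        "discovery (%s): %d CpGs -> %d covered -> %d differential -> "
        "%d fragments -> %d with >=%d CpGs -> %d regions",
        params.direction, n_sites, n_covered, n_diff, n_fragments,
        n_filtered, params.min_cpgs, len(regions),
    )
    return DiscoveryResult(regions, diff, stage_counts)


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------


def _reciprocal_overlap(a: GenomicRegion, b: GenomicRegion) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def evaluate_recovery(
    discovered: Sequence[CaSHRegion],
    truth: Sequence[GenomicRegion],
    min_reciprocal: float = 0.5,
) -> dict[str, int]:
    """Match discovered regions to planted truth by reciprocal overlap.

    A truth region is *recovered* when some discovered region overlaps it
    reciprocally by at least ``min_reciprocal``; a discovered region with no
    such match is counted as *outside*.
    """
    recovered = 0
    for t in truth:
        if any(_reciprocal_overlap(d.region, t) >= min_reciprocal for d in discovered):
            recovered += 1
    outside = 0
    for d in discovered:
        if not any(_reciprocal_overlap(d.region, t) >= min_reciprocal for t in truth):
            outside += 1
    return {"n_truth": len(truth), "recovered": recovered, "outside": outside}
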