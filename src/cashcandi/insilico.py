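"""In-silico dilution: mix tumor reads into healthy plasma reads at known
fractions and test the score's dose-response.

Mixing *replaces* plasma reads (output size equals the plasma input size), so
the CPM denominator is constant across a dilution series and score
differences reflect read composition only.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ctcandi import score_sample
from .methylio import GenomicRegion, MethRead

__all__ = [
    "downsample_reads",
    "mix_reads",
    "dilution_series",
    "spearman",
    "DEFAULT_FRACTIONS",
]

#: printed range 0.1%..5%; interior points are this artifact's choice
DEFAULT_FRACTIONS = (0.001, 0.005, 0.01, 0.02, 0.03, 0.05)


def downsample_reads(
    reads: Sequence[MethRead], target_count: int, seed: int
) -> list[MethRead]:
    """Uniform sample of ``target_count`` reads without replacement."""
    if target_count > len(reads):
        raise ValueError(
            f"target_count {target_count} exceeds available reads {len(reads)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=target_count, replace=False)
    return [reads[i] for i in idx]


def mix_reads(
    plasma_reads: Sequence[MethRead],
    tumor_reads: Sequence[MethRead],
    fraction: float,
    seed: int,
) -> list[MethRead]:
    """Replace ``round(fraction * N)`` uniformly chosen plasma reads with the
    same number of uniformly chosen tumor reads; output size stays ``N``."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n = len(plasma_reads)
    n_tumor = round(fraction * n)
    if n_tumor > len(tumor_reads):
        raise ValueError(
            f"need {n_tumor} tumor reads but only {len(tumor_reads)} available"
        )
    rng = np.random.default_rng(seed)
    if n_tumor == 0:
        return list(plasma_reads)
    drop = rng.choice(n, size=n_tumor, replace=False)
    take = rng.choice(len(tumor_reads), size=n_tumor, replace=False)
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[drop] = False
    mixed = [plasma_reads[i] for i in np.nonzero(keep_mask)[0]]
    mixed.extend(tumor_reads[j] for j in take)
    return mixed


def dilution_series(
    plasma_reads: Sequence[MethRead],
    tumor_reads: Sequence[MethRead],
    regions: Sequence[GenomicRegion],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_reps: int = 6,
    base_seed: int = 0,
    direction: str = "hyper",
) -> pd.DataFrame:
    """One score per (fraction, replicate); seed = base_seed + running index.

    Total mapped reads is ``len(plasma_reads)`` for every point (replacement
    mixing keeps it constant).
    """
    rows = []
    n_total = len(plasma_reads)
    for index, (fraction, rep) in enumerate(
        itertools.product(fractions, range(n_reps))
    ):
        seed = base_seed + index
        mixed = mix_reads(plasma_reads, tumor_reads, fraction, seed)
        score = score_sample(
            mixed, regions, total_mapped_reads=n_total, direction=direction,
            sample_id=f"mix_f{fraction}_r{rep}",
        )
        rows.append(
            {
                "tumor_fraction": fraction,
                "replicate": rep,
                "seed": seed,
                "ctcandi": score.ctcandi,
                "n_total_reads": n_total,
                "n_tumor_reads": round(fraction * n_total),
            }
        )
    return pd.DataFrame(rows)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return 0.0
    return float(rx @ ry) / denom


def spearman(x, y) -> tuple[float, float]:
    """Average-rank Spearman correlation.

    p-value by exact permutation for n <= 8, otherwise the t approximation
    with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
        rp = ry[perms]  # all permuted rank vectors
        rxc = rx - rx.mean()
        rpc = rp - rp.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc @ rxc) * (rpc * rpc).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = np.where(denom > 0, (rpc @ rxc) / denom, 0.0)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)
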