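"""Synthetic fixture generator: toy genomes, group methylation profiles, and
read sets with the statistical structure the scoring method assumes.

The model is deliberately simple: a beta-binomial per site with a single
symmetric conversion-error rate epsilon.  Planted regions carry the
discovery-grade contrast by construction (tumor-tissue mean beta 0.90 vs
0.02 in normal tissue and healthy plasma for the hyper direction, mirrored
for hypo); background sites share one low-level beta law across groups.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .insilico import mix_reads
from .methylio import GenomicRegion, MethRead

__all__ = [
    "GeneratorConfig",
    "PlantedRegion",
    "TruthTable",
    "Genome",
    "Profile",
    "PlasmaSample",
    "CohortData",
    "make_genome",
    "make_profiles",
    "emit_counts",
    "emit_reads",
    "make_cohort",
]


BetaLaw = tuple[float, float]  # (mean, concentration)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    # background CpG placement: islands scattered at `island_rate` per bp,
    # each with ~`island_mean_cpgs` CpGs spaced `island_spacing` bp apart
    island_rate: float = 8e-5
    island_mean_cpgs: float = 8.0
    island_spacing: int = 35
    # planted differential regions
    n_planted_regions: int = 50
    planted_cpgs: int = 16
    planted_span: int = 460
    min_region_separation: int = 2000
    # beta laws (mean, concentration); None resolves by direction
    direction: str = "hyper"
    tumor_planted: BetaLaw | None = None
    normal_planted: BetaLaw | None = None
    plasma_planted: BetaLaw | None = None
    background: BetaLaw = (0.05, 20.0)
    conversion_error: float = 0.005
    read_length: int = 150
    coverage: float = 30.0
    n_tissue_per_group: int = 5
    tumor_fraction_law: tuple = ("uniform", 0.005, 0.05)

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be hyper|hypo")
        if not 0 <= self.conversion_error <= 1:
            raise ValueError("conversion_error must lie in [0, 1]")
        if self.planted_cpgs < 10:
            raise ValueError("planted regions need >= 10 CpGs")
        if self.planted_span > 500:
            raise ValueError("planted span must be <= 500 bp")

    def law(self, group: str, planted: bool) -> BetaLaw:
        """Resolve the beta law for a group/stratum pair."""
        if not planted:
            return self.background
        hyper = self.direction == "hyper"
        defaults = {
            "tumor_tissue": (0.90, 50.0) if hyper else (0.02, 50.0),
            "normal_tissue": (0.02, 50.0) if hyper else (0.90, 50.0),
            "healthy_plasma": (0.02, 50.0) if hyper else (0.98, 50.0),
        }
        override = {
            "tumor_tissue": self.tumor_planted,
            "normal_tissue": self.normal_planted,
            "healthy_plasma": self.plasma_planted,
        }[group]
        return override if override is not None else defaults[group]


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int  # first member CpG
    end: int    # last member CpG
    members: tuple[int, ...]

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end)


@dataclass
class TruthTable:
    """Ground truth for a generated dataset; immutable once written."""

    direction: str
    regions: list[PlantedRegion]
    sample_fractions: dict[str, float] = field(default_factory=dict)

    def to_files(self, bed_path: str, tsv_path: str) -> None:
        with open(bed_path, "w") as fh:
            for r in self.regions:
                members = ",".join(map(str, r.members))
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{members}\n")
        with open(tsv_path, "w") as fh:
            fh.write(f"#direction\t{self.direction}\n")
            fh.write("sample_id\ttumor_fraction\n")
            for sid, f in self.sample_fractions.items():
                fh.write(f"{sid}\t{f!r}\n")

    @classmethod
    def from_files(cls, bed_path: str, tsv_path: str) -> "TruthTable":
        regions = []
        with open(bed_path) as fh:
            for line in fh:
                chrom, s0, e, members_s = line.rstrip("\n").split("\t")
                members = tuple(int(m) for m in members_s.split(","))
                regions.append(PlantedRegion(chrom, int(s0) + 1, int(e), members))
        fractions = {}
        direction = "hyper"
        with open(tsv_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#direction"):
                    direction = line.split("\t")[1]
                    continue
                if line.startswith("sample_id") or not line:
                    continue
                sid, f = line.split("\t")
                fractions[sid] = float(f)
        return cls(direction, regions, fractions)


@dataclass
class Genome:
    """CpG position map plus the planted-region truth skeleton."""

    config: GeneratorConfig
    positions: dict[str, np.ndarray]          # strictly increasing per chrom
    planted_mask: dict[str, np.ndarray]       # bool, aligned with positions
    truth: TruthTable

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class Profile:
    """Per-sample true methylation level m at every CpG."""

    sample_id: str
    group: str
    levels: dict[str, np.ndarray]  # chrom -> m aligned with genome positions


def _rng(config: GeneratorConfig, *stream) -> np.random.Generator:
    """Deterministic child generator for a named stream."""
    tokens = [config.seed] + [
        t if isinstance(t, int) else int.from_bytes(str(t).encode(), "little") % (2**32)
        for t in stream
    ]
    return np.random.default_rng(tokens)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def make_genome(config: GeneratorConfig) -> Genome:
    """Place planted regions and background CpG islands on a toy genome.

    Raises when the requested number of planted regions cannot satisfy the
    pairwise separation constraint.
    """
    rng = _rng(config, "genome")
    k = config.n_planted_regions
    per_chrom = [k // config.n_chrom + (1 if c < k % config.n_chrom else 0)
                 for c in range(config.n_chrom)]
    positions: dict[str, np.ndarray] = {}
    planted_mask: dict[str, np.ndarray] = {}
    regions: list[PlantedRegion] = []

    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        length = config.chrom_length
        k_c = per_chrom[c]
        planted_positions: list[int] = []
        if k_c:
            step = length // (k_c + 1)
            if step < config.planted_span + config.min_region_separation:
                raise ValueError(
                    f"cannot place {k_c} regions of span {config.planted_span} "
                    f"with separation {config.min_region_separation} on a "
                    f"{length} bp chromosome"
                )
            jitter_max = max(1, (step - config.planted_span
                                 - config.min_region_separation) // 2)
            for i in range(k_c):
                anchor = (i + 1) * step - config.planted_span // 2
                anchor += int(rng.integers(-jitter_max, jitter_max + 1))
                members = _planted_members(rng, anchor, config)
                regions.append(
                    PlantedRegion(chrom, members[0], members[-1], tuple(members))
                )
                planted_positions.extend(members)

        background = _background_positions(rng, length, config)
        if planted_positions:
            # keep background CpGs away from planted spans so region truth is clean
            keep = np.ones(background.size, dtype=bool)
            for r in regions:
                if r.chrom != chrom:
                    continue
                keep &= ~((background >= r.start - 200) & (background <= r.end + 200))
            background = background[keep]
        merged = np.concatenate([background, np.asarray(planted_positions, dtype=np.int64)])
        is_planted = np.concatenate(
            [np.zeros(background.size, dtype=bool),
             np.ones(len(planted_positions), dtype=bool)]
        )
        order = np.argsort(merged, kind="mergesort")
        positions[chrom] = merged[order]
        planted_mask[chrom] = is_planted[order]
        if merged.size and np.any(np.diff(positions[chrom]) < 2):
            raise AssertionError("CpG positions closer than 2 bp")

    truth = TruthTable(config.direction, regions)
    return Genome(config, positions, planted_mask, truth)


def _planted_members(rng: np.random.Generator, anchor: int, config: GeneratorConfig) -> list[int]:
    n = config.planted_cpgs
    base = np.linspace(0, config.planted_span, n)
    jitter = rng.integers(-5, 6, size=n)
    pos = np.sort(np.round(base).astype(np.int64) + jitter) + anchor
    # enforce a minimum 2 bp gap (CpG dinucleotides cannot overlap)
    for i in range(1, n):
        if pos[i] < pos[i - 1] + 2:
            pos[i] = pos[i - 1] + 2
    return [int(p) for p in pos]


def _background_positions(
    rng: np.random.Generator, length: int, config: GeneratorConfig
) -> np.ndarray:
    n_islands = rng.poisson(config.island_rate * length)
    out: list[np.ndarray] = []
    starts = np.sort(rng.integers(2, max(3, length - 1000), size=n_islands))
    for s in starts:
        size = 1 + rng.poisson(max(config.island_mean_cpgs - 1, 0))
        gaps = config.island_spacing + rng.integers(-10, 11, size=size)
        gaps = np.maximum(gaps, 2)
        pos = s + np.concatenate([[0], np.cumsum(gaps[:-1])])
        out.append(pos)
    if not out:
        return np.empty(0, dtype=np.int64)
    merged = np.unique(np.concatenate(out))
    merged = merged[(merged >= 2) & (merged <= length - 1)]
    if merged.size:
        keep = np.concatenate([[True], np.diff(merged) >= 2])
        merged = merged[keep]
    return merged.astype(np.int64)


# ---------------------------------------------------------------------------
# methylation profiles and observable data
# ---------------------------------------------------------------------------


def _beta_draw(rng: np.random.Generator, law: BetaLaw, size: int) -> np.ndarray:
    mean, conc = law
    if mean <= 0 or mean >= 1:
        return np.full(size, float(mean))
    a = mean * conc
    b = (1 - mean) * conc
    return rng.beta(a, b, size=size)


def make_profiles(
    genome: Genome,
    group: str,
    n_samples: int,
    sample_prefix: str | None = None,
) -> list[Profile]:
    """Independent per-sample, per-site methylation levels for one group."""
    if group not in ("tumor_tissue", "normal_tissue", "healthy_plasma"):
        raise ValueError(f"unknown group {group!r}")
    config = genome.config
    prefix = sample_prefix or group
    profiles = []
    for i in range(n_samples):
        rng = _rng(config, "profile", group, i)
        levels = {}
        for chrom, pos in genome.positions.items():
            mask = genome.planted_mask[chrom]
            m = _beta_draw(rng, config.law(group, planted=False), pos.size)
            n_planted = int(mask.sum())
            if n_planted:
                m[mask] = _beta_draw(rng, config.law(group, planted=True), n_planted)
            levels[chrom] = m
        profiles.append(Profile(f"{prefix}_{i}", group, levels))
    return profiles


def effective_methylation(m, epsilon: float):
    """Observable call probability under symmetric conversion error."""
    m = np.asarray(m, dtype=float)
    return m * (1 - epsilon) + (1 - m) * epsilon


def emit_counts(
    profile: Profile,
    genome: Genome,
    coverage: float | None = None,
    seed_tag: str = "counts",
) -> pd.DataFrame:
    """Strand-collapsed cytosine count table: depth ~ Poisson(coverage),
    methylated ~ Binomial(depth, effective m)."""
    config = genome.config
    cov = config.coverage if coverage is None else coverage
    if cov <= 0:
        raise ValueError("coverage must be positive")
    rng = _rng(config, seed_tag, profile.group, profile.sample_id)
    frames = []
    for chrom, pos in genome.positions.items():
        m_eff = effective_methylation(profile.levels[chrom], config.conversion_error)
        depth = rng.poisson(cov, size=pos.size)
        meth = rng.binomial(depth, m_eff)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "meth": meth, "unmeth": depth - meth}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.attrs["sample_id"] = profile.sample_id
    return table


def emit_reads(
    profile: Profile,
    genome: Genome,
    coverage: float | None = None,
    seed_tag: str = "reads",
) -> list[MethRead]:
    """Fixed-length single-end reads with uniform starts; per-spanned-CpG
    Bernoulli(effective m) methylation calls."""
    config = genome.config
    cov = config.coverage if coverage is None else coverage
    if cov <= 0:
        raise ValueError("coverage must be positive")
    rl = config.read_length
    rng = _rng(config, seed_tag, profile.group, profile.sample_id)
    reads: list[MethRead] = []
    sid = profile.sample_id
    for chrom, pos in genome.positions.items():
        length = config.chrom_length
        n_reads = int(round(cov * length / rl))
        starts = np.sort(rng.integers(1, length - rl + 2, size=n_reads))
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + rl - 1, side="right")
        counts = hi - lo
        total = int(counts.sum())
        # flat index of every (read, covered CpG) pair
        flat = (
            np.arange(total)
            - np.repeat(np.cumsum(counts) - counts, counts)
            + np.repeat(lo, counts)
        )
        m_eff = effective_methylation(profile.levels[chrom], config.conversion_error)
        calls_flat = (rng.random(total) < m_eff[flat]).tolist()
        pos_flat = pos[flat].tolist()
        starts_l = starts.tolist()
        counts_l = counts.tolist()
        cursor = 0
        for j in range(n_reads):
            c = counts_l[j]
            s = starts_l[j]
            if c:
                calls = tuple(
                    zip(pos_flat[cursor:cursor + c], calls_flat[cursor:cursor + c])
                )
                cursor += c
            else:
                calls = ()
            reads.append(MethRead(chrom, s, s + rl - 1, sid, calls))
    return reads


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class PlasmaSample:
    sample_id: str
    label: str  # "case" | "control"
    tumor_fraction: float
    reads: list[MethRead]

    @property
    def n_total(self) -> int:
        return len(self.reads)


@dataclass
class CohortData:
    """A full synthetic study: tissue count tables for discovery, plasma read
    sets for scoring (generated lazily, one sample at a time), and truth."""

    config: GeneratorConfig
    genome: Genome
    truth: TruthTable
    tissue_counts: dict[str, dict[str, pd.DataFrame]]
    sample_table: pd.DataFrame  # sample_id, label, tumor_fraction

    def iter_plasma_samples(self) -> Iterator[PlasmaSample]:
        """Yield plasma samples in sample_table order; cases are healthy-plasma
        reads with tumor-pool reads mixed in at the sample's true fraction."""
        config = self.config
        tumor_pool: list[MethRead] | None = None
        for rec in self.sample_table.itertuples(index=False):
            profile = make_profiles(
                self.genome, "healthy_plasma", 1, sample_prefix=rec.sample_id
            )[0]
            reads = emit_reads(profile, self.genome)
            if rec.label == "case" and rec.tumor_fraction > 0:
                if tumor_pool is None:
                    tumor_pool = self._tumor_pool()
                mix_seed = int(
                    _rng(config, "mixseed", rec.sample_id).integers(0, 2**31)
                )
                reads = mix_reads(reads, tumor_pool, rec.tumor_fraction, mix_seed)
            yield PlasmaSample(rec.sample_id, rec.label, rec.tumor_fraction, reads)

    def _tumor_pool(self) -> list[MethRead]:
        profile = make_profiles(self.genome, "tumor_tissue", 1, sample_prefix="tumor_pool")[0]
        return emit_reads(profile, self.genome)


def _draw_fractions(law, n: int, rng: np.random.Generator) -> np.ndarray:
    if callable(law):
        return np.asarray(law(rng, n), dtype=float)
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=n)
    if kind == "constant":
        return np.full(n, float(law[1]))
    raise ValueError(f"unknown tumor fraction law {law!r}")


def make_cohort(
    config: GeneratorConfig,
    n_cases: int = 49,
    n_controls: int = 60,
    tumor_fraction_law=None,
) -> CohortData:
    """Build a synthetic study: a tissue discovery cohort (count tables for
    tumor/normal/healthy-plasma groups) plus case/control plasma samples whose
    true tumor fractions are recorded in the truth table."""
    genome = make_genome(config)
    law = tumor_fraction_law if tumor_fraction_law is not None else config.tumor_fraction_law

    tissue_counts: dict[str, dict[str, pd.DataFrame]] = {}
    for group in ("tumor_tissue", "normal_tissue", "healthy_plasma"):
        profiles = make_profiles(genome, group, config.n_tissue_per_group)
        tissue_counts[group] = {
            p.sample_id: emit_counts(p, genome) for p in profiles
        }

    rng = _rng(config, "fractions")
    fractions = _draw_fractions(law, n_cases, rng)
    rows = []
    for i in range(n_cases):
        rows.append((f"case_{i}", "case", float(fractions[i])))
    for i in range(n_controls):
        rows.append((f"control_{i}", "control", 0.0))
    sample_table = pd.DataFrame(rows, columns=["sample_id", "label", "tumor_fraction"])

    truth = TruthTable(
        config.direction,
        genome.truth.regions,
        {r.sample_id: r.tumor_fraction for r in sample_table.itertuples(index=False)},
    )
    return CohortData(config, genome, truth, tissue_counts, sample_table)
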