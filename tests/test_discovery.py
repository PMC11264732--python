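import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cashcandi import discovery as dc
from cashcandi import synthdata as sd


def matrix_from_dict(data, groups):
    """data: {(chrom,pos): {sample: beta}}"""
    beta = pd.DataFrame.from_dict(data, orient="index")
    beta.index = pd.MultiIndex.from_tuples(beta.index, names=["chrom", "pos"])
    return dc.BetaMatrix(beta.sort_index(), groups)


class TestComputeBeta:
    def test_simple_ratio(self):
        assert dc.compute_beta(3, 7, min_coverage=1) == pytest.approx(0.3)

    def test_zero_coverage_missing(self):
        assert math.isnan(dc.compute_beta(0, 0, min_coverage=1))

    def test_below_coverage_floor(self):
        assert math.isnan(dc.compute_beta(4, 0, min_coverage=5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dc.compute_beta(-1, 3, 1)


class TestMissingnessFilter:
    def make(self, tumor_missing, n_tumor=5):
        groups = {f"t{i}": "tumor_tissue" for i in range(n_tumor)}
        groups.update({"n0": "normal_tissue", "n1": "normal_tissue"})
        row = {f"t{i}": (np.nan if i < tumor_missing else 0.5) for i in range(n_tumor)}
        row.update({"n0": 0.5, "n1": 0.5})
        return matrix_from_dict({("chr1", 10): row}, groups)

    def test_more_than_half_removed(self):
        out = dc.missingness_filter(self.make(tumor_missing=3, n_tumor=5))
        assert out.beta.shape[0] == 0

    def test_exactly_half_kept(self):
        out = dc.missingness_filter(self.make(tumor_missing=2, n_tumor=4))
        assert out.beta.shape[0] == 1

    def test_fully_observed_identity(self):
        m = self.make(tumor_missing=0)
        out = dc.missingness_filter(m)
        assert out.beta.equals(m.beta)

    def test_no_discovery_groups_errors(self):
        m = matrix_from_dict({("chr1", 1): {"s": 0.1}}, {"s": "case_plasma"})
        with pytest.raises(ValueError):
            dc.missingness_filter(m)


def oracle_rank_sum_p(x, y):
    """Independent enumeration oracle: count pairwise wins over all splits of
    the pooled values; two-sided p from the deviation of the win count."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def wins(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    obs = abs(wins(x, y) - n1 * (len(y)) / 2)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(wins(xs, ys) - n1 * len(ys) / 2) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_fully_separated_exact(self):
        x = [0.9, 0.91, 0.92, 0.93, 0.94]
        y = [0.1, 0.11, 0.12, 0.13, 0.14]
        assert dc.rank_sum_test(x, y) == pytest.approx(2 / 252)

    def test_identical_multisets(self):
        assert dc.rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            dc.rank_sum_test([], [1.0])

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.normal(), size=n2)
            assert dc.rank_sum_test(x, y) == pytest.approx(
                oracle_rank_sum_p(x.tolist(), y.tolist())
            )

    def test_asymptotic_close_to_monte_carlo(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1, size=20)
        y = rng.normal(0.7, 1, size=20)
        p = dc.rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(
            sum((a > b) + 0.5 * (a == b) for a in x for b in y) - 200
        )
        hits = 0
        n_mc = 4000
        for _ in range(n_mc):
            perm = rng.permutation(pooled)
            u = sum(
                (a > b) + 0.5 * (a == b) for a in perm[:20] for b in perm[20:]
            )
            hits += abs(u - 200) >= obs - 1e-9
        p_mc = hits / n_mc
        assert p == pytest.approx(p_mc, rel=0.10, abs=0.005)


class TestBhFdr:
    def test_single_p(self):
        assert dc.bh_fdr([0.04]) == pytest.approx([0.04])

    def test_step_up_hand_example(self):
        assert dc.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert dc.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        expected = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert dc.bh_fdr(p) == pytest.approx(expected)


def planted_toy_matrix(plasma_beta=0.01, n_null=50, n_per_group=10):
    # 10 samples per group: with 5 the smallest attainable rank-sum p
    # (2/252) cannot clear BH over 51 CpGs at the 0.05 level
    groups = {}
    for i in range(n_per_group):
        groups[f"t{i}"] = "tumor_tissue"
        groups[f"n{i}"] = "normal_tissue"
        groups[f"p{i}"] = "healthy_plasma"
    rng = np.random.default_rng(3)
    data = {}
    # planted CpG
    row = {}
    for i in range(n_per_group):
        row[f"t{i}"] = 0.9 + 0.005 * i
        row[f"n{i}"] = 0.1 + 0.005 * i
        row[f"p{i}"] = plasma_beta
    data[("chr1", 1000)] = row
    for j in range(n_null):
        row = {}
        for i in range(n_per_group):
            row[f"t{i}"] = 0.1 + rng.uniform(0, 0.02)
            row[f"n{i}"] = 0.1 + rng.uniform(0, 0.02)
            row[f"p{i}"] = 0.01
        data[("chr1", 2000 + 10 * j)] = row
    return matrix_from_dict(data, groups)


class TestCallDifferential:
    def test_identical_groups_empty(self):
        groups = {"t0": "tumor_tissue", "t1": "tumor_tissue",
                  "n0": "normal_tissue", "n1": "normal_tissue",
                  "p0": "healthy_plasma"}
        data = {("chr1", i): {"t0": 0.4, "t1": 0.5, "n0": 0.4, "n1": 0.5, "p0": 0.01}
                for i in range(1, 6)}
        out = dc.call_differential_cpgs(matrix_from_dict(data, groups), dc.DiscoveryParams())
        assert out.empty

    def test_planted_toy_recovered(self):
        matrix = planted_toy_matrix()
        out = dc.call_differential_cpgs(matrix, dc.DiscoveryParams())
        assert out["pos"].tolist() == [1000]
        # brute-force check of the three filters + BH on the planted row
        row = matrix.beta.loc[("chr1", 1000)]
        t = row[[f"t{i}" for i in range(10)]].to_numpy()
        n = row[[f"n{i}" for i in range(10)]].to_numpy()
        p_plasma = row[[f"p{i}" for i in range(10)]].mean()
        assert t.mean() - n.mean() > 0.3
        assert p_plasma < 0.05
        assert out["q_value"].iloc[0] < 0.05

    def test_plasma_filter_blocks(self):
        out = dc.call_differential_cpgs(
            planted_toy_matrix(plasma_beta=0.06), dc.DiscoveryParams()
        )
        assert out.empty

    def test_missing_group_errors(self):
        groups = {"t0": "tumor_tissue", "n0": "normal_tissue"}
        data = {("chr1", 1): {"t0": 0.9, "n0": 0.1}}
        with pytest.raises(ValueError):
            dc.call_differential_cpgs(matrix_from_dict(data, groups), dc.DiscoveryParams())

    def test_per_sample_plasma_mode(self):
        matrix = planted_toy_matrix(plasma_beta=0.01)
        # push one plasma sample above the threshold; mean stays < 0.05
        matrix.beta.loc[("chr1", 1000), "p0"] = 0.12
        params = dc.DiscoveryParams(plasma_mode="all")
        assert dc.call_differential_cpgs(matrix, params).empty
        params = dc.DiscoveryParams(plasma_mode="mean")
        assert dc.call_differential_cpgs(matrix, params)["pos"].tolist() == [1000]


def oracle_interval_union(positions, flank):
    """Closed-interval union oracle for fragment merging."""
    intervals = [(p - flank, p + flank, p) for p in positions]
    fragments = []
    current = None
    for lo, hi, p in intervals:
        if current is None or lo > current[1]:  # touching intervals chain
            current = [lo, hi, [p]]
            fragments.append(current)
        else:
            current[1] = max(current[1], hi)
            current[2].append(p)
    return [f[2] for f in fragments]


class TestMerge:
    def test_example_gaps(self):
        assert dc.merge_to_fragments([100, 200, 360], flank=75) == [[100, 200], [360]]

    def test_single_cpg(self):
        assert dc.merge_to_fragments([42], flank=75) == [[42]]

    def test_touching_intervals_chain(self):
        assert dc.merge_to_fragments([100, 250], flank=75) == [[100, 250]]

    def test_unsorted_errors(self):
        with pytest.raises(ValueError):
            dc.merge_to_fragments([100, 90], flank=75)

    def test_matches_interval_union_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            positions = np.unique(rng.integers(1, 20_000, size=n)).tolist()
            flank = int(rng.integers(1, 120))
            assert dc.merge_to_fragments(positions, flank) == oracle_interval_union(
                positions, flank
            )


class TestFragmentsAndRegions:
    def test_min_cpgs_boundary(self):
        nine = list(range(100, 1000, 100))
        ten = list(range(100, 1100, 100))
        assert dc.filter_fragments([nine], min_cpgs=10) == []
        assert dc.filter_fragments([ten], min_cpgs=10) == [ten]
        assert dc.filter_fragments([], min_cpgs=10) == []

    def test_compact_region_length(self):
        members = [1000 + round(i * 51 / 9) for i in range(10)]
        members[-1] = 1051
        (region,) = dc.finalize_regions({"chr1": [members]})
        assert (region.start, region.end, region.length) == (1000, 1051, 52)

    def test_published_length_arithmetic(self):
        members = [391824, 392000, 393789]
        (region,) = dc.finalize_regions({"chr6": [members]})
        assert region.length == 1966

    def test_regions_sorted_disjoint(self):
        frags = {"chr1": [[100, 200], [900, 1000]], "chr2": [[5, 50]]}
        regions = dc.finalize_regions(frags)
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start


class TestDiscover:
    def test_planted_recovery(self, small_genome, small_counts):
        res = dc.discover(
            small_counts["tumor_tissue"],
            small_counts["normal_tissue"],
            small_counts["healthy_plasma"],
        )
        truth = [r.region for r in small_genome.truth.regions]
        stats = dc.evaluate_recovery(res.regions, truth)
        assert stats["recovered"] >= 7  # >= 7/8 at this small scale
        assert stats["outside"] == 0

    def test_null_cohort_zero_regions(self, small_config):
        cfg = sd.GeneratorConfig(
            seed=5, n_chrom=1, chrom_length=80_000, n_planted_regions=0, coverage=15
        )
        genome = sd.make_genome(cfg)
        counts = {
            g: {
                p.sample_id: sd.emit_counts(p, genome)
                for p in sd.make_profiles(genome, g, 5)
            }
            for g in ("tumor_tissue", "normal_tissue", "healthy_plasma")
        }
        res = dc.discover(
            counts["tumor_tissue"], counts["normal_tissue"], counts["healthy_plasma"]
        )
        assert res.regions == []

    def test_row_order_invariance(self, small_counts):
        shuffled = {
            g: {s: t.sample(frac=1, random_state=1) for s, t in tables.items()}
            for g, tables in small_counts.items()
        }
        a = dc.discover(
            small_counts["tumor_tissue"],
            small_counts["normal_tissue"],
            small_counts["healthy_plasma"],
        )
        b = dc.discover(
            shuffled["tumor_tissue"],
            shuffled["normal_tissue"],
            shuffled["healthy_plasma"],
        )
        assert a.regions == b.regions

    def test_members_passed_all_filters(self, small_counts):
        res = dc.discover(
            small_counts["tumor_tissue"],
            small_counts["normal_tissue"],
            small_counts["healthy_plasma"],
        )
        diff = res.differential_cpgs
        retained = set(zip(diff["chrom"], diff["pos"]))
        in_regions = set()
        for r in res.regions:
            for m in r.members:
                assert (r.chrom, m) in retained
                in_regions.add((r.chrom, m))
        # retained CpGs outside regions only come from under-sized fragments
        orphans = retained - in_regions
        frag_sizes = {}
        for chrom, sub in diff.groupby("chrom"):
            for frag in dc.merge_to_fragments(sub["pos"].tolist(), 75):
                for p in frag:
                    frag_sizes[(chrom, p)] = len(frag)
        assert all(frag_sizes[o] < 10 for o in orphans)

    def test_mirror_symmetry_hyper_hypo(self, small_counts):
        mirrored_plasma = {
            s: t.assign(meth=t["unmeth"], unmeth=t["meth"])
            for s, t in small_counts["healthy_plasma"].items()
        }
        hyper = dc.discover(
            small_counts["tumor_tissue"],
            small_counts["normal_tissue"],
            small_counts["healthy_plasma"],
            dc.DiscoveryParams(direction="hyper"),
        )
        hypo = dc.discover(
            small_counts["normal_tissue"],
            small_counts["tumor_tissue"],
            mirrored_plasma,
            dc.DiscoveryParams(direction="hypo"),
        )
        assert [(r.chrom, r.members) for r in hyper.regions] == [
            (r.chrom, r.members) for r in hypo.regions
        ]

    def test_hypo_generator_symmetric_recovery(self):
        cfg = sd.GeneratorConfig(
            seed=21, n_chrom=1, chrom_length=120_000, n_planted_regions=6,
            coverage=20, direction="hypo",
        )
        genome = sd.make_genome(cfg)
        counts = {
            g: {
                p.sample_id: sd.emit_counts(p, genome)
                for p in sd.make_profiles(genome, g, 5)
            }
            for g in ("tumor_tissue", "normal_tissue", "healthy_plasma")
        }
        res = dc.discover(
            counts["tumor_tissue"], counts["normal_tissue"],
            counts["healthy_plasma"], dc.DiscoveryParams(direction="hypo"),
        )
        truth = [r.region for r in genome.truth.regions]
        stats = dc.evaluate_recovery(res.regions, truth)
        assert stats["recovered"] >= 5
        assert stats["outside"] == 0
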