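"""Differential methylation: window walker, rank tests, consolidation, PMDs."""

import numpy as np
import pytest

from episuite.dmr import (
    DmrCandidate,
    DmrParams,
    consolidate_dmrs,
    find_dmrs,
    find_dmrs_regions,
    find_pmds,
    fisher_combine,
    walk_windows,
)
from episuite.fixtures import synth_genome, synth_methylomes
from episuite.intervals import Interval, IntervalSet
from episuite.methstore import import_methylation_table

from conftest import write_table


def oracle_walk(eligible, seeds_pool, D, min_points, missing_at=None, max_missing=0):
    """Literal enumeration of the seeding/extension/advance steps."""
    missing_at = missing_at or {}
    eligible = sorted(eligible)
    seeds_pool = sorted(seeds_pool)
    windows = []
    if not seeds_pool:
        return windows
    seed = seeds_pool[0]
    while True:
        members = tuple(p for p in eligible if seed <= p <= seed + D)
        if len(members) >= min_points:
            if sum(missing_at.get(p, 0) for p in members) <= max_missing:
                windows.append(members)
        nxt = [p for p in seeds_pool if p >= seed + D // 2 and p > seed]
        if not nxt:
            return windows
        seed = nxt[0]


class TestWindowWalker:
    def test_hand_layout(self):
        # positions 100,150,400,900 with D=300: one window {100,150,400}
        got = walk_windows([100, 150, 400, 900], [100, 150, 400, 900],
                           max_dist=300, min_points=2)
        assert got == [(100, 150, 400)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        positions = np.unique(rng.integers(0, 5000, size=n)).tolist()
        eligible = [p for p in positions if rng.random() < 0.7]
        D = int(rng.integers(100, 1200))
        min_points = int(rng.integers(2, 6))
        missing_at = {p: int(rng.integers(0, 3)) for p in positions}
        max_missing = int(rng.integers(0, 4))
        got = walk_windows(eligible, positions, D, min_points, missing_at,
                           max_missing, seed_must_qualify=True)
        want = oracle_walk(eligible, eligible, D, min_points, missing_at, max_missing)
        assert got == want
        got_any = walk_windows(eligible, positions, D, min_points, missing_at,
                               max_missing, seed_must_qualify=False)
        want_any = oracle_walk(eligible, positions, D, min_points, missing_at, max_missing)
        assert got_any == want_any

    def test_empty_inputs(self):
        assert walk_windows([], [], 100, 2) == []


class TestFisherCombine:
    def test_single_p_identity(self):
        for p in (0.5, 0.01, 1e-8):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-12)

    def test_all_ones(self):
        assert fisher_combine([1, 1, 1]) == pytest.approx(1.0)

    def test_two_values(self):
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.017478661367769956, rel=1e-9)

    def test_zero_clamped_with_warning(self):
        # the clamp keeps the log finite; the chi2 survival may still
        # underflow to exactly 0, which is a valid combined p
        with pytest.warns(UserWarning):
            p = fisher_combine([0.0, 0.5])
        assert np.isfinite(p) and 0.0 <= p <= 1.0


def make_store(tmp_path, name, rows):
    table = write_table(tmp_path / f"{name}.tsv", rows)
    return import_methylation_table(table, name, 0.99, 0.001,
                                    str(tmp_path / f"{name}.gz"))


class TestFindDmrs:
    def test_identical_groups_give_nothing(self, tmp_path):
        rows = [("chr1", 100 + 50 * i, "+", "CG", 8, 2) for i in range(10)]
        a = make_store(tmp_path, "a", rows)
        b = make_store(tmp_path, "b", rows)
        params = DmrParams(min_depth=1, min_diff=0.0, min_points=2)
        assert find_dmrs({"g1": [a], "g2": [b]}, params) == []

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        rows = [("chr1", 100, "+", "CG", 8, 2)]
        a = make_store(tmp_path, "a", rows)
        with pytest.raises(ValueError, match="duplicate"):
            find_dmrs({"g1": [a], "g2": [a]}, DmrParams())

    def test_empty_group_rejected(self, tmp_path):
        rows = [("chr1", 100, "+", "CG", 8, 2)]
        a = make_store(tmp_path, "a", rows)
        with pytest.raises(ValueError, match="empty"):
            find_dmrs({"g1": [a], "g2": []}, DmrParams())

    def test_recovers_planted_dmrs(self, small_methylomes):
        stores, truth = small_methylomes
        candidates = find_dmrs(stores, DmrParams())
        regions = consolidate_dmrs(candidates, q_threshold=0.05)
        planted = [(iv.start, iv.end) for iv in truth.planted_dmrs]

        def hits(r):
            return [p for p in planted if r.start < p[1] and p[0] < r.end]

        assert all(hits(r) for r in regions)  # precision 1.0
        recovered = {tuple(p) for r in regions for p in hits(r)}
        assert len(recovered) == len(planted)  # full recall
        assert all(r.direction == "hyper" for r in regions)

    def test_snp_mask_and_exclusion_remove_a_dmr(self, small_methylomes):
        stores, truth = small_methylomes
        target = truth.planted_dmrs[0]
        mask = IntervalSet([target])
        for kw in ("snp_mask", "excluded_regions"):
            candidates = find_dmrs(stores, DmrParams(), **{kw: mask})
            regions = consolidate_dmrs(candidates, q_threshold=0.05)
            assert not any(
                r.start < target.end and target.start < r.end for r in regions
            )

    def test_per_chromosome_sharding_equals_serial(self, tmp_path):
        genome = synth_genome(str(tmp_path / "g2.fa"), n_chroms=2, length=60_000,
                              seed=13)
        stores, _ = synth_methylomes(genome, str(tmp_path), groups=2,
                                     samples_per_group=2, dmr_spec=(2, 20, 0.4),
                                     seed=13)
        serial = find_dmrs(stores, DmrParams())
        sharded = []
        for chrom in ("chr1", "chr2"):
            sharded.extend(find_dmrs(stores, DmrParams(), chroms=[chrom]))
        assert [(c.chrom, c.start, c.end, c.pvalue) for c in serial] == [
            (c.chrom, c.start, c.end, c.pvalue) for c in sharded
        ]


class TestRegionMode:
    def build(self, tmp_path):
        # 5 CpGs in chr1:0-1000; constant per-sample levels chosen to give
        # distinct paired differences (0.8, 0.75, 0.5) -> exact signed-rank
        # two-sided p = 2/2^3 = 0.25
        g1_levels = [(10, 0), (9, 1), (8, 2)]  # 1.0, 0.9, 0.8
        g2_levels = [(2, 8), (3, 17), (3, 7)]  # 0.2, 0.15, 0.3
        groups = {"g1": [], "g2": []}
        for gname, levels in (("g1", g1_levels), ("g2", g2_levels)):
            for si, (c, t) in enumerate(levels):
                rows = [("chr1", 100 + 100 * i, "+", "CG", c, t) for i in range(5)]
                groups[gname].append(make_store(tmp_path, f"{gname}_{si}", rows))
        return groups

    def test_wilcoxon_matches_exact_enumeration(self, tmp_path):
        groups = self.build(tmp_path)
        rois = IntervalSet([Interval("chr1", 0, 1000)])
        cands = find_dmrs_regions(groups, rois, DmrParams(min_depth=1))
        assert len(cands) == 1
        assert cands[0].pvalue == pytest.approx(0.25)
        assert cands[0].diff == pytest.approx(0.9 - (0.2 + 0.15 + 0.3) / 3)

    def test_roi_without_data_skipped(self, tmp_path):
        groups = self.build(tmp_path)
        rois = IntervalSet([Interval("chr1", 5000, 6000)])
        assert find_dmrs_regions(groups, rois, DmrParams(min_depth=1)) == []

    def test_identical_group_means_skipped(self, tmp_path):
        rows = [("chr1", 100 + 100 * i, "+", "CG", 5, 5) for i in range(5)]
        groups = {
            "g1": [make_store(tmp_path, "x1", rows), make_store(tmp_path, "x2", rows)],
            "g2": [make_store(tmp_path, "y1", rows), make_store(tmp_path, "y2", rows)],
        }
        rois = IntervalSet([Interval("chr1", 0, 1000)])
        assert find_dmrs_regions(groups, rois, DmrParams(min_depth=1)) == []


class TestConsolidate:
    def cand(self, start, end, diff, p):
        return DmrCandidate("chr1", start, end, 5, {}, diff, p)

    def test_empty(self):
        assert consolidate_dmrs([]) == []

    def test_same_direction_merge_with_fisher(self):
        c1 = self.cand(100, 200, 0.4, 1e-5)
        c2 = self.cand(250, 350, 0.3, 1e-4)
        out = consolidate_dmrs([c1, c2], q_threshold=0.05, merge_dist=100)
        assert len(out) == 1
        assert (out[0].start, out[0].end, out[0].n_merged) == (100, 350, 2)
        assert out[0].pvalue == pytest.approx(fisher_combine([1e-5, 1e-4]))

    def test_opposite_directions_not_merged(self):
        c1 = self.cand(100, 200, 0.4, 1e-5)
        c2 = self.cand(250, 350, -0.3, 1e-4)
        out = consolidate_dmrs([c1, c2], q_threshold=0.05, merge_dist=100)
        assert len(out) == 2
        assert {r.direction for r in out} == {"hyper", "hypo"}

    def test_gap_beyond_merge_dist_not_merged(self):
        c1 = self.cand(100, 200, 0.4, 1e-5)
        c2 = self.cand(500, 600, 0.3, 1e-4)
        out = consolidate_dmrs([c1, c2], q_threshold=0.05, merge_dist=100)
        assert len(out) == 2

    def test_non_significant_dropped(self):
        out = consolidate_dmrs([self.cand(0, 10, 0.4, 0.9)], q_threshold=0.05)
        assert out == []

    def test_merged_q_is_min_of_members(self):
        c1 = self.cand(100, 200, 0.4, 1e-5)
        c2 = self.cand(210, 300, 0.3, 1e-3)
        out = consolidate_dmrs([c1, c2], q_threshold=0.05, merge_dist=100)
        qs = {round(q, 12) for q in (2e-5, 1e-3)}  # BH over two tests
        assert out[0].qvalue == pytest.approx(min(qs))


class TestFindPmds:
    def test_uniform_methylomes_have_no_pmds(self, tmp_path):
        genome = synth_genome(str(tmp_path / "g.fa"), length=100_000, seed=3)
        for beta, label in (((50.0, 2.0), "high"), ((2.0, 50.0), "low")):
            stores, _ = synth_methylomes(
                genome, str(tmp_path / label), groups=1, samples_per_group=1,
                base_level_beta=beta, dmr_spec=(0, 0, 0.0), seed=3,
            )
            assert find_pmds(stores["group1"][0]) == []

    def test_planted_domain_recovered(self, tmp_path):
        genome = synth_genome(str(tmp_path / "g.fa"), length=200_000, seed=11)
        stores, truth = synth_methylomes(
            genome, str(tmp_path / "pmd"), groups=1, samples_per_group=1,
            base_level_beta=(45.0, 5.0),  # ~0.9 background
            dmr_spec=(0, 0, 0.0), pmd_spec=(1, 50_000, 0.45), seed=11,
        )
        window = 10_000
        pmds = find_pmds(stores["group1"][0], window=window)
        assert len(pmds) == 1
        planted = truth.planted_pmds[0]
        assert abs(pmds[0].start - planted.start) <= window
        assert abs(pmds[0].end - planted.end) <= window
        assert 0.2 <= pmds[0].mean_level < 0.7
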