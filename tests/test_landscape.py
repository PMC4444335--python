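"""Profile construction, CBS segmentation, and breakpoint classification."""

import numpy as np
import pandas as pd
import pytest

from tamp_landscape.genome import GeneRecord, GenomeModel, random_genome
from tamp_landscape.landscape import (Breakpoint, _arc_mask, _best_arc,
                                      breakpoint_region_genes,
                                      build_profile, cbs_segment,
                                      classify_breakpoints, segment_profile)


def brute_force_best_arc(x, min_width=2):
    """Independent oracle: exhaustive scan over all valid arcs maximizing
    the pooled two-sample t statistic (squared)."""
    n = len(x)
    best = (-np.inf, None, None)
    for i in range(0, n + 1):
        for j in range(i + 1, n + 1):
            m = j - i
            mo = n - m
            if m < min_width or mo < min_width:
                continue
            if i != 0 and i < min_width:
                continue
            if j != n and n - j < min_width:
                continue
            inside = x[i:j]
            outside = np.concatenate([x[:i], x[j:]])
            ss = ((inside - inside.mean()) ** 2).sum() + \
                 ((outside - outside.mean()) ** 2).sum()
            sp2 = ss / (n - 2)
            denom = sp2 * (1 / m + 1 / mo)
            diff2 = (inside.mean() - outside.mean()) ** 2
            if denom <= 0:
                stat = np.inf if diff2 > 0 else 0.0
            else:
                stat = diff2 / denom
            if stat > best[0] + 1e-12:
                best = (stat, i, j)
    return best


class TestBestArc:
    def test_matches_brute_force_on_random_profiles(self, rng):
        """The vectorized first split equals exhaustive arc maximization
        on every profile of <= 30 points."""
        for n in (4, 7, 12, 19, 25, 30):
            for _ in range(10):
                x = rng.normal(0, 1, size=n)
                mask = _arc_mask(n, 2)
                i, j, stat = _best_arc(x, mask)
                ostat, oi, oj = brute_force_best_arc(x)
                assert stat == pytest.approx(ostat, rel=1e-9)

    def test_tie_break_smallest_start_then_smallest_arc(self):
        # symmetric two-level profile: arcs (0,3) and (3,6) tie exactly
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        i, j, _ = _best_arc(x, _arc_mask(6, 2))
        assert (i, j) == (0, 3)


class TestCbsSegment:
    def test_constant_profile_single_segment(self):
        segs = cbs_segment(np.full(40, 0.07), n_permutations=500, rng=0)
        assert segs == [(0, 40, pytest.approx(0.07))]

    def test_two_plateau_profile_recovered(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.01, 20),
                            rng.normal(0.2, 0.01, 20)])
        segs = cbs_segment(x, n_permutations=2000, rng=1)
        assert len(segs) == 2
        (a0, a1, m0), (b0, b1, m1) = segs
        assert (a0, a1, b0, b1) == (0, 20, 20, 40)
        assert m0 == pytest.approx(0.0, abs=0.01)
        assert m1 == pytest.approx(0.2, abs=0.01)

    def test_three_plateaus(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.01, 15),
                            rng.normal(0.15, 0.01, 15),
                            rng.normal(-0.1, 0.01, 15)])
        segs = cbs_segment(x, n_permutations=2000, rng=2)
        assert [s[:2] for s in segs] == [(0, 15), (15, 30), (30, 45)]

    def test_segments_partition_profile(self, rng):
        x = rng.normal(0, 0.05, size=60)
        segs = cbs_segment(x, n_permutations=500, rng=3)
        assert segs[0][0] == 0 and segs[-1][1] == 60
        for (a0, a1, _), (b0, b1, _) in zip(segs, segs[1:]):
            assert a1 == b0
        assert sum(b - a for a, b, _ in segs) == 60

    def test_min_width_respected(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.01, 20),
                            rng.normal(0.3, 0.01, 20)])
        for min_width in (2, 3, 5):
            segs = cbs_segment(x, min_width=min_width,
                               n_permutations=1000, rng=4)
            assert all(b - a >= min_width for a, b, _ in segs)

    def test_min_width_below_one_rejected(self):
        with pytest.raises(ValueError, match="min_width"):
            cbs_segment([0.0, 1.0, 0.0, 1.0], min_width=0)

    def test_idempotence(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.01, 20),
                            rng.normal(0.2, 0.01, 20)])
        segs = cbs_segment(x, n_permutations=1000, rng=5)
        for a, b, _ in segs:
            again = cbs_segment(x[a:b], n_permutations=1000, rng=5)
            assert len(again) == 1

    def test_seed_determinism(self, rng):
        x = rng.normal(0, 0.05, size=50)
        x[25:] += 0.04  # borderline effect: p-value decides
        a = cbs_segment(x, n_permutations=2000, rng=6)
        b = cbs_segment(x, n_permutations=2000, rng=6)
        assert a == b

    def test_pure_noise_rarely_splits(self, rng):
        n_splits = sum(
            len(cbs_segment(rng.normal(0, 0.02, size=30),
                            n_permutations=500, rng=k)) - 1
            for k in range(10))
        assert n_splits <= 3

    def test_planted_breakpoint_precision_recall(self):
        """Across 50 seeded landscapes with effect >= 0.05 and per-point
        noise SE <= 0.015, planted breakpoints are recovered with
        precision and recall >= 0.9 (boundary matched within +/-1 index)."""
        tp = fp = fn = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n = 40
            cuts = np.sort(rng.choice(np.arange(4, n - 4), size=2,
                                      replace=False))
            while np.diff(cuts).min() < 4:
                cuts = np.sort(rng.choice(np.arange(4, n - 4), size=2,
                                          replace=False))
            levels = [0.0]
            for _ in cuts:
                step = rng.uniform(0.05, 0.15) * rng.choice([-1, 1])
                levels.append(levels[-1] + step)
            x = np.empty(n)
            edges = [0, *cuts, n]
            for lv, (a, b) in zip(levels, zip(edges[:-1], edges[1:])):
                x[a:b] = lv
            x += rng.normal(0, 0.015, size=n)
            segs = cbs_segment(x, n_permutations=1000, rng=rng)
            found = [a for a, _b, _m in segs[1:]]
            matched = set()
            for f in found:
                hits = [c for c in cuts if abs(c - f) <= 1
                        and c not in matched]
                if hits:
                    matched.add(hits[0])
                    tp += 1
                else:
                    fp += 1
            fn += len(cuts) - len(matched)
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.9
        assert recall >= 0.9


class TestBuildProfile:
    def test_empty_table_empty_profile(self, toy_genome):
        table = pd.DataFrame(columns=["tamp", "fitness", "se"])
        assert build_profile(table, toy_genome).empty

    def test_sorted_and_shuffle_invariant(self, small_genome, rng):
        ids = [g.id for g in small_genome.genes]
        table = pd.DataFrame({"tamp": ids,
                              "fitness": rng.normal(0, 0.1, len(ids)),
                              "se": 0.01})
        a = build_profile(table, small_genome)
        b = build_profile(table.sample(frac=1, random_state=3),
                          small_genome)
        pd.testing.assert_frame_equal(a, b)
        assert (a.groupby("chromosome")["position"]
                .apply(lambda s: s.is_monotonic_increasing).all())

    def test_unresolvable_ids_listed(self, toy_genome):
        table = pd.DataFrame({"tamp": ["A", "nope"], "fitness": [0.1, 0.2],
                              "se": [0.01, 0.01]})
        with pytest.raises(ValueError, match="nope"):
            build_profile(table, toy_genome)

    def test_dropped_tamps_excluded(self, toy_genome):
        table = pd.DataFrame({"tamp": ["A", "B"], "fitness": [0.1, 0.2],
                              "se": [0.01, 0.01],
                              "status": ["kept", "dropped_variance"]})
        prof = build_profile(table, toy_genome)
        assert prof["tamp"].tolist() == ["A"]


def _profile_genome(positions, fitness, length=200_000, cen=100_000):
    """Genome with one gene per profile point, plus a segmentable profile."""
    genes = [GeneRecord(f"g{i}", "chr1", int(p), int(p) + 500)
             for i, p in enumerate(positions)]
    genome = GenomeModel([("chr1", length)], {"chr1": cen}, genes)
    table = pd.DataFrame({"tamp": [g.id for g in genes],
                          "fitness": fitness, "se": 0.01})
    return genome, build_profile(table, genome)


class TestClassification:
    def test_downstep_on_right_arm(self):
        # right arm: fitness falls toward the telomere
        positions = np.linspace(110_000, 190_000, 20)
        fitness = np.concatenate([np.full(10, 0.15), np.full(10, -0.05)])
        genome, profile = _profile_genome(positions, fitness)
        segs = segment_profile(profile, n_permutations=1000, rng=0)
        bps = classify_breakpoints(segs, genome)
        assert len(bps) == 1
        assert bps[0].klass == "Downstep"
        assert bps[0].delta == pytest.approx(-0.20, abs=1e-9)
        assert bps[0].arm == "R"

    def test_mirror_symmetry_preserves_classes(self):
        """Reflecting a right-arm profile onto the left arm must yield the
        same Upstep/Downstep classes (telomere direction flips with the
        coordinate order)."""
        rng = np.random.default_rng(8)
        fitness = np.concatenate([rng.normal(0.15, 0.005, 10),
                                  rng.normal(-0.05, 0.005, 10),
                                  rng.normal(0.10, 0.005, 10)])
        right_pos = np.linspace(110_000, 190_000, 30)
        left_pos = 200_000 - right_pos[::-1]  # mirrored about the center
        g_r, p_r = _profile_genome(right_pos, fitness, cen=100_000)
        g_l, p_l = _profile_genome(left_pos, fitness[::-1], cen=100_000)
        bp_r = classify_breakpoints(
            segment_profile(p_r, n_permutations=1000, rng=1), g_r)
        bp_l = classify_breakpoints(
            segment_profile(p_l, n_permutations=1000, rng=1), g_l)
        assert [b.klass for b in bp_r] == \
            [b.klass for b in reversed(bp_l)]

    def test_cross_centromere_boundary_unclassified(self):
        positions = np.concatenate([np.linspace(10_000, 90_000, 10),
                                    np.linspace(110_000, 190_000, 10)])
        fitness = np.concatenate([np.full(10, 0.2), np.full(10, -0.1)])
        genome, profile = _profile_genome(positions, fitness)
        segs = segment_profile(profile, n_permutations=1000, rng=2)
        bps = classify_breakpoints(segs, genome)
        assert len(bps) == 1
        assert bps[0].klass == "cross_centromere"

    def test_adjacent_segments_never_share_a_mean(self, rng):
        x = rng.normal(0, 0.05, size=50)
        x[20:] += 0.3
        positions = np.linspace(110_000, 190_000, 50)
        genome, profile = _profile_genome(positions, x)
        segs = segment_profile(profile, n_permutations=500, rng=3)
        for a, b in zip(segs, segs[1:]):
            assert a.mean_fitness != b.mean_fitness


class TestBreakpointRegionGenes:
    def _toy(self):
        # genes A..E on the right arm, in order
        genes = [GeneRecord(n, "c", 60_000 + 2_000 * i, 61_500 + 2_000 * i)
                 for i, n in enumerate("ABCDE")]
        return GenomeModel([("c", 100_000)], {"c": 50_000}, genes)

    def test_region_plus_one_centromeric_gene(self):
        genome = self._toy()
        # breakpoint region between Tamps initiating at C and D covers
        # both genes; B is the next gene centromeric of the region
        bp = Breakpoint("c", "R", 64_000, 66_000, -0.1, "Downstep",
                        0.1, 0.0)
        got = breakpoint_region_genes(bp, genome, extra_centromeric=1)
        assert [g.id for g in got] == ["B", "C", "D"]

    def test_left_arm_centromeric_side_is_high_coordinates(self):
        genes = [GeneRecord(n, "c", 10_000 + 2_000 * i, 11_500 + 2_000 * i)
                 for i, n in enumerate("ABCDE")]
        genome = GenomeModel([("c", 100_000)], {"c": 50_000}, genes)
        bp = Breakpoint("c", "L", 12_000, 14_000, -0.1, "Downstep",
                        0.0, 0.1)
        got = breakpoint_region_genes(bp, genome, extra_centromeric=1)
        # region covers B and C; D is centromeric (toward higher coords)
        assert [g.id for g in got] == ["B", "C", "D"]

    def test_flanking_tamps_one_gene_apart(self):
        genome = self._toy()
        bp = Breakpoint("c", "R", 62_000, 64_000, 0.1, "Upstep", 0.0, 0.1)
        got = breakpoint_region_genes(bp, genome, extra_centromeric=1)
        assert [g.id for g in got] == ["A", "B", "C"]

    def test_cross_centromere_rejected(self):
        genome = self._toy()
        bp = Breakpoint("c", "", 40_000, 60_000, np.nan,
                        "cross_centromere", 0.0, 0.1)
        with pytest.raises(ValueError, match="cross-centromere"):
            breakpoint_region_genes(bp, genome)
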