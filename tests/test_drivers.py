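"""Region algebra, driver filtering, amplicon prediction, exact tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tamp_landscape.drivers import (cen_threshold_genes,
                                    common_effect_regions,
                                    driver_coverage, filter_driver_candidates,
                                    fisher_exact, fisher_exact_with_holm,
                                    group_means, holm_bonferroni,
                                    pleiotropy_variance, predict_amplicon,
                                    rank_sum_exact, step_gene_contrast,
                                    union_regions)
from tamp_landscape.genome import GeneRecord, GenomeModel
from tamp_landscape.landscape import Breakpoint, FitnessSegment


def _seg(chrom, i0, i1, p0, p1, mean):
    return FitnessSegment(chrom, i0, i1, p0, p1, mean, i1 - i0)


class TestUnionRegions:
    def test_identical_breakpoints_region_count_equals_segments(self):
        segs = [_seg("c", 0, 10, 0, 90, 0.1), _seg("c", 10, 20, 110, 200, -0.1)]
        regions = union_regions({"a": segs, "b": segs})
        assert len(regions) == 2
        np.testing.assert_allclose(regions["a"], regions["b"])

    def test_interleaved_boundaries(self):
        # condition a splits at 100, condition b at 150 -> 3 regions
        a = [_seg("c", 0, 10, 0, 95, 0.2), _seg("c", 10, 20, 105, 200, 0.0)]
        b = [_seg("c", 0, 15, 0, 145, 0.3), _seg("c", 15, 20, 155, 200, -0.3)]
        regions = union_regions({"a": a, "b": b})
        assert len(regions) == 3
        # middle region: covered by a's second segment and b's first
        mid = regions.iloc[1]
        assert mid["a"] == pytest.approx(0.0)
        assert mid["b"] == pytest.approx(0.3)

    def test_region_count_at_least_max_single_condition(self, rng):
        for trial in range(10):
            def rand_segs():
                cuts = np.sort(rng.choice(np.arange(10, 190), size=rng.integers(0, 4), replace=False))
                edges = [0, *cuts.tolist(), 200]
                return [_seg("c", i, i + 1, float(a), float(b) - 1,
                             float(rng.normal()))
                        for i, (a, b) in enumerate(zip(edges[:-1],
                                                       edges[1:]))]
            conds = {"a": rand_segs(), "b": rand_segs(), "c": rand_segs()}
            regions = union_regions(conds)
            assert len(regions) >= max(len(s) for s in conds.values())

    def test_single_condition_passthrough(self):
        segs = [_seg("c", 0, 5, 0, 40, 0.1), _seg("c", 5, 9, 60, 100, 0.4)]
        regions = union_regions({"only": segs})
        assert len(regions) == 2
        assert regions["only"].tolist() == [0.1, 0.4]


class TestCommonEffects:
    def _regions(self, rows):
        frame = pd.DataFrame(rows, columns=["a", "b", "c"])
        frame["chrom"] = "c"
        frame["start"] = 0.0
        frame["end"] = 1.0
        return frame

    def test_universally_advantageous(self):
        out = common_effect_regions(self._regions([[0.06, 0.07, 0.06]]),
                                    ("a", "b", "c"))
        assert out.tolist() == ["universally_advantageous"]

    def test_threshold_is_strict(self):
        out = common_effect_regions(self._regions([[0.06, 0.07, 0.04],
                                                   [0.05, 0.06, 0.06],
                                                   [-0.06, -0.08, -0.051]]),
                                    ("a", "b", "c"))
        assert out.tolist() == ["condition_specific", "condition_specific",
                                "universally_detrimental"]


class TestStepGeneContrast:
    def test_identical_fitness_everywhere_p_one(self):
        fitness = {g: 0.05 for g in "abcdefgh"}
        down = [["a", "b"], ["c"], ["d", "e"]]
        up = [["f"], ["g"], ["h"]]
        _, _, t, p = step_gene_contrast(down, up, fitness)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_t(self):
        fitness = dict(a=0.1, b=0.12, c=0.08, x=-0.1, y=-0.12, z=-0.08)
        down = [["a"], ["b"], ["c"]]
        up = [["x"], ["y"], ["z"]]
        d, u, t, p = step_gene_contrast(down, up, fitness)
        # pooled two-sample t with df = 4 on the per-breakpoint means
        sp2 = (np.var(d, ddof=1) * 2 + np.var(u, ddof=1) * 2) / 4
        t_expected = (np.mean(d) - np.mean(u)) / np.sqrt(sp2 * (2 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_uncovered_breakpoints_skipped_with_warning(self, caplog):
        fitness = dict(a=0.1, b=0.2, x=-0.1, y=-0.2)
        with caplog.at_level("WARNING"):
            d, u, _, _ = step_gene_contrast([["a"], ["b"], ["zzz"]],
                                            [["x"], ["y"]], fitness)
        assert len(d) == 2 and "no gene" in caplog.text

    def test_single_breakpoint_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            step_gene_contrast([["a"]], [["x"], ["y"]],
                               dict(a=0.1, x=0.0, y=0.1))


class TestDriverFiltering:
    def test_gene_without_evidence_not_candidate(self):
        downs = {"glucose": {"ds1": ["g1", "g2"]}}
        evidence = {"glucose": {"upregulated": {"other"},
                                "CEN_outlier": set(),
                                "CEN_mean_2SD": set(), "mutated": set()}}
        assert filter_driver_candidates(downs, evidence) == []

    def test_planted_driver_recovered_exactly(self):
        downs = {"glucose": {"ds1": ["g1", "g2", "g3"],
                             "ds2": ["g7", "g8"]},
                 "sulfate": {"ds3": ["g1", "g9"]}}
        evidence = {"glucose": {"upregulated": {"g2", "g9"},
                                "CEN_outlier": set(),
                                "CEN_mean_2SD": set(), "mutated": set()},
                    "sulfate": {"upregulated": set(),
                                "CEN_outlier": {"g9"},
                                "CEN_mean_2SD": set(), "mutated": set()}}
        got = filter_driver_candidates(downs, evidence)
        assert {(c.gene, c.condition, c.downstep) for c in got} == \
            {("g2", "glucose", "ds1"), ("g9", "sulfate", "ds3")}
        # evidence is a union: one list suffices, flags are recorded
        assert got[0].evidence == ("upregulated",)

    def test_missing_evidence_list_warned_and_skipped(self, caplog):
        downs = {"glucose": {"ds1": ["g1"]}}
        with caplog.at_level("WARNING"):
            got = filter_driver_candidates(
                downs, {"glucose": {"mutated": {"g1"}}})
        assert "missing" in caplog.text
        assert [c.gene for c in got] == ["g1"]

    def test_cen_threshold_lists(self):
        fitness = {"lo": -0.2, "mid": 0.0, "hi": 0.051, "edge": 0.050}
        got = cen_threshold_genes(fitness, -0.052, 0.050)
        assert got == {"lo", "hi"}  # strictly beyond the printed cutoffs

    def test_coverage_fraction(self):
        downs = {"glucose": {f"ds{i}": [f"g{i}"] for i in range(4)}}
        evidence = {"glucose": {"upregulated": {"g0", "g1", "g2"},
                                "CEN_outlier": set(),
                                "CEN_mean_2SD": set(), "mutated": set()}}
        cands = filter_driver_candidates(downs, evidence)
        cov = driver_coverage([f"ds{i}" for i in range(4)], cands)
        assert cov == pytest.approx(0.75)


class TestPredictAmplicon:
    def _setup(self):
        genome = GenomeModel([("c", 200_000)], {"c": 100_000},
                             [GeneRecord("g1", "c", 110_000, 111_000),
                              GeneRecord("g2", "c", 150_000, 151_000)])
        segs = {"a": [_seg("c", 0, 5, 110_000, 140_000, 0.06),
                      _seg("c", 5, 9, 150_000, 190_000, -0.02)]}
        bps = {"a": [Breakpoint("c", "R", 140_000, 150_000, -0.08,
                                "Downstep", 0.06, -0.02)]}
        return genome, segs, bps

    def test_fitness_at_initiation_point(self):
        genome, segs, bps = self._setup()
        preds = predict_amplicon("c", (120_000, 200_000), genome, segs, bps)
        assert preds[0].predicted_fitness == pytest.approx(0.06)
        assert preds[0].n_downsteps == 1

    def test_amplicon_without_breakpoints(self):
        genome, segs, bps = self._setup()
        preds = predict_amplicon("c", (160_000, 200_000), genome, segs, bps)
        assert preds[0].predicted_fitness == pytest.approx(-0.02)
        assert preds[0].n_downsteps == 0

    def test_interior_interval_rejected(self):
        genome, segs, bps = self._setup()
        with pytest.raises(ValueError, match="chromosome end"):
            predict_amplicon("c", (120_000, 180_000), genome, segs, bps)

    def test_left_telomere_amplicon(self):
        genome, segs, bps = self._setup()
        segs["a"].insert(0, _seg("c", 0, 3, 10_000, 90_000, 0.11))
        preds = predict_amplicon("c", (0, 80_000), genome, segs, bps)
        assert preds[0].predicted_fitness == pytest.approx(0.11)


class TestPleiotropy:
    def test_constant_fitness_zero_variance(self):
        assert pleiotropy_variance([0.1, 0.1, 0.1]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sample_variance(self):
        assert pleiotropy_variance([0.3, 0.0, -0.3]) == \
            pytest.approx(0.09, abs=1e-15)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            pleiotropy_variance([0.1])


class TestRankSumExact:
    def test_complete_separation_4v4(self):
        p = rank_sum_exact([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0])
        assert p == pytest.approx(2 / 70, abs=1e-12)
        assert round(p, 3) == 0.029

    def test_identical_groups_p_one(self):
        assert rank_sum_exact([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == \
            pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        """Every 3v3 and 4v3 input agrees with explicit enumeration over
        all rank assignments."""
        for na, nb in ((3, 3), (4, 3)):
            for _ in range(20):
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
                p = rank_sum_exact(a, b)
                ranks = stats.rankdata(np.concatenate([a, b]))
                mu = na * (na + nb + 1) / 2
                w_obs = ranks[:na].sum()
                count = total = 0
                for combo in itertools.combinations(range(na + nb), na):
                    w = ranks[list(combo)].sum()
                    total += 1
                    if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                        count += 1
                assert p == pytest.approx(count / total, abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        """Cross-check against the independent library implementation on
        tie-free data."""
        for _ in range(20):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            ours = rank_sum_exact(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(0.5, 1, size=25)
        ours = rank_sum_exact(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_exact([], [1.0])


class TestFisherHolm:
    def test_perfect_association_table(self):
        # all 20 observations on the diagonal
        p = fisher_exact([[0, 10], [10, 0]])
        # both extreme tables have probability 1/C(20,10)
        from math import comb
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_identical_row_proportions_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            table = rng.integers(0, 12, size=(2, 2))
            ours = fisher_exact(table.tolist())
            ref = stats.fisher_exact(table)[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    def test_holm_known_adjustment(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_holm_monotone_and_bounded(self, rng):
        p = rng.uniform(size=12)
        adj = np.asarray(holm_bonferroni(p))
        assert (adj <= 1.0).all()
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_joint_fisher_holm(self):
        raw, adj = fisher_exact_with_holm(
            [[[0, 10], [10, 0]], [[5, 5], [5, 5]]])
        assert adj[0] == pytest.approx(min(raw[0] * 2, 1.0))
        assert adj[1] == pytest.approx(1.0)


class TestGroupMeans:
    def test_hand_computed_means(self):
        values = {"t1": 0.25, "t2": 0.21, "t3": -0.2, "t4": -0.16}
        got = group_means(values, {"with_driver": ["t1", "t2"],
                                   "without": ["t3", "t4"]})
        assert got["with_driver"] == pytest.approx(0.23)
        assert got["without"] == pytest.approx(-0.18)

    def test_missing_member_raises(self):
        with pytest.raises(KeyError, match="t9"):
            group_means({"t1": 0.1}, {"g": ["t1", "t9"]})
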