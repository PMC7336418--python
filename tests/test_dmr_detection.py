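import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavedmr.dmr_detection import (
    DetectionConfig,
    DMRegion,
    classify_direction,
    detect_dmrs,
    group_adjacent,
    group_average,
    mark_dm,
    nearest_gene,
    required_covered,
    sample_stats,
    validate_coverage,
)
from wavedmr.meth_io import GeneAnnotation
from wavedmr.signal_core import MethylationSignal, build_signal
from wavedmr.wavelet import transform

from conftest import brute_force_detect, make_map


def signal(values, coverage=None, start=1, sample_id="s"):
    values = np.asarray(values, float)
    if coverage is None:
        coverage = np.where(values > 0, 10, 10)
    return MethylationSignal(
        chromosome="chr1",
        start=start,
        end=start + len(values) - 1,
        values=values,
        coverage=np.asarray(coverage, int),
        sample_id=sample_id,
    )


def config(**kw):
    base = dict(level=2, dmr_threshold=0.25, coverage_threshold=1,
                min_valid_fraction=0.25)
    base.update(kw)
    return DetectionConfig(**base)


class TestDetectionConfig:
    def test_defaults(self):
        c = DetectionConfig(level=4)
        assert c.dmr_threshold == 0.25
        assert c.min_valid_fraction == 0.25
        assert c.coverage_threshold == 1
        assert c.filter_name == "haar"

    @pytest.mark.parametrize(
        "kw",
        [
            dict(level=0),
            dict(level=2, dmr_threshold=0.0),
            dict(level=2, dmr_threshold=1.5),
            dict(level=2, min_valid_fraction=0.0),
            dict(level=2, analysis_type="x"),
            dict(level=2, filter_name="nope"),
            dict(level=2, coverage_pooling="sometimes"),
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            DetectionConfig(**kw)


class TestGroupAverage:
    def test_identical_signals(self):
        t = [transform(signal([1, 0, 0, 1]), level=1) for _ in range(2)]
        assert np.array_equal(group_average(t), t[0].scaling)

    def test_single_signal_identity(self):
        t = transform(signal([0.2, 0.4]), level=1)
        assert np.array_equal(group_average([t]), t.scaling)

    def test_arithmetic_mean(self):
        a = transform(signal([0.2, 0.2]), level=1)
        b = transform(signal([0.8, 0.8]), level=1)
        assert np.allclose(group_average([a, b]), [0.5])

    def test_empty_group(self):
        with pytest.raises(ValueError):
            group_average([])

    def test_mismatched_levels(self):
        a = transform(signal([0.2, 0.2, 0.2, 0.2]), level=1)
        b = transform(signal([0.2, 0.2, 0.2, 0.2]), level=2)
        with pytest.raises(ValueError):
            group_average([a, b])


class TestMarkDm:
    def test_exceeds(self):
        assert mark_dm(np.array([0.8]), np.array([0.2]), 0.5).tolist() == [True]

    def test_identical_groups_never_marked(self):
        x = np.array([0.1, 0.9, 0.5])
        assert not mark_dm(x, x, 0.01).any()

    def test_strict_inequality(self):
        assert mark_dm(np.array([0.7]), np.array([0.2]), 0.5).tolist() == [False]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mark_dm(np.zeros(2), np.zeros(3), 0.1)


class TestRequiredCovered:
    def test_quarter_of_four(self):
        assert required_covered(2, 0.25) == 1

    def test_seven_percent_of_64(self):
        assert required_covered(6, 0.07) == 4

    def test_clamped_to_one(self):
        assert required_covered(1, 0.25) == 1

    def test_floor_not_ceil(self):
        assert required_covered(6, 0.249) == 15


class TestValidateCoverage:
    def test_single_covered_position_suffices(self):
        cfg = config(level=2, coverage_threshold=50)
        cov = [np.array([60, 0, 0, 0]), np.array([70, 0, 0, 0])]
        out = validate_coverage(np.array([True]), cov, cfg)
        assert out.tolist() == [True]

    def test_all_zero_coverage_removes_marks(self):
        cfg = config(level=2)
        out = validate_coverage(
            np.array([True, True]), [np.zeros(8, int)], cfg
        )
        assert not out.any()

    def test_applied_after_marking_not_by_zeroing(self):
        # an unmarked window stays unmarked even with full coverage
        cfg = config(level=2)
        out = validate_coverage(np.array([False]), [np.full(4, 100)], cfg)
        assert out.tolist() == [False]

    def test_pooling_all_requires_every_sample(self):
        cfg = config(level=2, coverage_threshold=10)
        cov = [np.array([20, 0, 0, 0]), np.array([0, 0, 0, 20])]
        assert not validate_coverage(np.array([True]), cov, cfg).any()

    def test_pooling_any(self):
        cfg = config(level=2, coverage_threshold=10, coverage_pooling="any")
        cov = [np.array([20, 0, 0, 0]), np.array([0, 0, 0, 20])]
        assert validate_coverage(np.array([True]), cov, cfg).all()

    def test_pooling_per_group_mean(self):
        cfg = config(level=1, coverage_threshold=10,
                     coverage_pooling="per-group-mean")
        cov = [np.array([30, 0]), np.array([0, 0]), np.array([15, 0])]
        out = validate_coverage(np.array([True]), cov, cfg, n_case=2)
        assert out.tolist() == [True]  # case mean 15, control 15 at position 0

    def test_monotone_in_coverage_threshold(self, rng):
        mask = rng.random(32) < 0.5
        cov = [rng.integers(0, 80, size=128) for _ in range(3)]
        kept = [
            validate_coverage(mask, cov, config(level=2, coverage_threshold=t)).sum()
            for t in (1, 25, 50)
        ]
        assert kept[0] >= kept[1] >= kept[2]


class TestGroupAdjacent:
    def test_worked_mask(self):
        regions = group_adjacent(np.array([True, True, False, True]), 2, 1001)
        assert [(r[0], r[1]) for r in regions] == [(1001, 1008), (1013, 1016)]

    def test_all_false(self):
        assert group_adjacent(np.zeros(5, bool), 2, 1) == []

    def test_all_true_single_region(self):
        regions = group_adjacent(np.ones(7, bool), 3, 1)
        assert len(regions) == 1
        lo, hi, idx = regions[0]
        assert hi - lo + 1 == 7 * 8 and idx == list(range(7))


class TestClassifyDirection:
    def test_hyper(self):
        assert classify_direction([0], np.array([0.9]), np.array([0.2])) == (
            "hyper", pytest.approx(0.7))

    def test_hypo(self):
        d, md = classify_direction([0], np.array([0.1]), np.array([0.8]))
        assert d == "hypo" and md == pytest.approx(-0.7)

    def test_mean_over_windows(self):
        d, md = classify_direction(
            [0, 1], np.array([0.8, 0.6]), np.array([0.2, 0.2])
        )
        assert d == "hyper" and md == pytest.approx(0.5)

    def test_empty_region(self):
        with pytest.raises(ValueError):
            classify_direction([], np.array([]), np.array([]))


class TestSampleStats:
    def test_worked_example(self):
        m = make_map([(10, 2, 0, 2, 0), (14, 6, 0, 4, 0)])
        s = sample_stats((8, 16), m)
        assert s.n_informative == 2
        assert (s.coverage_min, s.coverage_avg, s.coverage_max) == (4, 7, 10)
        assert (s.reads_c, s.reads_mc) == (8, 6)
        assert (s.gap_min, s.gap_avg, s.gap_max) == (4, 4, 4)

    def test_no_records_zeroed(self):
        s = sample_stats((100, 200), make_map([(10, 1, 0, 1, 0)]))
        assert s.n_informative == 0 and s.coverage_avg == 0

    def test_single_record_gap_zero(self):
        s = sample_stats((8, 16), make_map([(10, 2, 0, 2, 0)]))
        assert (s.gap_min, s.gap_avg, s.gap_max) == (0, 0, 0)

    def test_invariant_ordering(self):
        m = make_map([(10, 2, 1, 2, 1), (20, 6, 0, 4, 2), (23, 1, 0, 0, 0)])
        s = sample_stats((1, 30), m)
        assert s.coverage_min <= s.coverage_avg <= s.coverage_max
        assert s.gap_min <= s.gap_avg <= s.gap_max


class TestNearestGene:
    genes = [
        GeneAnnotation("A", "chr1", 100, 200),
        GeneAnnotation("B", "chr1", 500, 600),
    ]

    def test_overlap_distance_zero(self):
        assert nearest_gene((150, 160), self.genes) == ("A", 0)

    def test_downstream_gap(self):
        assert nearest_gene((300, 300), self.genes) == ("A", 100)

    def test_tie_break_lower_start(self):
        assert nearest_gene((350, 350), self.genes) == ("A", 150)

    def test_empty_annotation(self):
        assert nearest_gene((1, 10), []) == (None, None)


class TestDetectDmrs:
    def test_identical_groups_empty(self):
        vals = np.tile([0.9, 0.1], 16)
        case = [signal(vals)]
        control = [signal(vals.copy())]
        assert detect_dmrs(case, control, config()) == []

    def test_single_planted_block(self):
        n, level = 64, 3
        case_vals = np.zeros(n)
        case_vals[16:24] = 1.0  # exactly one level-3 window
        case = [signal(case_vals, coverage=np.full(n, 30))]
        control = [signal(np.zeros(n), coverage=np.full(n, 30))]
        regions = detect_dmrs(case, control, config(level=level, dmr_threshold=0.5))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (17, 24)
        assert r.direction == "hyper"
        assert r.mean_difference == pytest.approx(1.0)
        assert r.n_windows == 1

    def test_groups_must_share_interval(self):
        with pytest.raises(ValueError):
            detect_dmrs([signal(np.zeros(8))],
                        [signal(np.zeros(8), start=5)], config())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            detect_dmrs([], [signal(np.zeros(8))], config())

    def test_min_region_length(self, rng):
        case = [signal(rng.random(256).round(2))]
        control = [signal(rng.random(256).round(2))]
        cfg = config(level=3, dmr_threshold=0.1)
        for r in detect_dmrs(case, control, cfg):
            assert r.end - r.start + 1 >= 8
            assert (r.end - r.start + 1) % 8 == 0

    def test_symmetry_under_group_swap(self, rng):
        case = [signal(rng.random(256).round(2)) for _ in range(2)]
        control = [signal(rng.random(256).round(2)) for _ in range(2)]
        cfg = config(level=3, dmr_threshold=0.15)
        fwd = detect_dmrs(case, control, cfg)
        rev = detect_dmrs(control, case, cfg)
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert (a.start, a.end) == (b.start, b.end)
            assert a.direction != b.direction
            assert a.mean_difference == pytest.approx(-b.mean_difference)

    def test_sign_mixing_splits_regions(self):
        n, level = 16, 2
        case_vals = np.concatenate([np.ones(4), np.zeros(4), np.zeros(8)])
        ctrl_vals = np.concatenate([np.zeros(4), np.ones(4), np.zeros(8)])
        case = [signal(case_vals, coverage=np.full(n, 10))]
        control = [signal(ctrl_vals, coverage=np.full(n, 10))]
        regions = detect_dmrs(case, control, config(level=level, dmr_threshold=0.5))
        assert [r.direction for r in regions] == ["hyper", "hypo"]
        assert [(r.start, r.end) for r in regions] == [(1, 4), (5, 8)]

    def test_per_sample_stats_attached(self):
        m_case = make_map([(i, 0, 0, 10, 0) for i in range(1, 9)], sample_id="c1")
        m_ctrl = make_map([(i, 10, 0, 0, 0) for i in range(1, 9)], sample_id="k1")
        case = [build_signal(m_case, 1, 8)]
        control = [build_signal(m_ctrl, 1, 8)]
        regions = detect_dmrs(
            case, control, config(level=2, dmr_threshold=0.5),
            maps={"c1": m_case, "k1": m_ctrl},
        )
        assert len(regions) == 1
        assert {s.sample_id for s in regions[0].per_sample} == {"c1", "k1"}
        c1 = next(s for s in regions[0].per_sample if s.sample_id == "c1")
        assert c1.n_informative == 8 and c1.reads_mc == 80

    def test_gene_annotation_attached(self):
        case = [signal(np.ones(8), coverage=np.full(8, 10), start=100)]
        control = [signal(np.zeros(8), coverage=np.full(8, 10), start=100)]
        genes = [GeneAnnotation("G1", "chr1", 300, 400)]
        regions = detect_dmrs(case, control,
                              config(level=2, dmr_threshold=0.5), genes=genes)
        assert regions[0].closest_gene == "G1"
        assert regions[0].gene_distance == 300 - regions[0].end


def _random_instance(rng, n, n_case, n_control, density=0.5):
    def grp(k):
        out = []
        for _ in range(k):
            vals = np.where(rng.random(n) < density, rng.random(n), 0.0).round(3)
            cov = np.where(vals > 0, rng.integers(1, 60, size=n), 0)
            cov += rng.integers(0, 2, size=n)  # some covered zero-ratio positions
            vals[cov == 0] = 0.0
            out.append(signal(vals, coverage=cov))
        return out
    return grp(n_case), grp(n_control)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 4096))
        level = int(rng.integers(1, 7))
        cfg = config(
            level=level,
            dmr_threshold=float(rng.uniform(0.05, 0.5)),
            coverage_threshold=int(rng.integers(1, 40)),
            min_valid_fraction=float(rng.uniform(0.05, 1.0)),
        )
        case, control = _random_instance(rng, n, 2, 2)
        got = detect_dmrs(case, control, cfg)
        expected = brute_force_detect(
            [s.values for s in case],
            [s.values for s in control],
            [s.coverage for s in case] + [s.coverage for s in control],
            cfg,
        )
        assert [(r.start, r.end, r.direction, r.n_windows) for r in got] == [
            (e[0], e[1], e[2], e[4]) for e in expected
        ]
        for r, e in zip(got, expected):
            assert r.mean_difference == pytest.approx(e[3], abs=1e-9)


class TestMonotonicity:
    """Region counts are monotone on well-separated planted datasets; the
    count of marked windows is monotone unconditionally."""

    @staticmethod
    def planted():
        from wavedmr.signal_core import build_signal
        from wavedmr.synthetic import SimulationParams, generate_maps

        params = SimulationParams(
            n_positions=10_000, cpg_density=1.0, base_methylation=0.2,
            effect_size=0.6, dmr_lengths=(64,), n_dmrs=4, coverage_mean=50.0,
            overdispersion=0.02, n_case=2, n_control=2, seed=5,
        )
        case, control, _ = generate_maps(params)
        return (
            [build_signal(m, 1, params.n_positions) for m in case],
            [build_signal(m, 1, params.n_positions) for m in control],
        )

    def test_dmr_count_non_increasing_in_threshold(self):
        case, control = self.planted()
        counts = [
            len(detect_dmrs(case, control, config(level=4, dmr_threshold=t)))
            for t in np.linspace(0.05, 0.5, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_dmr_count_non_increasing_in_coverage(self):
        case, control = self.planted()
        counts = [
            len(detect_dmrs(case, control,
                            config(level=4, dmr_threshold=0.2,
                                   coverage_threshold=t)))
            for t in (1, 5, 10, 20, 35, 50)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_marked_window_total_monotone_on_any_data(self, rng):
        # total marked-window count (sum of n_windows) is monotone even on
        # noise, where region counts can transiently rise as runs split
        case, control = _random_instance(rng, 2048, 2, 2)
        totals = [
            sum(r.n_windows for r in
                detect_dmrs(case, control, config(level=3, dmr_threshold=t)))
            for t in np.linspace(0.05, 0.5, 8)
        ]
        assert totals == sorted(totals, reverse=True)


class TestDMRegionType:
    def test_length_invariant_enforced(self):
        with pytest.raises(ValueError):
            DMRegion(chromosome="chr1", start=1, end=5, direction="hyper",
                     mean_difference=0.5, n_windows=1, level=2)
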