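"""Interval algebra against a brute-force per-base oracle, signal statistics,
and the nearest-flanking-gene query."""

import numpy as np
import pytest

from enhancermap.intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    nearest_flanking,
    overlap_stats,
    signal_stat,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "start,end", [(-1, 10), (10, 10), (10, 5)]
    )
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)


class TestOverlapStats:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (150, 250), (50, 0.5, 0.5)),
            ((100, 200), (100, 200), (100, 1.0, 1.0)),
            ((100, 200), (300, 400), (0, 0.0, 0.0)),
        ],
    )
    def test_overlap_examples(self, a, b, expected):
        assert overlap_stats(iv(*a), iv(*b)) == expected

    def test_different_chromosomes_zero(self):
        assert overlap_stats(iv(0, 10), iv(0, 10, "chr2")) == (0, 0.0, 0.0)

    def test_overlap_bp_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s1, s2 = rng.integers(0, 1000, 2)
            a = iv(int(s1), int(s1) + int(rng.integers(1, 200)))
            b = iv(int(s2), int(s2) + int(rng.integers(1, 200)))
            assert overlap_stats(a, b)[0] == overlap_stats(b, a)[0]


def brute_force_coverage(ivset, max_pos=10_000):
    """Per-base membership oracle over a small coordinate range."""
    cov = {}
    for interval in ivset:
        mask = cov.setdefault(interval.chrom, np.zeros(max_pos, dtype=bool))
        mask[interval.start:interval.end] = True
    return cov


def coverage_of(ivset, max_pos=10_000):
    return brute_force_coverage(ivset, max_pos)


def random_set(rng, n_max=50, span=10_000):
    n = int(rng.integers(0, n_max + 1))
    ivs = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, 3))}"
        s = int(rng.integers(0, span - 1))
        e = s + int(rng.integers(1, 500))
        ivs.append(GenomicInterval(chrom, s, min(e, span)))
    return IntervalSet(ivs)


class TestIntervalSetAlgebra:
    @pytest.mark.parametrize(
        "op,a,b,expected",
        [
            ("intersect", [(0, 1000)], [(500, 1500)], [(500, 1000)]),
            ("subtract", [(0, 1000)], [(200, 300)], [(0, 200), (300, 1000)]),
            ("merge", [(0, 100), (100, 200)], None, [(0, 200)]),
        ],
    )
    def test_textbook_examples(self, op, a, b, expected):
        sa = IntervalSet([iv(*t) for t in a])
        if op == "merge":
            result = sa.merge()
        else:
            result = getattr(sa, op)(IntervalSet([iv(*t) for t in b]))
        assert [(i.start, i.end) for i in result] == expected

    def test_algebra_matches_per_base_oracle(self):
        """intersect/subtract/merge agree exactly with per-base set logic on
        random instances."""
        rng = np.random.default_rng(42)
        for _ in range(150):
            a, b = random_set(rng), random_set(rng)
            cov_a, cov_b = coverage_of(a), coverage_of(b)
            chroms = set(cov_a) | set(cov_b)
            for op, expected_mask in (
                ("intersect", lambda c: cov_a.get(c, 0) & cov_b.get(c, 0)
                 if c in cov_a and c in cov_b else np.zeros(10_000, bool)),
                ("subtract", lambda c: cov_a.get(c, np.zeros(10_000, bool))
                 & ~cov_b.get(c, np.zeros(10_000, bool))),
            ):
                result_cov = coverage_of(getattr(a, op)(b))
                for chrom in chroms:
                    got = result_cov.get(chrom, np.zeros(10_000, bool))
                    assert np.array_equal(got, expected_mask(chrom)), (op, chrom)
            merged_cov = coverage_of(a.merge())
            for chrom in chroms:
                got = merged_cov.get(chrom, np.zeros(10_000, bool))
                assert np.array_equal(got, cov_a.get(chrom, np.zeros(10_000, bool)))

    def test_results_are_merged_disjoint(self):
        rng = np.random.default_rng(1)
        a, b = random_set(rng), random_set(rng)
        for result in (a.merge(), a.intersect(b), a.subtract(b)):
            for chrom in result.chromosomes:
                ivs = result.on(chrom)
                assert all(
                    ivs[i].end < ivs[i + 1].start for i in range(len(ivs) - 1)
                )


class TestSignalTrack:
    def test_constant_track_mean_and_max(self):
        t = SignalTrack({"chr1": [(0, 1000, 2.0)]})
        region = iv(100, 900)
        assert signal_stat(t, region, "mean") == pytest.approx(2.0)
        assert signal_stat(t, region, "max") == pytest.approx(2.0)

    def test_half_covered_interval(self):
        t = SignalTrack({"chr1": [(0, 50, 4.0)]})
        region = iv(0, 100)
        assert signal_stat(t, region, "mean") == pytest.approx(2.0)
        assert signal_stat(t, region, "max") == pytest.approx(4.0)

    def test_unknown_chromosome_raises(self):
        t = SignalTrack({"chr1": [(0, 100, 1.0)]})
        with pytest.raises(KeyError, match="chrX"):
            signal_stat(t, iv(0, 10, "chrX"), "mean")

    def test_mass_conservation(self):
        """mean x length over a whole chromosome equals total signal mass."""
        rng = np.random.default_rng(3)
        edges = np.sort(rng.choice(np.arange(1, 5000), size=20, replace=False))
        bounds = [0, *edges.tolist(), 5000]
        steps = [
            (bounds[i], bounds[i + 1], float(rng.uniform(0, 5)))
            for i in range(len(bounds) - 1)
        ]
        t = SignalTrack({"chr1": steps})
        mass = sum((e - s) * v for s, e, v in steps)
        assert t.mean(iv(0, 5000)) * 5000 == pytest.approx(mass)

    def test_max_difference_on_step_tracks(self):
        a = SignalTrack({"chr1": [(0, 100, 5.0), (100, 200, 1.0)]})
        b = SignalTrack({"chr1": [(50, 150, 2.0)]})
        # difference: [0,50)=5, [50,100)=3, [100,150)=-1, [150,200)=1
        assert a.max_difference(b, iv(0, 200)) == pytest.approx(5.0)
        assert b.max_difference(a, iv(0, 200)) == pytest.approx(-1.0 + 2.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            SignalTrack({"chr1": [(0, 10, -1.0)]})


class TestNearestFlanking:
    def test_both_sides(self):
        genes = IntervalSet([
            GenomicInterval("chr1", 1000, 2000, name="g1"),
            GenomicInterval("chr1", 9000, 10000, name="g2"),
        ])
        up, down, d_up, d_down = nearest_flanking(iv(5000, 6000), genes)
        assert (up.name, down.name) == ("g1", "g2")
        assert (d_up, d_down) == (3000, 3000)

    def test_before_first_gene(self):
        genes = IntervalSet([GenomicInterval("chr1", 1000, 2000, name="g1")])
        up, down, d_up, d_down = nearest_flanking(iv(100, 200), genes)
        assert up is None and down.name == "g1"
        assert d_down == 800

    def test_abutting_gene_distance_zero(self):
        genes = IntervalSet([GenomicInterval("chr1", 1000, 2000, name="g1")])
        up, _, d_up, _ = nearest_flanking(iv(2000, 3000), genes)
        assert up.name == "g1" and d_up == 0
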