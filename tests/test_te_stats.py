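"""TE baseline filtering, containment, binomial family enrichment, motif
scanning (against a sliding-window oracle) and the permutation test."""

import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from enhancermap.intervals import Genome, GenomicInterval, IntervalSet
from enhancermap.te_stats import (
    TEAnnotation,
    _place_features,
    cns_overlap,
    family_enrichment,
    motif_scan,
    permutation_enrichment,
    resolve_nested_and_filter,
    te_containment,
)


def te(start, end, family="famA", superfamily="LTR", chrom="chr1"):
    return TEAnnotation(GenomicInterval(chrom, start, end), family, superfamily)


class TestBaselineFilter:
    def test_short_element_dropped(self):
        out = resolve_nested_and_filter([te(0, 500)], IntervalSet())
        assert out == []

    def test_just_over_length_floor_kept(self):
        assert len(resolve_nested_and_filter([te(0, 636)], IntervalSet())) == 1
        assert len(resolve_nested_and_filter([te(0, 635)], IntervalSet())) == 0

    def test_intronic_element_dropped(self):
        introns = IntervalSet([GenomicInterval("chr1", 0, 10_000)])
        assert resolve_nested_and_filter([te(1000, 2000)], introns) == []

    def test_partially_intronic_element_kept(self):
        introns = IntervalSet([GenomicInterval("chr1", 0, 1500)])
        assert len(resolve_nested_and_filter([te(1000, 2000)], introns)) == 1

    def test_nested_element_excluded(self):
        outer, inner = te(0, 5000), te(1000, 2000, family="famB")
        out = resolve_nested_and_filter([outer, inner], IntervalSet())
        assert [t.family for t in out] == ["famA"]


class TestContainment:
    def test_eighty_percent_within_one_te(self):
        cand = GenomicInterval("chr1", 1000, 2000)
        result = te_containment([cand], [te(900, 1850)])
        assert len(result.pairs) == 1

    def test_split_across_two_tes_not_contained(self):
        cand = GenomicInterval("chr1", 1000, 2000)
        tes = [te(500, 1500), te(1500, 2500, family="famB")]
        result = te_containment([cand], tes)
        assert result.pairs == []
        assert len(result.any_overlap) == 1

    def test_full_containment_records_position(self):
        cand = GenomicInterval("chr1", 1200, 1700)
        result = te_containment([cand], [te(1000, 3000)])
        assert len(result.full_pairs) == 1
        assert result.position_fractions[0] == pytest.approx(200 / 1500)


class TestFamilyEnrichment:
    def test_worked_binomial_example(self):
        """M=100 baseline TEs, M_f=10 in the family, K=5 hits of which
        k_f=3 in the family: closed-form tail P(Bin(5, 0.1) >= 3)."""
        baseline = [te(i * 10_000, i * 10_000 + 1000,
                       family=("famF" if i < 10 else "famO"))
                    for i in range(100)]
        hits = [0, 1, 2, 40, 50]  # three in famF, two outside
        pairs = [(GenomicInterval("chr1", 1, 2), baseline[i]) for i in hits]
        result = {f.family: f for f in family_enrichment(pairs, baseline)}
        exact = sum(
            math.comb(5, k) * 0.1**k * 0.9 ** (5 - k) for k in range(3, 6)
        )
        assert exact == pytest.approx(0.00856, abs=1e-5)
        assert result["famF"].p_value == pytest.approx(exact, abs=1e-6)
        assert result["famF"].p_value == pytest.approx(
            float(sp_stats.binom.sf(2, 5, 0.1)), abs=1e-12
        )

    def test_zero_hits_p_one(self):
        baseline = [te(0, 1000), te(5000, 6000, family="famB")]
        result = family_enrichment([], baseline)
        assert all(f.p_value == 1.0 for f in result)

    def test_single_family_baseline_never_enriched(self):
        baseline = [te(i * 5000, i * 5000 + 1000) for i in range(10)]
        pairs = [(GenomicInterval("chr1", 1, 2), baseline[0])]
        (result,) = family_enrichment(pairs, baseline)
        assert result.p_value == 1.0
        assert not result.enriched

    def test_hit_counts_sum_to_total(self):
        baseline = [te(i * 5000, i * 5000 + 1000,
                       family=f"fam{i % 3}") for i in range(30)]
        pairs = [(GenomicInterval("chr1", 1, 2), baseline[i]) for i in (0, 4, 8, 13)]
        result = family_enrichment(pairs, baseline)
        assert sum(f.n_with_enhancer for f in result) == 4


def brute_force_motif_count(seq, motif):
    from Bio.Seq import Seq

    rc = str(Seq(motif).reverse_complement())
    n = 0
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i:i + len(motif)]
        if window == motif or window == rc:
            n += 1
    return n


class TestMotifScan:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAGGCCCATT", 1), ("AATGGGCCTT", 1), ("", 0), ("GGCCCAGGCCCA", 2)],
    )
    def test_examples(self, seq, expected):
        assert motif_scan([seq]) == [expected]

    def test_matches_sliding_window_oracle_on_random_sequences(self):
        rng = np.random.default_rng(19)
        bases = np.array(list("ACGT"))
        for _ in range(30):
            seq = "".join(bases[rng.integers(0, 4, size=int(rng.integers(50, 10_000)))])
            assert motif_scan([seq])[0] == brute_force_motif_count(seq, "GGCCCA")

    def test_degenerate_motif_rejected(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            motif_scan(["ACGT"], motif="GGNCCA")


class TestPermutationEnrichment:
    def test_features_equal_to_class_give_minimal_p(self):
        genome = Genome({"chr1": 100_000})
        mask = genome.as_interval_set()
        feats = IntervalSet([
            GenomicInterval("chr1", i * 10_000, i * 10_000 + 500) for i in range(5)
        ])
        out = permutation_enrichment(feats, feats, mask, n=100, seed=0)
        assert out["observed"] == 5
        assert out["p_value"] == pytest.approx(1 / 101)

    def test_empty_feature_set_p_one(self):
        genome = Genome({"chr1": 10_000})
        out = permutation_enrichment(
            IntervalSet(), genome.as_interval_set(), genome.as_interval_set(),
            n=10, seed=0,
        )
        assert out["p_value"] == 1.0

    def test_oversized_feature_rejected(self):
        mask = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        feats = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        small_mask = IntervalSet([GenomicInterval("chr1", 0, 500)])
        with pytest.raises(ValueError, match="longer than"):
            permutation_enrichment(feats, feats, small_mask, n=5, seed=0)

    def test_placement_respects_mask_and_is_non_overlapping(self):
        mask = IntervalSet([
            GenomicInterval("chr1", 0, 5000),
            GenomicInterval("chr1", 20_000, 30_000),
            GenomicInterval("chr2", 0, 8000),
        ]).merge()
        rng = np.random.default_rng(3)
        placed = _place_features(np.full(30, 400), list(mask), rng)
        assert len(placed) == 30
        assert placed.merge().subtract(mask).total_bp() == 0
        assert placed.merge().total_bp() == 30 * 400  # pairwise disjoint


class TestCnsOverlap:
    def test_flags(self):
        cands = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 5000, 6000)]
        cns = IntervalSet([GenomicInterval("chr1", 500, 600)])
        flags, count = cns_overlap(cands, cns)
        assert flags == [True, False] and count == 1

    def test_abutting_is_not_overlap(self):
        cands = [GenomicInterval("chr1", 1000, 2000)]
        cns = IntervalSet([GenomicInterval("chr1", 2000, 2100)])
        flags, count = cns_overlap(cands, cns)
        assert flags == [False] and count == 0

    def test_empty_cns_all_false(self):
        cands = [GenomicInterval("chr1", 0, 100)]
        flags, count = cns_overlap(cands, IntervalSet())
        assert flags == [False] and count == 0
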