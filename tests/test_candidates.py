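"""Candidate integration, specificity arithmetic, tissue-contrast ranking
and the rank-sum permutation null (checked against exhaustive enumeration)."""

from itertools import permutations

import numpy as np
import pytest

from enhancermap.candidates import (
    classify_specificity,
    integrate,
    rank_candidates,
    rank_permutation_p,
)
from enhancermap.config import PipelineConfig
from enhancermap.intervals import Genome, GenomicInterval, IntervalSet, SignalTrack
from enhancermap.partition import GeneModel, partition


@pytest.fixture
def distal_partition():
    """A 100-kb chromosome with one gene at [5000, 8000) (+ strand)."""
    genome = Genome({"chr1": 100_000})
    gene = GeneModel("g1", "chr1", 5000, 8000, "+", exons=[(5000, 8000)])
    return partition([gene], IntervalSet(), genome)


def tissue_sets(v2, husk):
    return {
        "V2-IST": IntervalSet([GenomicInterval("chr1", s, e) for s, e in v2]),
        "husk": IntervalSet([GenomicInterval("chr1", s, e) for s, e in husk]),
    }


class TestIntegrate:
    def test_triple_overlap_is_candidate(self, distal_partition):
        lumrs = IntervalSet([GenomicInterval("chr1", 41000, 42000)])
        dhs = tissue_sets([(41200, 41300)], [])
        k9 = tissue_sets([(41400, 41600)], [])
        out = integrate(lumrs, dhs, k9, distal_partition)
        assert len(out["V2-IST"]) == 1
        assert out["V2-IST"][0].region.start == 41000
        assert len(out["husk"]) == 0

    def test_missing_k9_not_a_candidate(self, distal_partition):
        lumrs = IntervalSet([GenomicInterval("chr1", 41000, 42000)])
        out = integrate(
            lumrs, tissue_sets([(41200, 41300)], []), tissue_sets([], []),
            distal_partition,
        )
        assert len(out["V2-IST"]) == 0

    def test_single_bp_promoter_overlap_excludes(self, distal_partition):
        # promoter is [4000, 5000); LUMR ends at 4001 -> 1 bp of overlap
        lumrs = IntervalSet([GenomicInterval("chr1", 3000, 4001)])
        dhs = tissue_sets([(3100, 3300)], [])
        k9 = tissue_sets([(3400, 3600)], [])
        out = integrate(lumrs, dhs, k9, distal_partition)
        assert len(out["V2-IST"]) == 0

    def test_missing_tissue_input_rejected(self, distal_partition):
        with pytest.raises(ValueError, match="missing"):
            integrate(IntervalSet(), {"V2-IST": IntervalSet()},
                      tissue_sets([], []), distal_partition)


class TestSpecificity:
    def make_candidates(self, part, v2_regions, husk_regions):
        all_regions = sorted(set(v2_regions) | set(husk_regions))
        lumrs = IntervalSet([GenomicInterval("chr1", s, e) for s, e in all_regions])
        dhs = tissue_sets(v2_regions, husk_regions)
        k9 = tissue_sets(v2_regions, husk_regions)
        per = integrate(lumrs, dhs, k9, part)
        return classify_specificity(per["V2-IST"], per["husk"])

    def test_shared_candidate(self, distal_partition):
        cands = self.make_candidates(
            distal_partition, [(30000, 31000)], [(30000, 31000)]
        )
        assert [c.specificity for c in cands] == ["shared"]

    def test_union_arithmetic(self, distal_partition):
        v2 = [(20000 + i * 2000, 21000 + i * 2000) for i in range(5)]
        husk = v2[:2] + [(60000 + i * 2000, 61000 + i * 2000) for i in range(4)]
        cands = self.make_candidates(distal_partition, v2, husk)
        n_shared = sum(1 for c in cands if c.specificity == "shared")
        n_v2 = sum(1 for c in cands if "V2-IST" in c.tissues_detected)
        n_husk = sum(1 for c in cands if "husk" in c.tissues_detected)
        assert n_shared == 2
        assert len(cands) == n_v2 + n_husk - n_shared

    def test_disjoint_sets_share_nothing(self, distal_partition):
        cands = self.make_candidates(
            distal_partition, [(20000, 21000)], [(60000, 61000)]
        )
        assert all(c.specificity != "shared" for c in cands)


def make_tracks(cand_signal):
    """Tracks where candidate i has V2-minus-husk contrast cand_signal[i]."""
    steps_v2, steps_husk = [], []
    for i, (dn, k9) in enumerate(cand_signal):
        s = 10_000 + i * 2000
        steps_v2.append((s, s + 500, max(dn, 0.0)))
        steps_husk.append((s, s + 500, max(-dn, 0.0)))
    dnase = {
        "V2-IST": SignalTrack({"chr1": [(s, e, v) for s, e, v in steps_v2]}),
        "husk": SignalTrack({"chr1": [(s, e, v) for s, e, v in steps_husk]}),
    }
    steps_v2, steps_husk = [], []
    for i, (dn, k9) in enumerate(cand_signal):
        s = 10_000 + i * 2000
        steps_v2.append((s, s + 500, max(k9, 0.0)))
        steps_husk.append((s, s + 500, max(-k9, 0.0)))
    k9t = {
        "V2-IST": SignalTrack({"chr1": [(s, e, v) for s, e, v in steps_v2]}),
        "husk": SignalTrack({"chr1": [(s, e, v) for s, e, v in steps_husk]}),
    }
    return dnase, k9t


def make_labeled_candidates(n):
    from enhancermap.candidates import EnhancerCandidate

    out = []
    for i in range(n):
        s = 10_000 + i * 2000
        c = EnhancerCandidate(
            region=GenomicInterval("chr1", s, s + 500),
            tissues_detected=["V2-IST"],
        )
        c.specificity = "V2-IST-specific"
        out.append(c)
    return out


class TestRanking:
    def test_rank_sum_and_ids(self):
        # dnase contrasts give ranks (1,2,3); k9 contrasts give (2,1,3)
        cands = make_labeled_candidates(3)
        dnase, k9 = make_tracks([(5.0, 2.0), (3.0, 4.0), (1.0, 0.5)])
        ranked = rank_candidates(cands, dnase, k9, "V2-IST")
        by_start = sorted(ranked, key=lambda c: c.region.start)
        assert [c.dnase_rank["V2-IST"] for c in by_start] == [1, 2, 3]
        assert [c.k9_rank["V2-IST"] for c in by_start] == [2, 1, 3]
        assert [c.rank_sum["V2-IST"] for c in by_start] == [3, 3, 6]
        # tie on rank_sum 3 broken by dnase_rank
        assert [c.overall_rank["V2-IST"] for c in by_start] == [1, 2, 3]
        assert [c.candidate_id["V2-IST"] for c in by_start] == ["V1", "V2", "V3"]

    def test_negative_contrast_ranks_last(self):
        cands = make_labeled_candidates(3)
        dnase, k9 = make_tracks([(5.0, 2.0), (-4.0, -1.0), (3.0, 1.0)])
        ranked = rank_candidates(cands, dnase, k9, "V2-IST")
        worst = max(ranked, key=lambda c: c.overall_rank["V2-IST"])
        assert worst.region.start == 10_000 + 1 * 2000
        assert worst.dnase_diff["V2-IST"] < 0

    def test_single_candidate_all_ranks_one(self):
        cands = make_labeled_candidates(1)
        dnase, k9 = make_tracks([(2.0, 2.0)])
        (only,) = rank_candidates(cands, dnase, k9, "V2-IST")
        assert only.dnase_rank["V2-IST"] == only.k9_rank["V2-IST"] == 1
        assert only.overall_rank["V2-IST"] == 1
        assert only.candidate_id["V2-IST"] == "V1"


def exhaustive_rank1_p(n, observed_sum):
    """Oracle: exact P(smallest position-wise sum of two random
    permutations of 1..n <= observed_sum) by enumeration."""
    hits = total = 0
    for p1 in permutations(range(1, n + 1)):
        for p2 in permutations(range(1, n + 1)):
            total += 1
            if min(a + b for a, b in zip(p1, p2)) <= observed_sum:
                hits += 1
    return hits / total


class TestPermutationP:
    def test_minimal_sum_matches_exhaustive_null(self):
        """At N=3, the exact null gives P(rank-1 sum <= 2) = 12/36 = 1/3
        (the two 1s must align); the sampled estimate converges to it."""
        exact = exhaustive_rank1_p(3, 2)
        assert exact == pytest.approx(12 / 36)
        p = rank_permutation_p(3, [2, 4, 6], n_perm=20_000, seed=3)
        assert p[0] == pytest.approx(exact, abs=0.01)

    def test_maximal_sum_at_last_rank_is_one(self):
        n = 5
        p = rank_permutation_p(n, [2, 4, 6, 8, 2 * n], n_perm=500, seed=0)
        assert p[-1] == 1.0

    def test_deterministic_given_seed(self):
        obs = [3, 5, 7, 9]
        a = rank_permutation_p(4, obs, n_perm=200, seed=11)
        b = rank_permutation_p(4, obs, n_perm=200, seed=11)
        c = rank_permutation_p(4, obs, n_perm=200, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_p_values_in_unit_interval(self):
        p = rank_permutation_p(10, sorted(np.arange(2, 22, 2)), n_perm=100, seed=1)
        assert np.all(p > 0) and np.all(p <= 1)
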