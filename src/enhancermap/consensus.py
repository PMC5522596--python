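"""Replicate consensus for DNase and H3K9ac peak calls.

Two peaks agree when they overlap reciprocally by at least 70% of each
peak's length; the retained region is the union of the agreeing peaks.
With three replicates, the first two are integrated and the result is then
chained against the third under the same rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .intervals import GenomicInterval, IntervalSet, overlap_stats

__all__ = ["ReplicatePeakSet", "ConsensusReport", "consensus"]


@dataclass
class ReplicatePeakSet:
    """Peak calls of one biological replicate (merged-disjoint)."""

    tissue: str
    assay: str  # "DNase" or "H3K9ac"
    replicate_id: str
    peaks: IntervalSet

    def __post_init__(self) -> None:
        self.peaks = self.peaks.merge()


@dataclass
class ConsensusReport:
    """Bookkeeping from one consensus run: pairs tested and kept per stage."""

    stages: List[Dict[str, int]] = field(default_factory=list)


def _pairwise_consensus(
    a: IntervalSet, b: IntervalSet, min_frac: float
) -> Tuple[IntervalSet, Dict[str, int]]:
    """Reciprocal-overlap consensus between two merged-disjoint peak sets.

    Peaks connected by a passing pair form components whose members are
    merged into one retained region (union coordinates).
    """
    kept: List[GenomicInterval] = []
    pairs_tested = 0
    pairs_passed = 0
    for chrom in a.chromosomes:
        b_on = b.on(chrom)
        if not b_on:
            continue
        for pa in a.on(chrom):
            for pb in b.overlapping(pa):
                pairs_tested += 1
                ov, frac_a, frac_b = overlap_stats(pa, pb)
                if frac_a >= min_frac and frac_b >= min_frac:
                    pairs_passed += 1
                    kept.append(GenomicInterval(chrom, min(pa.start, pb.start),
                                                max(pa.end, pb.end)))
    result = IntervalSet(kept).merge()
    return result, {
        "pairs_tested": pairs_tested,
        "pairs_passed": pairs_passed,
        "regions_kept": len(result),
    }


def consensus(
    replicates: Sequence[ReplicatePeakSet],
    min_frac: float = 0.70,
    report: ConsensusReport | None = None,
) -> IntervalSet:
    """High-confidence consensus regions across 2+ replicates.

    Raises ``ValueError`` with fewer than two replicates; an empty replicate
    yields an empty consensus with a warning.
    """
    if len(replicates) < 2:
        raise ValueError(f"consensus requires >= 2 replicates, got {len(replicates)}")
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    for rep in replicates:
        if len(rep.peaks) == 0:
            warnings.warn(
                f"replicate {rep.replicate_id} ({rep.tissue} {rep.assay}) has no peaks; "
                "consensus will be empty"
            )
    current = replicates[0].peaks
    for rep in replicates[1:]:
        current, stats = _pairwise_consensus(current, rep.peaks, min_frac)
        if report is not None:
            report.stages.append(stats)
    return current
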