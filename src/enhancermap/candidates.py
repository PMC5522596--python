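"""Integration of LUMRs, consensus DHSs and consensus H3K9ac regions into
per-tissue enhancer candidates, tissue-specificity labels, tissue-contrast
ranking and permutation p-values.

A candidate is a LUMR that overlaps (>= 1 bp) at least one consensus DHS and
one consensus H3K9ac region in a tissue while overlapping zero genic or
promoter base pairs. Candidates found in both tissues (identical LUMR
coordinates, since LUMRs are tissue-independent) are "shared"; the rest are
tissue-specific.

Ranking: for each candidate and each assay, the contrast is the largest
per-position signed difference (candidate tissue minus the other tissue) on
the step tracks. Candidates are ranked per assay descending, the two ranks
are summed and the sum re-ranked ascending to give the overall rank; the
candidate ID is the tissue letter (V or H) plus the overall rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, IntervalSet, SignalTrack
from .partition import RegionPartition

__all__ = [
    "TISSUES",
    "EnhancerCandidate",
    "integrate",
    "classify_specificity",
    "rank_candidates",
    "rank_permutation_p",
]

TISSUES = ("V2-IST", "husk")
TISSUE_LETTER = {"V2-IST": "V", "husk": "H"}


@dataclass
class EnhancerCandidate:
    """A qualifying LUMR with per-tissue evidence, ranks and p-values."""

    region: GenomicInterval
    tissues_detected: List[str]
    dhs_list: Dict[str, List[GenomicInterval]] = field(default_factory=dict)
    k9_list: Dict[str, List[GenomicInterval]] = field(default_factory=dict)
    specificity: Optional[str] = None  # "V2-IST-specific" | "husk-specific" | "shared"
    dnase_diff: Dict[str, float] = field(default_factory=dict)
    k9_diff: Dict[str, float] = field(default_factory=dict)
    dnase_rank: Dict[str, int] = field(default_factory=dict)
    k9_rank: Dict[str, int] = field(default_factory=dict)
    rank_sum: Dict[str, int] = field(default_factory=dict)
    overall_rank: Dict[str, int] = field(default_factory=dict)
    rank_p: Dict[str, float] = field(default_factory=dict)
    candidate_id: Dict[str, str] = field(default_factory=dict)
    cns: bool = False

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.region.chrom, self.region.start, self.region.end)


def integrate(
    lumrs: IntervalSet,
    dhs_consensus: Dict[str, IntervalSet],
    k9_consensus: Dict[str, IntervalSet],
    part: RegionPartition,
) -> Dict[str, List[EnhancerCandidate]]:
    """Per-tissue candidate sets from the three-feature overlap rule."""
    for tissue in TISSUES:
        if tissue not in dhs_consensus or tissue not in k9_consensus:
            raise ValueError(f"missing consensus peak input for tissue {tissue!r}")
    exclusion = part.genic_and_promoter
    out: Dict[str, List[EnhancerCandidate]] = {t: [] for t in TISSUES}
    for lumr in lumrs:
        if exclusion.overlaps(lumr):
            continue
        for tissue in TISSUES:
            dhs_hits = dhs_consensus[tissue].overlapping(lumr)
            if not dhs_hits:
                continue
            k9_hits = k9_consensus[tissue].overlapping(lumr)
            if not k9_hits:
                continue
            out[tissue].append(
                EnhancerCandidate(
                    region=lumr,
                    tissues_detected=[tissue],
                    dhs_list={tissue: dhs_hits},
                    k9_list={tissue: k9_hits},
                )
            )
    return out


def classify_specificity(
    candidates_v2: Sequence[EnhancerCandidate],
    candidates_husk: Sequence[EnhancerCandidate],
) -> List[EnhancerCandidate]:
    """Merge per-tissue candidate lists into one labeled union list.

    Shared candidates are those whose LUMR coordinates qualify in both
    tissues; |union| = |V2| + |husk| - |shared| holds exactly.
    """
    by_key: Dict[Tuple[str, int, int], EnhancerCandidate] = {}
    for cand in candidates_v2:
        by_key[cand.key] = cand
    for cand in candidates_husk:
        if cand.key in by_key:
            merged = by_key[cand.key]
            merged.tissues_detected = ["V2-IST", "husk"]
            merged.dhs_list.update(cand.dhs_list)
            merged.k9_list.update(cand.k9_list)
        else:
            by_key[cand.key] = cand
    union = sorted(by_key.values(), key=lambda c: c.key)
    for cand in union:
        if len(cand.tissues_detected) == 2:
            cand.specificity = "shared"
        else:
            cand.specificity = f"{cand.tissues_detected[0]}-specific"
    return union


def rank_candidates(
    candidates: Sequence[EnhancerCandidate],
    dnase_tracks: Dict[str, SignalTrack],
    k9_tracks: Dict[str, SignalTrack],
    tissue: str,
) -> List[EnhancerCandidate]:
    """Rank the candidates detected in ``tissue`` by tissue contrast.

    Ties in per-assay differences share no rank: ordering is by descending
    difference then (chrom, start) for determinism. The overall rank orders
    the rank sums ascending with ties broken by (dnase_rank, chrom, start).
    Returns the ranked sub-list (shared candidates appear in both tissues'
    lists).
    """
    other = "husk" if tissue == "V2-IST" else "V2-IST"
    in_tissue = [c for c in candidates if tissue in c.tissues_detected]
    for cand in in_tissue:
        cand.dnase_diff[tissue] = dnase_tracks[tissue].max_difference(
            dnase_tracks[other], cand.region
        )
        cand.k9_diff[tissue] = k9_tracks[tissue].max_difference(
            k9_tracks[other], cand.region
        )
    for attr, rank_attr in (("dnase_diff", "dnase_rank"), ("k9_diff", "k9_rank")):
        ordered = sorted(
            in_tissue,
            key=lambda c: (-getattr(c, attr)[tissue], c.region.chrom, c.region.start),
        )
        for r, cand in enumerate(ordered, start=1):
            getattr(cand, rank_attr)[tissue] = r
    for cand in in_tissue:
        cand.rank_sum[tissue] = cand.dnase_rank[tissue] + cand.k9_rank[tissue]
    ordered = sorted(
        in_tissue,
        key=lambda c: (
            c.rank_sum[tissue],
            c.dnase_rank[tissue],
            c.region.chrom,
            c.region.start,
        ),
    )
    letter = TISSUE_LETTER[tissue]
    for r, cand in enumerate(ordered, start=1):
        cand.overall_rank[tissue] = r
        cand.candidate_id[tissue] = f"{letter}{r}"
    return ordered


def rank_permutation_p(
    n_candidates: int,
    observed_rank_sums: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
    n_features: int = 2,
) -> np.ndarray:
    """Permutation p-values for rank sums, per overall rank position.

    The null re-ranks ``n_features`` independent uniform permutations of
    1..N summed position-wise; for the candidate at overall rank r with sum
    s, p is the fraction of permutations whose r-th smallest null sum is
    <= s, floored at 1/n_perm so p is never exactly zero (a zero count means
    "< 1/n_perm"). ``observed_rank_sums`` must be ordered by overall rank
    (ascending sums). Deterministic given ``seed``.
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    observed = np.asarray(observed_rank_sums)
    if observed.shape != (n_candidates,):
        raise ValueError("observed_rank_sums must have one entry per candidate")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_candidates, dtype=np.int64)
    base = np.arange(1, n_candidates + 1)
    for _ in range(n_perm):
        sums = np.zeros(n_candidates, dtype=np.int64)
        for _f in range(n_features):
            sums += rng.permutation(base)
        sums.sort()
        counts += sums <= observed
    return np.maximum(counts, 1) / n_perm
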