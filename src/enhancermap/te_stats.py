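"""Transposable-element containment and family enrichment, motif-occurrence
enrichment, conserved-non-coding-sequence overlap, and the generic
permutation test for feature distributions within the mappable genome.

Family enrichment follows a binomial model: with K enhancer-containing TEs
drawn from a baseline of M elements, a family with M_f members and k_f
enhancer-containing members has p = P(X >= k_f), X ~ Binomial(K, M_f / M),
Bonferroni-corrected over the families tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, overlap_stats

__all__ = [
    "TEAnnotation",
    "FamilyEnrichment",
    "TEContainment",
    "resolve_nested_and_filter",
    "te_containment",
    "family_enrichment",
    "motif_scan",
    "motif_enrichment",
    "permutation_enrichment",
    "cns_overlap",
]


@dataclass
class TEAnnotation:
    """A transposable element with family and superfamily labels."""

    interval: GenomicInterval
    family: str
    superfamily: str = "other"  # LTR | TIR | helitron | other

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("TE family id must be non-empty")


@dataclass
class FamilyEnrichment:
    family: str
    n_members: int        # baseline members M_f
    n_with_enhancer: int  # enhancer-containing members k_f
    p_value: float
    p_adjusted: float
    enriched: bool

    def __post_init__(self) -> None:
        if self.n_with_enhancer > self.n_members:
            raise ValueError("k_f cannot exceed M_f")


@dataclass
class TEContainment:
    """Containment tallies of candidates within single TEs."""

    pairs: List[Tuple[GenomicInterval, TEAnnotation]]          # >= min_frac containment
    full_pairs: List[Tuple[GenomicInterval, TEAnnotation]]     # 100% containment
    any_overlap: List[GenomicInterval]                         # >= 1 bp with any TE
    position_fractions: List[float] = field(default_factory=list)


def resolve_nested_and_filter(
    tes: Sequence[TEAnnotation],
    introns: IntervalSet,
    min_len: int = 635,
) -> List[TEAnnotation]:
    """Baseline TE set: outermost elements only, non-intronic, length > min_len.

    Elements fully contained within another TE are nested insertions and are
    dropped (the outermost span represents the locus); elements fully inside
    introns are dropped; elements with length <= ``min_len`` are dropped.
    """
    by_chrom: Dict[str, List[TEAnnotation]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    out: List[TEAnnotation] = []
    for chrom, group in sorted(by_chrom.items()):
        group.sort(key=lambda t: (t.interval.start, -t.interval.end))
        max_end_so_far = -1
        for te in group:
            iv = te.interval
            nested = iv.end <= max_end_so_far
            max_end_so_far = max(max_end_so_far, iv.end)
            if nested:
                continue
            if len(iv) <= min_len:
                continue
            if introns.overlap_bp(iv) == len(iv):
                continue
            out.append(te)
    return out


def te_containment(
    candidates: Sequence[GenomicInterval],
    tes: Sequence[TEAnnotation],
    min_frac: float = 0.80,
) -> TEContainment:
    """Candidates contained (>= ``min_frac`` of their length) within a single TE.

    Also tallies any-overlap and full containment, and for fully contained
    candidates the relative position within the TE (for randomness checks of
    where enhancers sit inside elements).
    """
    te_set = IntervalSet([t.interval for t in tes])
    by_key = {
        (t.interval.chrom, t.interval.start, t.interval.end): t for t in tes
    }
    pairs: List[Tuple[GenomicInterval, TEAnnotation]] = []
    full_pairs: List[Tuple[GenomicInterval, TEAnnotation]] = []
    any_overlap: List[GenomicInterval] = []
    position_fractions: List[float] = []
    for cand in candidates:
        hits = te_set.overlapping(cand)
        if not hits:
            continue
        any_overlap.append(cand)
        best = max(hits, key=lambda h: overlap_stats(cand, h)[0])
        ov, frac_c, _ = overlap_stats(cand, best)
        te = by_key[(best.chrom, best.start, best.end)]
        if frac_c >= min_frac:
            pairs.append((cand, te))
        if frac_c == 1.0:
            full_pairs.append((cand, te))
            slack = len(best) - len(cand)
            position_fractions.append(
                (cand.start - best.start) / slack if slack > 0 else 0.5
            )
    return TEContainment(
        pairs=pairs, full_pairs=full_pairs,
        any_overlap=any_overlap, position_fractions=position_fractions,
    )


def family_enrichment(
    te_enhancer_pairs: Sequence[Tuple[GenomicInterval, TEAnnotation]],
    baseline: Sequence[TEAnnotation],
    alpha: float = 0.05,
) -> List[FamilyEnrichment]:
    """Binomial family enrichment with Bonferroni correction.

    Only families with at least one enhancer-containing member are tested;
    the correction factor is the number of families tested.
    """
    if not baseline:
        raise ValueError("baseline TE set must be non-empty")
    baseline_keys = {
        (t.interval.chrom, t.interval.start, t.interval.end) for t in baseline
    }
    members: Dict[str, int] = {}
    for te in baseline:
        members[te.family] = members.get(te.family, 0) + 1
    hit_tes = {
        (t.interval.chrom, t.interval.start, t.interval.end): t
        for _, t in te_enhancer_pairs
        if (t.interval.chrom, t.interval.start, t.interval.end) in baseline_keys
    }
    k_total = len(hit_tes)
    k_per_family: Dict[str, int] = {}
    for te in hit_tes.values():
        k_per_family[te.family] = k_per_family.get(te.family, 0) + 1
    total_m = len(baseline)
    tested = sorted(k_per_family)
    n_tests = len(tested)
    out: List[FamilyEnrichment] = []
    for fam in sorted(members):
        k_f = k_per_family.get(fam, 0)
        m_f = members[fam]
        if k_total == 0 or k_f == 0:
            p = 1.0
        else:
            p = float(stats.binom.sf(k_f - 1, k_total, m_f / total_m))
        adj = min(1.0, p * n_tests) if k_f >= 1 else 1.0
        out.append(
            FamilyEnrichment(
                family=fam, n_members=m_f, n_with_enhancer=k_f,
                p_value=p, p_adjusted=adj, enriched=(k_f >= 1 and adj < alpha),
            )
        )
    return out


def motif_scan(sequences: Sequence[str], motif: str = "GGCCCA") -> List[int]:
    """Exact-match occurrence counts per sequence, both strands, overlaps counted."""
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be a non-degenerate DNA string, got {motif!r}")
    rc = str(Seq(motif).reverse_complement())
    patterns = {motif, rc}
    counts: List[int] = []
    for seq in sequences:
        s = seq.upper()
        n = 0
        for pat in patterns:
            start = s.find(pat)
            while start != -1:
                n += 1
                start = s.find(pat, start + 1)
        counts.append(n)
    return counts


def _random_intergenic_draw(
    lengths: Sequence[int],
    segments: List[GenomicInterval],
    rng: np.random.Generator,
) -> List[GenomicInterval]:
    seg_lens = np.array([len(s) for s in segments])
    out = []
    for length in lengths:
        capacity = seg_lens - length + 1
        ok = capacity > 0
        if not ok.any():
            raise ValueError(
                f"no intergenic segment can host a draw of length {length}"
            )
        probs = np.where(ok, capacity, 0).astype(float)
        probs /= probs.sum()
        k = int(rng.choice(len(segments), p=probs))
        offset = int(rng.integers(0, capacity[k]))
        seg = segments[k]
        out.append(GenomicInterval(seg.chrom, seg.start + offset, seg.start + offset + length))
    return out


def motif_enrichment(
    candidate_seqs: Sequence[str],
    fetch_sequence,
    intergenic_regions: IntervalSet,
    motif: str = "GGCCCA",
    n_draws: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Fold enrichment of motif presence vs length-matched intergenic draws.

    ``fetch_sequence(interval) -> str`` pulls genomic sequence (e.g. from a
    pyfaidx-backed genome). Empirical p is the fraction of draws whose
    presence fraction reaches the observed one, with the (b+1)/(n+1)
    estimator so p is never exactly 0. When the motif occurs nowhere the
    fold is undefined and flagged with ``fold = nan``.
    """
    observed_counts = motif_scan(candidate_seqs, motif)
    obs_frac = float(np.mean([c > 0 for c in observed_counts]))
    lengths = [len(s) for s in candidate_seqs]
    segments = list(intergenic_regions.merge())
    rng = np.random.default_rng(seed)
    null_fracs = np.empty(n_draws)
    for d in range(n_draws):
        draw = _random_intergenic_draw(lengths, segments, rng)
        counts = motif_scan([fetch_sequence(iv) for iv in draw], motif)
        null_fracs[d] = np.mean([c > 0 for c in counts])
    mean_null = float(null_fracs.mean())
    if obs_frac == 0 and mean_null == 0:
        warnings.warn("motif absent from candidates and background; fold undefined")
        fold = float("nan")
    elif mean_null == 0:
        fold = float("inf")
    else:
        fold = obs_frac / mean_null
    b = int(np.sum(null_fracs >= obs_frac))
    return {
        "observed_fraction": obs_frac,
        "null_mean_fraction": mean_null,
        "fold": fold,
        "p_value": (b + 1) / (n_draws + 1),
        "n_draws": n_draws,
    }


def _place_features_arrays(
    lengths: np.ndarray,
    segments: List[GenomicInterval],
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
    """Place features uniformly in the mask without mutual overlap.

    Returns (chrom_index, start, end) arrays. Placement is vectorised:
    all pending features are drawn at once, collisions (with accepted
    features or among the new draws, detected by a sorted sweep) are
    re-drawn, up to ``max_retries`` rounds.
    """
    seg_lens = np.array([len(s) for s in segments], dtype=np.int64)
    seg_starts = np.array([s.start for s in segments], dtype=np.int64)
    chrom_names = sorted({s.chrom for s in segments})
    chrom_idx_of_seg = np.array(
        [chrom_names.index(s.chrom) for s in segments], dtype=np.int64
    )
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.max(initial=0) > seg_lens.max(initial=0):
        raise ValueError("a feature is longer than the largest mask segment")

    n = len(lengths)
    acc_chrom = np.empty(0, dtype=np.int64)
    acc_start = np.empty(0, dtype=np.int64)
    acc_end = np.empty(0, dtype=np.int64)
    pending = lengths.copy()
    for _round in range(max_retries):
        if len(pending) == 0:
            break
        # draw a segment (weighted by capacity for this length) and an offset
        new_start = np.empty(len(pending), dtype=np.int64)
        new_chrom = np.empty(len(pending), dtype=np.int64)
        for length in np.unique(pending):
            sel = pending == length
            capacity = np.maximum(seg_lens - length + 1, 0)
            probs = capacity / capacity.sum()
            segs = rng.choice(len(segments), size=int(sel.sum()), p=probs)
            offsets = (rng.random(int(sel.sum())) * capacity[segs]).astype(np.int64)
            new_start[sel] = seg_starts[segs] + offsets
            new_chrom[sel] = chrom_idx_of_seg[segs]
        new_end = new_start + pending
        # pass 1: reject draws overlapping an already-accepted feature
        # (accepted features are disjoint and act as fixed obstacles)
        keep = np.ones(len(pending), dtype=bool)
        for ci in np.unique(new_chrom):
            on_acc = acc_chrom == ci
            if not on_acc.any():
                continue
            a_order = np.argsort(acc_start[on_acc], kind="stable")
            a_start = acc_start[on_acc][a_order]
            a_end = acc_end[on_acc][a_order]
            sel = new_chrom == ci
            idx = np.searchsorted(a_start, new_start[sel], side="right") - 1
            prev_hit = (idx >= 0) & (a_end[np.clip(idx, 0, None)] > new_start[sel])
            nxt = idx + 1
            next_hit = (nxt < len(a_start)) & (
                a_start[np.clip(nxt, 0, len(a_start) - 1)] < new_end[sel]
            )
            keep[sel] &= ~(prev_hit | next_hit)
        # pass 2: sweep among the surviving draws; later-starting colliders re-draw
        order = np.lexsort((new_start, new_chrom))
        running_end = -1
        running_chrom = -1
        for k in order:
            if not keep[k]:
                continue
            if new_chrom[k] != running_chrom:
                running_chrom = int(new_chrom[k])
                running_end = -1
            if new_start[k] < running_end:
                keep[k] = False
            else:
                running_end = max(running_end, int(new_end[k]))
        acc_chrom = np.concatenate([acc_chrom, new_chrom[keep]])
        acc_start = np.concatenate([acc_start, new_start[keep]])
        acc_end = np.concatenate([acc_end, new_end[keep]])
        pending = pending[~keep]
    else:
        if len(pending):
            raise RuntimeError(
                f"could not place {len(pending)} feature(s) without overlap "
                f"after {max_retries} rounds"
            )
    return acc_chrom, acc_start, acc_end, chrom_names


def _place_features(
    lengths: np.ndarray,
    segments: List[GenomicInterval],
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> IntervalSet:
    chroms, starts, ends, names = _place_features_arrays(
        np.asarray(lengths), segments, rng, max_retries
    )
    return IntervalSet(
        [GenomicInterval(names[int(c)], int(s), int(e))
         for c, s, e in zip(chroms, starts, ends)]
    )


def permutation_enrichment(
    features: IntervalSet,
    region_class: IntervalSet,
    mappable_mask: IntervalSet,
    n: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Permutation test: are features over-represented in a region class?

    The observed statistic is the number of features overlapping the class
    by >= 1 bp. Each permutation re-places the features (lengths preserved,
    non-overlapping) uniformly at random within the mappable mask. The
    enrichment p uses the (b+1)/(n+1) estimator.
    """
    feats = list(features)
    if not feats:
        return {"observed": 0, "null_mean": 0.0, "null_sd": 0.0, "p_value": 1.0, "n": n}
    observed = sum(1 for f in feats if region_class.overlaps(f))
    lengths = np.array([len(f) for f in feats])
    segments = list(mappable_mask.merge())
    rng = np.random.default_rng(seed)

    # merged region class per chromosome for O(log n) vectorised overlap tests
    merged_class = region_class.merge()
    chrom_names = sorted({s.chrom for s in segments})
    class_coords = {}
    for ci, chrom in enumerate(chrom_names):
        ivs = merged_class.on(chrom)
        class_coords[ci] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )

    def count_overlaps(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> int:
        total = 0
        for ci, (cs, ce) in class_coords.items():
            if len(cs) == 0:
                continue
            sel = chroms == ci
            if not sel.any():
                continue
            # merged-disjoint: only the last region starting before each
            # feature's end can overlap it
            idx = np.searchsorted(cs, ends[sel], side="left") - 1
            ok = idx >= 0
            hit = np.zeros(int(sel.sum()), dtype=bool)
            hit[ok] = ce[idx[ok]] > starts[sel][ok]
            total += int(hit.sum())
        return total

    null = np.empty(n)
    for i in range(n):
        c, s, e, _ = _place_features_arrays(lengths, segments, rng)
        null[i] = count_overlaps(c, s, e)
    b = int(np.sum(null >= observed))
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std()),
        "p_value": (b + 1) / (n + 1),
        "n": n,
    }


def cns_overlap(
    candidates: Sequence[GenomicInterval], cns_set: IntervalSet
) -> Tuple[List[bool], int]:
    """Per-candidate conserved-non-coding-sequence flags and their total."""
    flags = [cns_set.overlaps(c) for c in candidates]
    return flags, sum(flags)
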