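"""Calling of low/unmethylated regions (LUMRs) from per-cytosine CG and CHG
methylation frequencies.

Regions with below-threshold methylation are segmented independently in the
CG and CHG contexts, intersected, and then re-filtered on the coverage-
weighted mean frequency over fixed 100-bp windows. CHH methylation is never
used for region calling (it is uniformly low in maize) but is carried through
for profiling.

Segmentation here is a transparent run-based segmenter: maximal runs of
consecutive covered sites below the frequency threshold, with at least
``min_sites`` sites no more than ``max_gap_bp`` apart. Sites at exactly the
threshold break a run (strict ``<``), and regions whose windowed mean is at
or above the threshold are dropped (``>=``), so the boundary case is excluded
on both routes.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, SignalTrack

__all__ = [
    "segment_low",
    "combine_lumr",
    "filter_mean_methylation",
    "call_lumrs",
    "methylation_window_track",
]


def segment_low(
    sites: pd.DataFrame,
    context: str,
    threshold: float = 0.20,
    min_sites: int = 4,
    max_gap_bp: int = 300,
) -> IntervalSet:
    """Maximal runs of low-methylation sites in one context.

    ``sites`` has columns chrom, pos, context, frequency, coverage. Sites
    with zero coverage are skipped (frequency undefined). A region spans the
    first through last site of the run, end-exclusive (+1).
    """
    if context not in ("CG", "CHG"):
        raise ValueError(f"context must be 'CG' or 'CHG', got {context!r}")
    sel = sites[(sites["context"] == context) & (sites["coverage"] > 0)]
    if sel.empty:
        warnings.warn(f"no covered {context} sites; returning empty set")
        return IntervalSet(merged=True)
    out: List[GenomicInterval] = []
    for chrom, group in sel.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        low = (group["frequency"].to_numpy()[order] < threshold)
        run_start_idx: Optional[int] = None
        prev_pos = None
        n_in_run = 0

        def close_run(last_pos: int, first_pos: int, n: int) -> None:
            if n >= min_sites:
                out.append(GenomicInterval(str(chrom), int(first_pos), int(last_pos) + 1))

        first_pos = None
        for p, is_low in zip(pos, low):
            if is_low and (prev_pos is None or not n_in_run or p - prev_pos <= max_gap_bp):
                if n_in_run == 0:
                    first_pos = p
                n_in_run += 1
            elif is_low:
                # gap too large: close and restart
                close_run(prev_pos, first_pos, n_in_run)
                first_pos = p
                n_in_run = 1
            else:
                if n_in_run:
                    close_run(prev_pos, first_pos, n_in_run)
                n_in_run = 0
            if is_low:
                prev_pos = p
        if n_in_run:
            close_run(prev_pos, first_pos, n_in_run)
    return IntervalSet(out).merge()


def combine_lumr(cg_low: IntervalSet, chg_low: IntervalSet) -> IntervalSet:
    """LUMRs: regions low in both CG and CHG context (intersection)."""
    return cg_low.intersect(chg_low)


def filter_mean_methylation(
    regions: IntervalSet,
    sites: pd.DataFrame,
    max_mean: float = 0.20,
    window: int = 100,
) -> IntervalSet:
    """Drop regions whose windowed mean CG+CHG methylation is >= ``max_mean``.

    For each region, coverage-weighted mean frequencies are computed over the
    fixed genome-aligned ``window``-bp windows it touches, and the region's
    score is the average of those window means. Regions with no covered
    sites are retained with a warning (they cannot be contradicted).
    """
    sel = sites[sites["context"].isin(["CG", "CHG"]) & (sites["coverage"] > 0)]
    kept: List[GenomicInterval] = []
    for iv in regions:
        on = sel[(sel["chrom"] == iv.chrom)
                 & (sel["pos"] >= iv.start) & (sel["pos"] < iv.end)]
        if on.empty:
            warnings.warn(
                f"region {iv.chrom}:{iv.start}-{iv.end} has no covered CG/CHG sites; retained"
            )
            kept.append(iv)
            continue
        win_idx = on["pos"].to_numpy() // window
        weights = on["coverage"].to_numpy().astype(float)
        freqs = on["frequency"].to_numpy()
        df = pd.DataFrame({"w": win_idx, "cw": weights, "fw": freqs * weights})
        per_window = df.groupby("w").sum()
        window_means = per_window["fw"] / per_window["cw"]
        if float(window_means.mean()) < max_mean:
            kept.append(iv)
    return IntervalSet(kept, merged=regions.merged)


def call_lumrs(
    sites: pd.DataFrame,
    threshold: float = 0.20,
    min_sites: int = 4,
    max_gap_bp: int = 300,
    window: int = 100,
) -> IntervalSet:
    """Full LUMR calling: segment CG and CHG, intersect, filter on windowed mean."""
    cg = segment_low(sites, "CG", threshold, min_sites, max_gap_bp)
    chg = segment_low(sites, "CHG", threshold, min_sites, max_gap_bp)
    return filter_mean_methylation(combine_lumr(cg, chg), sites, threshold, window)


def methylation_window_track(
    sites: pd.DataFrame, context: str, window: int = 100
) -> SignalTrack:
    """Coverage-weighted mean frequency per fixed window, as a step track."""
    sel = sites[(sites["context"] == context) & (sites["coverage"] > 0)]
    steps: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom, group in sel.groupby("chrom", sort=True):
        win_idx = group["pos"].to_numpy() // window
        weights = group["coverage"].to_numpy().astype(float)
        freqs = group["frequency"].to_numpy()
        df = pd.DataFrame({"w": win_idx, "cw": weights, "fw": freqs * weights})
        agg = df.groupby("w").sum()
        means = agg["fw"] / agg["cw"]
        steps[str(chrom)] = [
            (int(w) * window, (int(w) + 1) * window, float(m))
            for w, m in means.items()
        ]
    return SignalTrack(steps)
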